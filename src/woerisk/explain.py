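"""Closed-form SHAP attributions for the linear WoE risk model.

For a linear model on WoE features the Shapley value of variable i has the
closed form

    phi_i(x) = w_i * (WoE_i(x_i) - mean over the reference sample of WoE_i),

on the log-odds scale, so contributions sum to the subject's log-odds minus
the reference-mean log-odds (local accuracy).  Variables are ranked by the
mean absolute contribution over the sample — the usual bar-chart summary.
The reference sample is the training set by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .model import FittedRiskModel, woe_design

logger = logging.getLogger(__name__)

__all__ = ["ContributionSet", "shap_values", "rank_variables"]


@dataclass
class ContributionSet:
    """Per-subject, per-variable log-odds contributions."""

    phi: pd.DataFrame                 # subjects x selected variables
    reference_means: pd.Series        # mean WoE per variable over reference
    reference_n: int
    reference_mean_log_odds: float
    log_odds: np.ndarray              # full model log-odds per subject


def shap_values(model: FittedRiskModel, reference: CohortTable,
                subjects: CohortTable) -> ContributionSet:
    """Exact linear SHAP values for every subject against a reference
    sample (the training set, conventionally)."""
    if reference.n == 0:
        raise ValueError("reference cohort is empty")
    names = list(model.selected)
    ref_woe = woe_design(reference, model.schemes, names)
    sub_woe = woe_design(subjects, model.schemes, names)
    w = pd.Series({n: model.weights[n] for n in names})
    ref_means = ref_woe.mean(axis=0)
    phi = (sub_woe - ref_means) * w
    log_odds = model.intercept + sub_woe.to_numpy() @ w.to_numpy() \
        if names else np.full(subjects.n, model.intercept)
    ref_mean_lo = model.intercept + float(ref_means @ w) if names \
        else model.intercept
    return ContributionSet(
        phi=phi,
        reference_means=ref_means,
        reference_n=reference.n,
        reference_mean_log_odds=ref_mean_lo,
        log_odds=np.asarray(log_odds, dtype=float),
    )


def rank_variables(contributions: ContributionSet, top_k: int | None = None
                   ) -> pd.DataFrame:
    """Mean-absolute-contribution ranking (descending; ties alphabetical).

    Returns a table of (rank, variable, mean_abs_contribution); ``top_k``
    beyond the number of variables is truncated with a warning.
    """
    if contributions.phi.shape[1] == 0:
        raise ValueError("no contributions to rank")
    mean_abs = contributions.phi.abs().mean(axis=0)
    order = sorted(mean_abs.index, key=lambda v: (-mean_abs[v], v))
    if top_k is not None and top_k > len(order):
        logger.warning("top_k=%d exceeds %d variables; truncating",
                       top_k, len(order))
    if top_k is not None:
        order = order[:top_k]
    return pd.DataFrame({
        "rank": np.arange(1, len(order) + 1),
        "variable": order,
        "mean_abs_contribution": [float(mean_abs[v]) for v in order],
    })
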