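"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from woerisk.cohort import CohortTable, VariableSpec


def brute_force_auc(scores, labels) -> float:
    """Pairwise concordance with half-credit for ties — the textbook AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def smoothed_iv(ev, ne, smoothing) -> float:
    """Direct evaluation of the smoothed IV sum for one partition."""
    ev = np.asarray(ev, dtype=float)
    ne = np.asarray(ne, dtype=float)
    B = len(ev)
    pe = (ev + smoothing) / (ev.sum() + smoothing * B)
    pn = (ne + smoothing) / (ne.sum() + smoothing * B)
    return float(np.sum((pe - pn) * np.log(pe / pn)))


def exhaustive_best_iv(cell_ev, cell_ne, smoothing, min_fraction=0.05,
                       max_bins=10) -> float:
    """Maximum smoothed IV over every contiguous partition of the cells."""
    m = len(cell_ev)
    n_obs = float(np.sum(cell_ev) + np.sum(cell_ne))
    best = -math.inf
    for k in range(m):
        for cuts in itertools.combinations(range(1, m), k):
            bounds = [0, *cuts, m]
            if len(bounds) - 1 > max_bins:
                continue
            ge = [float(np.sum(cell_ev[a:b])) for a, b in zip(bounds, bounds[1:])]
            gn = [float(np.sum(cell_ne[a:b])) for a, b in zip(bounds, bounds[1:])]
            if any(e + n < min_fraction * n_obs - 1e-9 for e, n in zip(ge, gn)):
                continue
            best = max(best, smoothed_iv(ge, gn, smoothing))
    return best


@pytest.fixture
def hand_cohort() -> CohortTable:
    """Six subjects, one continuous + one categorical + one binary variable,
    with missing entries, small enough to reason about by hand."""
    values = pd.DataFrame({
        "Score@Baseline": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0],
        "Sport": ["Soccer", "Soccer", "Rowing", np.nan, "Rowing", "Soccer"],
        "Prior Injury": ["yes", "no", "no", "yes", np.nan, "yes"],
    })
    specs = [
        VariableSpec("Score@Baseline", "continuous", "baseline", measure="Score"),
        VariableSpec("Sport", "categorical", "static", tags=("sport",)),
        VariableSpec("Prior Injury", "binary", "static"),
    ]
    return CohortTable(
        subject_ids=[f"S{i}" for i in range(6)],
        values=values,
        outcome=np.array([0, 0, 1, 1, 0, 1]),
        specs=specs,
        group=pd.Series(values["Sport"], name="Sport"),
    )


@pytest.fixture(scope="session")
def desk_cohort():
    """Mid-size synthetic cohort with ground truth, shared across tests."""
    from woerisk.synthetic import GeneratorSpec, generate_cohort

    spec = GeneratorSpec(n_subjects=1200, n_informative=3, n_noise=17,
                         n_categorical=2, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def operating_fixture():
    """39 subjects (24 events / 15 non-events) arranged so the best
    threshold at a 1/15 false-positive budget yields 19 true and 1 false
    positive."""
    scores = np.array([2.0] * 18 + [1.0] + [0.1] * 5 + [1.5] + [0.5] * 14)
    labels = np.array([1] * 24 + [0] * 15)
    return scores, labels
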