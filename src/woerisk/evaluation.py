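"""Discrimination metrics, operating points, group comparison and the
repeated-stratified-split stability experiment.

AUC is pairwise concordance (ties counted 1/2); average precision is the
step-sum of precision over recall increments; the operating point picks the
threshold with the highest sensitivity whose false-positive rate does not
exceed a target.  The split experiment reruns the entire pipeline —
binning, L1 path, AICc selection, L2 refit — on each of ``n_runs``
stratified splits (seed r for run r) and aggregates performance, support
sizes and per-variable selection frequency, with two companion arms: refits
on a fixed support and a no-sport-variable ablation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from . import model as _model
from .binning import BinningParams
from .cohort import CohortTable, stratified_split

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "SplitExperimentReport",
    "OperatingPoint",
    "roc_auc",
    "pr_metrics",
    "operating_point",
    "compare_logit_groups",
    "evaluate",
    "run_split_experiment",
]


@dataclass
class OperatingPoint:
    target_fpr: float
    achieved_fpr: float
    tpr: float
    precision: float
    threshold: float
    no_positives: bool = False


@dataclass
class EvaluationReport:
    auc: float
    average_precision: float
    best_f1: float
    roc_points: pd.DataFrame
    pr_points: pd.DataFrame
    operating_points: list[OperatingPoint]
    group_test: tuple[float, float, str] | None = None
    per_group_auc: dict | None = None


@dataclass
class SplitExperimentReport:
    n_runs: int
    auc_values: list[float]
    auc_mean: float
    auc_sd: float
    support_sizes: list[int]
    selection_frequency: dict[str, float]
    fixed_support: tuple[str, ...] = ()
    fixed_auc_values: list[float] = field(default_factory=list)
    fixed_auc_mean: float = float("nan")
    fixed_auc_sd: float = float("nan")
    nosport_auc_values: list[float] = field(default_factory=list)
    nosport_auc_mean: float = float("nan")
    nosport_auc_sd: float = float("nan")
    per_sport_auc: dict[str, float] | None = None
    failed_runs: list[int] = field(default_factory=list)


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]
            ) -> tuple[float, pd.DataFrame]:
    """AUC (pairwise concordance with half-credit ties) and the ROC curve
    from a threshold sweep; positive prediction means score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, points


def pr_metrics(scores: Sequence[float], labels: Sequence[int]
               ) -> tuple[float, float, pd.DataFrame]:
    """Average precision (step-sum of delta-recall x precision), the best
    achievable F1 over thresholds, and the PR curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    ap = float(average_precision_score(labels, scores))
    precision, recall, thr = precision_recall_curve(labels, scores)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = 2 * precision * recall / (precision + recall)
    f1 = np.nan_to_num(f1, nan=0.0)
    best_f1 = float(f1.max())
    points = pd.DataFrame({
        "recall": recall[:-1], "precision": precision[:-1], "threshold": thr,
    })
    return ap, best_f1, points


def operating_point(scores: Sequence[float], labels: Sequence[int],
                    target_fpr: float) -> OperatingPoint:
    """Threshold maximizing TPR subject to FPR <= target_fpr (ties: the
    smaller achieved FPR), with confusion-matrix metrics at that threshold.

    A target of 0 is always feasible at a threshold above every score; with
    no positive predictions, precision is reported as 1 with a flag.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    if not 0 <= target_fpr <= 1:
        raise ValueError("target_fpr must be in [0, 1]")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    thresholds = np.append(np.unique(scores), np.inf)
    best: OperatingPoint | None = None
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fpr = fp / n_neg
        if fpr > target_fpr + 1e-12:
            continue
        tpr = tp / n_pos
        no_pos = (tp + fp) == 0
        prec = 1.0 if no_pos else tp / (tp + fp)
        cand = OperatingPoint(target_fpr=target_fpr, achieved_fpr=fpr, tpr=tpr,
                              precision=prec, threshold=float(t),
                              no_positives=no_pos)
        if best is None or (cand.tpr, -cand.achieved_fpr) > (best.tpr, -best.achieved_fpr):
            best = cand
    assert best is not None  # threshold +inf always feasible
    return best


def compare_logit_groups(log_odds: Sequence[float], labels: Sequence[int],
                         method: str = "mannwhitney") -> tuple[float, float]:
    """Two-sided comparison of the log-odds distributions of the two
    outcome groups.  Default is the Mann-Whitney U rank test (exact null
    enumeration when both groups are small and there are no ties);
    ``method="welch"`` switches to Welch's t."""
    log_odds = np.asarray(log_odds, dtype=float)
    labels = np.asarray(labels, dtype=int)
    g1 = log_odds[labels == 1]
    g0 = log_odds[labels == 0]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("both groups need at least 2 members")
    if method == "welch":
        res = stats.ttest_ind(g1, g0, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    pooled = np.concatenate([g0, g1])
    no_ties = len(np.unique(pooled)) == len(pooled)
    mw_method = "exact" if (no_ties and len(g0) * len(g1) <= 10000) else "auto"
    res = stats.mannwhitneyu(g1, g0, alternative="two-sided", method=mw_method)
    return float(res.statistic), float(res.pvalue)


def evaluate(scores: Sequence[float], labels: Sequence[int],
             target_fprs: Sequence[float] = (),
             group_logit: Sequence[float] | None = None,
             groups: Sequence | None = None) -> EvaluationReport:
    """Assemble the full discrimination report for one score vector."""
    auc, roc_points = roc_auc(scores, labels)
    ap, best_f1, pr_points = pr_metrics(scores, labels)
    ops = [operating_point(scores, labels, t) for t in target_fprs]
    gt = None
    if group_logit is not None:
        stat, p = compare_logit_groups(group_logit, labels)
        gt = (stat, p, "mannwhitney")
    per_group = None
    if groups is not None:
        per_group = {}
        labels_arr = np.asarray(labels, dtype=int)
        scores_arr = np.asarray(scores, dtype=float)
        for g in pd.unique(pd.Series(list(groups))):
            idx = np.asarray(pd.Series(list(groups)) == g)
            sub = labels_arr[idx]
            if len(np.unique(sub)) < 2:
                per_group[g] = float("nan")
                logger.info("group %r lacks both classes; AUC undefined", g)
            else:
                per_group[g] = float(roc_auc_score(sub, scores_arr[idx]))
    return EvaluationReport(auc=auc, average_precision=ap, best_f1=best_f1,
                            roc_points=roc_points, pr_points=pr_points,
                            operating_points=ops, group_test=gt,
                            per_group_auc=per_group)


def _sport_variables(cohort: CohortTable) -> list[str]:
    out = []
    for s in cohort.specs:
        if "sport" in {t.lower() for t in s.tags} or s.name.lower() in (
                "sport", "sport type", "sport_type"):
            out.append(s.name)
    return out


def _fit_fixed_support(train: CohortTable, support: Sequence[str],
                       params: BinningParams, l2_strength: float):
    """Refit the L2 model for a predetermined variable set on a new train
    split (binning refit on that split; no L1 selection)."""
    from . import binning as _binning
    from sklearn.linear_model import LogisticRegression

    schemes = {}
    for name in support:
        spec = train.spec(name)
        schemes[name] = _binning.fit_binning(
            train.values[name], train.outcome,
            kind=spec.kind, params=params, variable=name)
    X = _model.woe_design(train, schemes, list(support))
    est = LogisticRegression(C=1.0 / l2_strength,
                             solver="lbfgs", max_iter=10000, tol=1e-9)
    est.fit(X.to_numpy(), train.outcome)
    return _model.FittedRiskModel(
        selected=tuple(support), intercept=float(est.intercept_[0]),
        weights=dict(zip(support, est.coef_.ravel().tolist())),
        schemes=schemes, l2_strength=l2_strength,
    )


def run_split_experiment(cohort: CohortTable, n_runs: int = 20,
                         test_fraction: float = 0.2,
                         params: BinningParams | None = None,
                         l2_strength: float = 1.0,
                         grid: Sequence[float] | None = None,
                         sport_ablation: bool = True,
                         per_sport: bool = False) -> SplitExperimentReport:
    """Repeat the full pipeline over ``n_runs`` stratified splits.

    Run r uses split seed r; rejected draws are redrawn within the run and
    never consume another run's seed.  Companion arms: (a) fixed-support
    refits using run 0's selected set, (b) the pipeline without
    sport-informative variables.  A failing run is excluded and flagged.
    """
    params = params or BinningParams()
    aucs, support_sizes, supports = [], [], []
    fixed_aucs, nosport_aucs = [], []
    failed = []
    fixed_support: tuple[str, ...] = ()
    sport_vars = _sport_variables(cohort) if sport_ablation else []
    sport_scores: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    for r in range(n_runs):
        try:
            split = stratified_split(cohort, test_fraction, seed=r)
            fitted = _model.fit_pipeline(split.train, params=params, grid=grid,
                                         l2_strength=l2_strength)
            pred = _model.predict(fitted, split.test)
            auc, _ = roc_auc(pred["log_odds"], split.test.outcome)
        except Exception as exc:  # noqa: BLE001 - runs are isolated
            logger.warning("split run %d failed: %s", r, exc)
            failed.append(r)
            continue
        aucs.append(auc)
        supports.append(set(fitted.selected))
        support_sizes.append(len(fitted.selected))
        if r == 0:
            fixed_support = fitted.selected
        if per_sport and split.test.group is not None:
            sport_scores.append((
                pred["log_odds"].to_numpy(), split.test.outcome,
                split.test.group.to_numpy(),
            ))
        if fixed_support:
            fm = _fit_fixed_support(split.train, fixed_support, params,
                                    l2_strength)
            fpred = _model.predict(fm, split.test)
            fauc, _ = roc_auc(fpred["log_odds"], split.test.outcome)
            fixed_aucs.append(fauc)
        if sport_vars:
            reduced_train = split.train.drop_variables(sport_vars)
            reduced_test = split.test.drop_variables(sport_vars)
            nm = _model.fit_pipeline(reduced_train, params=params, grid=grid,
                                     l2_strength=l2_strength)
            npred = _model.predict(nm, reduced_test)
            nauc, _ = roc_auc(npred["log_odds"], reduced_test.outcome)
            nosport_aucs.append(nauc)

    all_vars = [s.name for s in cohort.specs]
    n_ok = len(aucs)
    freq = {
        v: (sum(v in s for s in supports) / n_ok if n_ok else 0.0)
        for v in all_vars
    }
    per_sport_auc = None
    if per_sport and sport_scores:
        per_sport_auc = {}
        lo = np.concatenate([s[0] for s in sport_scores])
        yy = np.concatenate([s[1] for s in sport_scores])
        gg = np.concatenate([s[2] for s in sport_scores])
        for g in pd.unique(gg):
            idx = gg == g
            if len(np.unique(yy[idx])) < 2:
                per_sport_auc[g] = float("nan")
            else:
                per_sport_auc[g] = float(roc_auc_score(yy[idx], lo[idx]))

    def _mean(v):
        return float(np.mean(v)) if v else float("nan")

    def _sd(v):
        return float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")

    return SplitExperimentReport(
        n_runs=n_runs,
        auc_values=aucs, auc_mean=_mean(aucs), auc_sd=_sd(aucs),
        support_sizes=support_sizes,
        selection_frequency=freq,
        fixed_support=fixed_support,
        fixed_auc_values=fixed_aucs,
        fixed_auc_mean=_mean(fixed_aucs), fixed_auc_sd=_sd(fixed_aucs),
        nosport_auc_values=nosport_aucs,
        nosport_auc_mean=_mean(nosport_aucs), nosport_auc_sd=_sd(nosport_aucs),
        per_sport_auc=per_sport_auc,
        failed_runs=failed,
    )
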