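"""L1-path variable selection with AICc model choice and L2-regularized
refit on Weight-of-Evidence features.

The working model is logistic regression on WoE-coded variables,

    log-odds(x) = w0 + sum_i w_i * WoE_i(x_i),

fit along a descending grid of L1 penalties so coefficients enter one by
one; the corrected Akaike Information Criterion

    AICc = 2*NLL + 2k + 2k(k+1)/(n - k - 1)

picks the path point, and the retained support is refit with a mild L2
penalty to tame collinearity among selected WoE features.

Because the WoE coding of each variable is itself estimated from the
training labels (one log-ratio per bin), a selected variable costs more
than one parameter.  By default k therefore counts the *effective* degrees
of freedom, 1 + sum over the support of that variable's bin count
(``complexity="effective"``); ``complexity="support"`` gives the plain
lasso-IC accounting k = nonzero + 1.  With the plain accounting the
criterion cannot see the bin parameters and retains essentially every
variable whose supervised binning manufactured in-sample evidence, which
measurably hurts held-out discrimination on synthetic cohorts with known
ground truth.

The penalty is parameterized per sample: the L1 objective is mean logistic
loss + lambda * ||w||_1 (intercept unpenalized), so the analytic null
threshold is lambda_max = max_j |x_j'(y - ybar)| / n.

A raw-variable benchmark (mean imputation, one-hot, standardization, plain
ridge-stabilized logistic fit) is included for comparison.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import binning as _binning
from .binning import BinningParams, BinningScheme
from .cohort import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "PathPoint",
    "FittedRiskModel",
    "woe_design",
    "default_grid",
    "lambda_max",
    "l1_path",
    "aicc",
    "select_and_refit",
    "fit_pipeline",
    "predict",
    "BaselineBenchmark",
    "fit_baseline_benchmark",
    "save_model",
    "load_model",
]

ZERO_SNAP = 1e-8


@dataclass
class PathPoint:
    """One point of the L1 regularization path.

    ``k`` is the parameter count charged to AICc: intercept plus, for each
    nonzero coefficient, either 1 (plain lasso-IC accounting) or the
    variable's effective degrees of freedom when a ``dof`` map was given.
    """

    lam: float
    intercept: float
    coef: np.ndarray
    names: tuple[str, ...]
    nll: float
    k: int
    aicc: float
    converged: bool = True

    @property
    def support(self) -> tuple[str, ...]:
        return tuple(n for n, c in zip(self.names, self.coef) if c != 0.0)


@dataclass
class FittedRiskModel:
    """Selected variables, refit weights, and the audit trail."""

    selected: tuple[str, ...]
    intercept: float
    weights: dict[str, float]
    schemes: dict[str, BinningScheme]
    l2_strength: float
    path: list[PathPoint] = field(default_factory=list)
    chosen_lambda: float | None = None


def woe_design(cohort: CohortTable, schemes: Mapping[str, BinningScheme],
               names: Sequence[str] | None = None) -> pd.DataFrame:
    """WoE-transform every (requested) variable of a cohort into a fully
    numeric design matrix with no missing entries."""
    names = list(names) if names is not None else [
        s.name for s in cohort.specs if s.name in schemes
    ]
    cols = {}
    for name in names:
        if name not in cohort.values.columns:
            raise KeyError(f"variable {name!r} absent from cohort")
        cols[name] = _binning.transform(schemes[name], cohort.values[name])
    return pd.DataFrame(cols)


def _nll(intercept: float, coef: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    z = intercept + X @ coef
    # log(1 + exp(-|z|)) formulation for numerical stability
    return float(np.sum(np.logaddexp(0.0, -z * (2 * y - 1))))


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest per-sample L1 penalty at which all coefficients are zero."""
    ybar = y.mean()
    return float(np.max(np.abs(X.T @ (y - ybar))) / len(y))


def default_grid(X: np.ndarray, y: np.ndarray, n_points: int = 100,
                 ratio: float = 1e-4) -> np.ndarray:
    lmax = lambda_max(X, y)
    return np.geomspace(lmax, ratio * lmax, n_points)


def aicc(nll: float, k: int, n: int) -> float:
    """Corrected AIC: 2*NLL + 2k + 2k(k+1)/(n-k-1).  Requires n > k+1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return 2.0 * nll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def l1_path(X, y, grid: Sequence[float] | None = None,
            dof: Mapping[str, int] | None = None,
            tol: float = 1e-7, max_iter: int = 10000) -> list[PathPoint]:
    """Fit the L1-penalized logistic path over a descending penalty grid.

    ``dof`` maps variable names to their effective parameter count for the
    AICc complexity term (defaults to 1 each, the plain lasso-IC
    accounting); pass each variable's bin count to charge the supervised
    binning's degrees of freedom.  Coefficients with magnitude below
    ``ZERO_SNAP`` are snapped to exactly zero.  A non-converged grid point
    is flagged and excluded from model selection rather than aborting the
    path.
    """
    names = tuple(X.columns) if isinstance(X, pd.DataFrame) else tuple(
        f"x{j}" for j in range(np.asarray(X).shape[1]))
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes")
    n = len(y)
    if grid is None:
        grid = default_grid(Xa, y)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) > 0):
        raise ValueError("penalty grid must be descending")

    est = LogisticRegression(
        l1_ratio=1.0, solver="saga", warm_start=True, fit_intercept=True,
        tol=tol, max_iter=max_iter, random_state=0,
    )
    points: list[PathPoint] = []
    for lam in grid:
        est.C = 1.0 / (n * lam) if lam > 0 else 1e15  # lam 0: unpenalized fit
        converged = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            est.fit(Xa, y)
            if any("onverge" in str(w.message) for w in caught):
                converged = False
                logger.warning("path point lambda=%.3g did not converge; skipped", lam)
        coef = est.coef_.ravel().copy()
        coef[np.abs(coef) < ZERO_SNAP] = 0.0
        intercept = float(est.intercept_[0])
        support = [nm for nm, c in zip(names, coef) if c != 0.0]
        k = 1 + (sum(dof.get(nm, 1) for nm in support) if dof else len(support))
        nll = _nll(intercept, coef, Xa, y)
        point_aicc = aicc(nll, k, n) if n > k + 1 else math.inf
        points.append(PathPoint(lam=float(lam), intercept=intercept, coef=coef,
                                names=names, nll=nll, k=k, aicc=point_aicc,
                                converged=converged))
    return points


def select_and_refit(path: Sequence[PathPoint], X, y,
                     schemes: Mapping[str, BinningScheme] | None = None,
                     l2_strength: float = 1.0) -> FittedRiskModel:
    """Pick the converged path point with minimal AICc (ties: fewer
    variables, then larger penalty) and refit its support with an L2
    penalty of strength ``l2_strength`` (objective: sum logistic loss +
    l2_strength/2 * ||w||^2)."""
    usable = [p for p in path if p.converged and math.isfinite(p.aicc)]
    if not usable:
        raise ValueError("no converged path point with finite AICc")
    best = min(usable, key=lambda p: (p.aicc, p.k, -p.lam))
    selected = best.support

    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
        np.asarray(X, dtype=float), columns=list(best.names))
    y = np.asarray(y, dtype=float)

    if not selected:
        logger.warning("empty support selected; returning intercept-only model")
        prior = y.mean()
        return FittedRiskModel(
            selected=(), intercept=math.log(prior / (1 - prior)), weights={},
            schemes={}, l2_strength=l2_strength, path=list(path),
            chosen_lambda=best.lam,
        )

    Xs = Xdf[list(selected)].to_numpy(dtype=float)
    est = LogisticRegression(C=1.0 / l2_strength, solver="lbfgs",
                             max_iter=10000, tol=1e-9)
    est.fit(Xs, y)
    weights = dict(zip(selected, est.coef_.ravel().tolist()))
    schemes = dict(schemes or {})
    return FittedRiskModel(
        selected=tuple(selected),
        intercept=float(est.intercept_[0]),
        weights=weights,
        schemes={k: v for k, v in schemes.items() if k in selected} or schemes,
        l2_strength=l2_strength,
        path=list(path),
        chosen_lambda=best.lam,
    )


def fit_pipeline(train: CohortTable, params: BinningParams | None = None,
                 grid: Sequence[float] | None = None,
                 l2_strength: float = 1.0,
                 complexity: str = "effective") -> FittedRiskModel:
    """Full training pipeline: supervised binning -> WoE design -> L1 path
    -> AICc selection -> L2 refit.  Uses only the training cohort.

    ``complexity`` chooses the AICc parameter accounting: "effective"
    charges each selected variable its bin count (the binning was estimated
    on the same labels), "support" charges 1 per selected variable.
    """
    if complexity not in ("effective", "support"):
        raise ValueError("complexity must be 'effective' or 'support'")
    schemes = _binning.fit_all(train, params)
    X = woe_design(train, schemes)
    dof = ({v: len(schemes[v].bins) for v in X.columns}
           if complexity == "effective" else None)
    path = l1_path(X, train.outcome, grid=grid, dof=dof)
    return select_and_refit(path, X, train.outcome, schemes=schemes,
                            l2_strength=l2_strength)


def predict(model: FittedRiskModel, cohort: CohortTable) -> pd.DataFrame:
    """Per-subject (log_odds, probability); missing inputs flow through each
    variable's missing bin, so output is never missing."""
    log_odds = np.full(cohort.n, model.intercept, dtype=float)
    for name in model.selected:
        if name not in cohort.values.columns:
            raise KeyError(f"selected variable {name!r} absent from cohort")
        woe = _binning.transform(model.schemes[name], cohort.values[name])
        log_odds += model.weights[name] * woe
    prob = 1.0 / (1.0 + np.exp(-log_odds))
    return pd.DataFrame({
        "subject_id": cohort.subject_ids,
        "log_odds": log_odds,
        "probability": prob,
    })


# ---------------------------------------------------------------------------
# raw-variable benchmark

@dataclass
class BaselineBenchmark:
    """Mean-impute + standardize + one-hot benchmark logistic model."""

    continuous: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    categorical_levels: dict[str, list[str]]
    intercept: float
    weights: dict[str, float]

    def design(self, cohort: CohortTable) -> pd.DataFrame:
        cols = {}
        for name in self.continuous:
            v = pd.to_numeric(cohort.values[name]).to_numpy(dtype=float)
            v = np.where(np.isnan(v), self.means[name], v)
            cols[name] = (v - self.means[name]) / self.sds[name]
        for name, levels in self.categorical_levels.items():
            raw = cohort.values[name].astype(object)
            for lvl in levels:
                cols[f"{name}={lvl}"] = (
                    (raw.notna()) & (raw.astype(str) == lvl)
                ).to_numpy(dtype=float)
        return pd.DataFrame(cols)

    def predict(self, cohort: CohortTable) -> pd.DataFrame:
        D = self.design(cohort)
        log_odds = self.intercept + sum(
            self.weights[c] * D[c].to_numpy() for c in D.columns
        )
        prob = 1.0 / (1.0 + np.exp(-log_odds))
        return pd.DataFrame({
            "subject_id": cohort.subject_ids,
            "log_odds": log_odds,
            "probability": prob,
        })


def fit_baseline_benchmark(cohort: CohortTable,
                           ridge: float = 1e-3) -> BaselineBenchmark:
    """Benchmark on the original variables: continuous columns are
    mean-imputed then standardized with training statistics; categorical
    columns are one-hot encoded over training levels (unseen-at-test
    levels map to an all-zero row); a plain logistic model is fit with a
    small ridge penalty for stability."""
    continuous, means, sds = [], {}, {}
    cat_levels: dict[str, list[str]] = {}
    for s in cohort.specs:
        if s.kind == "continuous":
            v = pd.to_numeric(cohort.values[s.name]).to_numpy(dtype=float)
            obs = v[~np.isnan(v)]
            if obs.size == 0 or np.std(obs) == 0:
                logger.warning("zero-variance column %r dropped from benchmark",
                               s.name)
                continue
            mu = float(obs.mean())
            filled = np.where(np.isnan(v), mu, v)
            sd = float(filled.std(ddof=0))
            if sd == 0:
                logger.warning("zero-variance column %r dropped from benchmark",
                               s.name)
                continue
            continuous.append(s.name)
            means[s.name], sds[s.name] = mu, sd
        else:
            levels = sorted(cohort.values[s.name].dropna().astype(str).unique())
            if len(levels) < 2:
                logger.warning("constant column %r dropped from benchmark", s.name)
                continue
            cat_levels[s.name] = levels

    bench = BaselineBenchmark(continuous=continuous, means=means, sds=sds,
                              categorical_levels=cat_levels,
                              intercept=0.0, weights={})
    D = bench.design(cohort)
    est = LogisticRegression(C=1.0 / ridge, solver="lbfgs",
                             max_iter=10000, tol=1e-8)
    est.fit(D.to_numpy(), cohort.outcome)
    bench.intercept = float(est.intercept_[0])
    bench.weights = dict(zip(D.columns, est.coef_.ravel().tolist()))
    return bench


# ---------------------------------------------------------------------------
# serialization

def save_model(model: FittedRiskModel, path) -> None:
    payload = {
        "selected": list(model.selected),
        "intercept": model.intercept,
        "weights": model.weights,
        "l2_strength": model.l2_strength,
        "chosen_lambda": model.chosen_lambda,
        "schemes": json.loads(_schemes_json(model.schemes)),
        "path": [
            {
                "lam": p.lam, "intercept": p.intercept,
                "coef": list(p.coef), "names": list(p.names),
                "nll": p.nll, "k": p.k,
                "aicc": None if not math.isfinite(p.aicc) else p.aicc,
                "converged": p.converged,
            }
            for p in model.path
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _schemes_json(schemes: Mapping[str, BinningScheme]) -> str:
    from .binning import _bin_to_dict
    payload = {
        name: {
            "variable": s.variable, "kind": s.kind, "iv": s.iv,
            "smoothing": s.smoothing, "fitted_on": s.fitted_on,
            "bins": [_bin_to_dict(b) for b in s.bins],
        }
        for name, s in schemes.items()
    }
    return json.dumps(payload)


def load_model(path) -> FittedRiskModel:
    from .binning import _bin_from_dict
    with open(path) as fh:
        payload = json.load(fh)
    schemes = {
        name: BinningScheme(
            variable=d["variable"], kind=d["kind"],
            bins=[_bin_from_dict(b) for b in d["bins"]],
            iv=d["iv"], smoothing=d["smoothing"], fitted_on=d["fitted_on"],
        )
        for name, d in payload["schemes"].items()
    }
    points = [
        PathPoint(
            lam=p["lam"], intercept=p["intercept"],
            coef=np.array(p["coef"], dtype=float), names=tuple(p["names"]),
            nll=p["nll"], k=p["k"],
            aicc=math.inf if p["aicc"] is None else p["aicc"],
            converged=p["converged"],
        )
        for p in payload["path"]
    ]
    return FittedRiskModel(
        selected=tuple(payload["selected"]),
        intercept=payload["intercept"],
        weights=dict(payload["weights"]),
        schemes=schemes,
        l2_strength=payload["l2_strength"],
        path=points,
        chosen_lambda=payload["chosen_lambda"],
    )
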