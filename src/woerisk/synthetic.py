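"""Synthetic concussion-cohort generator with known ground truth.

Emulates the statistical structure the risk-modelling pipeline assumes:
mixed continuous/categorical/binary variables over four assessment
timepoints, correlated variable blocks, nonlinear (piecewise-constant)
threshold effects on the log-odds of injury, sport-varying base rates, and
heavy missingness.

The generative order matters: the missingness mask is drawn first
(completely at random), and each subject's latent log-odds is computed from
the *observed* entries — a masked informative value contributes the
configured missing-shift (0 by default, so plain MCAR; nonzero in the
informative-missingness mode, which makes the missing bin itself
predictive).  The outcome is then Bernoulli of the logistic of that latent
score.  ``GroundTruth.bayes_auc`` is therefore the discrimination ceiling
attainable by any model that sees the masked table, which is exactly what
parameter-recovery tests compare a fitted pipeline against.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableSpec, TIMEPOINT_LABELS

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdEffect",
    "GeneratorSpec",
    "GroundTruth",
    "generate_cohort",
    "estimate_bayes_auc",
    "DEFAULT_SPORT_RATES",
    "DEFAULT_SPORT_WEIGHTS",
]

# Per-sport cohort sizes and injury rates of a representative collegiate
# sample (sexes pooled); used as the default sport mixture.
_SPORT_TABLE = {
    "Baseball/Softball": (19, 0.579),
    "Basketball": (17, 0.765),
    "Cheer": (8, 0.500),
    "Field Hockey": (9, 0.889),
    "Football": (28, 0.643),
    "Lacrosse": (34, 0.588),
    "Rowing": (11, 0.455),
    "Soccer": (25, 0.640),
    "Swimming and Diving": (12, 0.250),
    "Tennis": (4, 0.500),
    "Track and Field": (11, 0.818),
    "Volleyball": (16, 0.688),
}
DEFAULT_SPORT_RATES = {k: r for k, (n, r) in _SPORT_TABLE.items()}
DEFAULT_SPORT_WEIGHTS = {k: n for k, (n, r) in _SPORT_TABLE.items()}

_TP_CYCLE = ("baseline", "acute", "asymptomatic", "rtp")


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return math.log(p / (1 - p))


@dataclass(frozen=True)
class ThresholdEffect:
    """Piecewise-constant log-odds effect of one continuous variable:
    ``shifts[i]`` applies on the i-th segment delimited by ``cutpoints``."""

    variable: str
    cutpoints: tuple[float, ...]
    shifts: tuple[float, ...]

    def __post_init__(self):
        if len(self.shifts) != len(self.cutpoints) + 1:
            raise ValueError("need one shift per segment (len(cutpoints)+1)")

    def shift(self, x: float) -> float:
        return self.shifts[int(np.searchsorted(self.cutpoints, x, side="right"))]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic cohort.

    Continuous variables come in blocks of 5 sharing a latent factor with
    loading ``sqrt(block_correlation)``; they are scaled to mean 10.5 and sd
    2 so the default threshold cutpoints {9, 12} sit inside the bulk of the
    distribution.  The first categorical variable is Sport, carrying the
    default collegiate mixture and per-sport injury rates.
    """

    n_subjects: int = 500
    n_informative: int = 5
    n_noise: int = 42
    n_categorical: int = 3
    block_correlation: float = 0.3
    missing_rate: float = 0.35
    threshold_effects: tuple[ThresholdEffect, ...] | None = None
    sport_rates: Mapping[str, float] | None = None
    sport_weights: Mapping[str, float] | None = None
    base_log_odds: float = _logit(120 / 194)
    missing_shift: float = 0.0
    effect_size: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if self.n_informative + self.n_noise + self.n_categorical < 1:
            raise ValueError("at least one variable required")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must be in [0, 1)")
        rates = self.sport_rates if self.sport_rates is not None else DEFAULT_SPORT_RATES
        if any(not 0 <= r <= 1 for r in rates.values()):
            raise ValueError("sport rates must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator knows: which variables carry signal, each
    subject's true log-odds, and the attainable (Bayes) AUC."""

    informative_set: tuple[str, ...]
    threshold_variables: tuple[str, ...]
    latent_score: np.ndarray
    bayes_auc: float
    effects: tuple[ThresholdEffect, ...] = ()


_BLOCK = 5


def _continuous_names(n_cont: int) -> list[tuple[str, str, str]]:
    """(column name, measure, timepoint) for each continuous variable.

    Measures repeat across the four timepoints so difference features have
    baseline counterparts: variable j is measure j//4 at timepoint j%4.
    """
    out = []
    for j in range(n_cont):
        measure = f"M{j // 4:02d}"
        tp = _TP_CYCLE[j % 4]
        out.append((f"{measure}@{TIMEPOINT_LABELS[tp]}", measure, tp))
    return out


def _default_effects(spec: GeneratorSpec, cont_names: list[str]) -> tuple[ThresholdEffect, ...]:
    n_cont = len(cont_names)
    idx = [b * _BLOCK for b in range(spec.n_informative) if b * _BLOCK < n_cont]
    while len(idx) < min(spec.n_informative, n_cont):
        nxt = max(idx, default=-1) + 1
        if nxt >= n_cont:
            break
        idx.append(nxt)
    a = spec.effect_size
    effects = []
    for r, j in enumerate(idx):
        sign = 1.0 if r % 2 == 0 else -1.0
        effects.append(
            ThresholdEffect(cont_names[j], (9.0, 12.0), (sign * a, 0.0, -sign * a))
        )
    return tuple(effects)


def generate_cohort(
    spec: GeneratorSpec, max_retries: int = 5
) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort and its ground truth under ``spec.seed``."""
    base = spec.base_log_odds
    for attempt in range(max_retries + 1):
        cohort, truth = _generate_once(spec, base)
        if 0 < cohort.outcome.sum() < cohort.n:
            if attempt:
                logger.info("cohort regenerated %d time(s) with shifted base log-odds",
                            attempt)
            return cohort, truth
        # single-class draw: nudge the base rate toward the missing class
        base += -1.0 if cohort.outcome.sum() == cohort.n else 1.0
    raise RuntimeError("could not generate a two-class cohort; check the spec")


def _generate_once(spec: GeneratorSpec, base: float) -> tuple[CohortTable, GroundTruth]:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    n_cont = spec.n_informative + spec.n_noise
    cont_meta = _continuous_names(n_cont)
    cont_names = [c[0] for c in cont_meta]

    # correlated blocks: shared factor per block of 5
    rho = spec.block_correlation
    n_blocks = max(1, math.ceil(n_cont / _BLOCK))
    factors = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, n_cont))
    z = np.empty((n, n_cont))
    for j in range(n_cont):
        b = j // _BLOCK
        z[:, j] = math.sqrt(rho) * factors[:, b] + math.sqrt(1 - rho) * eps[:, j]
    X = 10.5 + 2.0 * z

    effects = spec.threshold_effects
    if effects is None:
        effects = _default_effects(spec, cont_names)
    effect_by_name = {e.variable: e for e in effects}
    unknown = set(effect_by_name) - set(cont_names)
    if unknown:
        raise ValueError(f"threshold effects name unknown variables: {sorted(unknown)}")

    # categorical variables: Sport first, then generic noise factors
    cat_cols: dict[str, np.ndarray] = {}
    cat_specs: list[VariableSpec] = []
    sport = None
    sport_shift = np.zeros(n)
    if spec.n_categorical >= 1:
        rates = dict(spec.sport_rates if spec.sport_rates is not None
                     else DEFAULT_SPORT_RATES)
        weights = dict(spec.sport_weights if spec.sport_weights is not None
                       else {k: DEFAULT_SPORT_WEIGHTS.get(k, 1.0) for k in rates})
        levels = sorted(rates)
        probs = np.array([weights[l] for l in levels], dtype=float)
        probs /= probs.sum()
        sport = rng.choice(levels, size=n, p=probs)
        shift_map = {l: _logit(rates[l]) - base for l in levels}
        sport_shift = np.array([shift_map[s] for s in sport])
        cat_cols["Sport"] = sport
        cat_specs.append(VariableSpec("Sport", "categorical", "static",
                                      tags=("sport",)))
    for i in range(1, spec.n_categorical):
        name = f"C{i:02d}"
        if i % 2 == 1:
            lv = np.array(["A", "B", "C", "D"])
            kind = "categorical"
        else:
            lv = np.array(["no", "yes"])
            kind = "binary"
        cat_cols[name] = rng.choice(lv, size=n)
        cat_specs.append(VariableSpec(name, kind, "static"))

    # MCAR mask over every predictive column
    all_names = cont_names + list(cat_cols)
    mask = rng.random((n, len(all_names))) < spec.missing_rate

    # latent log-odds from OBSERVED entries only
    latent = np.full(n, base)
    if sport is not None:
        j_sport = all_names.index("Sport")
        latent += np.where(mask[:, j_sport], 0.0, sport_shift)
    for name, eff in effect_by_name.items():
        j = cont_names.index(name)
        shifts = np.array([eff.shift(v) for v in X[:, j]])
        latent += np.where(mask[:, j], spec.missing_shift, shifts)

    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-latent))).astype(int)

    values = pd.DataFrame(X, columns=cont_names)
    for name, col in cat_cols.items():
        values[name] = col
    for j, name in enumerate(all_names):
        values.loc[mask[:, j], name] = np.nan

    specs = [
        VariableSpec(name, "continuous", tp, measure=measure)
        for name, measure, tp in cont_meta
    ] + cat_specs
    cohort = CohortTable(
        subject_ids=[f"S{i:04d}" for i in range(n)],
        values=values,
        outcome=y,
        specs=specs,
        group=pd.Series(sport, name="Sport") if sport is not None else None,
    )
    informative = tuple(effect_by_name) + (("Sport",) if sport is not None else ())
    truth = GroundTruth(
        informative_set=informative,
        threshold_variables=tuple(effect_by_name),
        latent_score=latent,
        bayes_auc=estimate_bayes_auc_safe(latent, y),
        effects=tuple(effects),
    )
    return cohort, truth


def estimate_bayes_auc(latent_score: Sequence[float], outcome: Sequence[int]) -> float:
    """Concordance of the true log-odds against the drawn outcome — the
    discrimination ceiling for the generated cohort."""
    from .evaluation import roc_auc

    auc, _ = roc_auc(latent_score, outcome)
    return auc


def estimate_bayes_auc_safe(latent, y) -> float:
    if len(set(np.asarray(y).tolist())) < 2:
        return float("nan")
    return estimate_bayes_auc(latent, y)


def write_cohort(cohort: CohortTable, truth: GroundTruth | None,
                 table_path, dictionary_path, truth_path=None) -> None:
    """Emit a cohort as delimited text + dictionary config (+ ground-truth
    sidecar), in the exact format ``load_cohort`` reads back."""
    import yaml

    df = cohort.values.copy()
    df.insert(0, "subject_id", cohort.subject_ids)
    df["MSK Injury"] = cohort.outcome
    df.to_csv(table_path, index=False)
    cfg = {
        "outcome": "MSK Injury",
        "subject_id": "subject_id",
        "group": "Sport" if "Sport" in cohort.values.columns else None,
        "missing_values": ["", "NA", "NaN"],
        "variables": {
            s.name: {
                "kind": s.kind,
                "timepoint": s.timepoint,
                **({"measure": s.measure} if s.measure else {}),
                **({"tags": list(s.tags)} if s.tags else {}),
            }
            for s in cohort.specs
        },
    }
    with open(dictionary_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    if truth is not None and truth_path is not None:
        payload = {
            "informative_set": list(truth.informative_set),
            "threshold_variables": list(truth.threshold_variables),
            "bayes_auc": truth.bayes_auc,
            "latent_score": [float(v) for v in truth.latent_score],
        }
        with open(truth_path, "w") as fh:
            json.dump(payload, fh, indent=1)
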