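"""Supervised optimal binning and Weight-of-Evidence (WoE) transformation.

Each variable is discretized into bins chosen to maximize Information Value
(IV) on the training set, and every bin is assigned the natural-log ratio of
class-conditional frequencies

    WoE_bin = ln[ P(bin | event) / P(bin | non-event) ],

with a pseudo-count ``smoothing`` added per class per bin so the ratio stays
finite when a bin holds a single class.  Positive WoE is evidence *for* the
event.  Missing values always form their own bin when present in training,
so "imputation" is just another evidence lookup; the transform therefore
never emits missing values.

Continuous variables are pre-binned on quantiles and then merged by exact
dynamic programming over contiguous partitions; categorical variables are
ordered by event rate and grouped by the same DP.  Monotonicity of WoE
across bins is deliberately not enforced.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Bin",
    "BinningParams",
    "BinningScheme",
    "woe_value",
    "information_value",
    "fit_binning",
    "transform",
    "fit_all",
    "iv_manifest",
    "save_schemes",
    "load_schemes",
]


@dataclass(frozen=True)
class Bin:
    """One bin: a half-open interval [lo, hi), a set of category levels,
    or the distinguished missing bin."""

    n_event: int
    n_nonevent: int
    woe: float
    lo: float | None = None           # continuous bins only; -inf allowed
    hi: float | None = None           # continuous bins only; +inf allowed
    levels: tuple[str, ...] | None = None  # categorical bins only
    is_missing: bool = False

    @property
    def count(self) -> int:
        return self.n_event + self.n_nonevent


@dataclass(frozen=True)
class BinningParams:
    """Knobs of the optimal-binning search.

    min_bin_fraction: smallest admissible share of the non-missing
        training sample per (non-missing) bin.
    max_bins: upper bound on the number of non-missing bins.
    pre_bins: number of quantile cells used as DP atoms for continuous
        variables.
    smoothing: pseudo-count added per class per bin in every frequency.
    """

    min_bin_fraction: float = 0.05
    max_bins: int = 10
    pre_bins: int = 20
    smoothing: float = 0.5


@dataclass
class BinningScheme:
    """Fitted binning for one variable: ordered bins (missing bin last,
    when present), total IV, and the smoothing used."""

    variable: str
    kind: str  # "continuous" or "categorical"
    bins: list[Bin]
    iv: float
    smoothing: float
    fitted_on: str = ""

    @property
    def n_event_total(self) -> int:
        return sum(b.n_event for b in self.bins)

    @property
    def n_nonevent_total(self) -> int:
        return sum(b.n_nonevent for b in self.bins)

    @property
    def missing_bin(self) -> Bin | None:
        for b in self.bins:
            if b.is_missing:
                return b
        return None


def woe_value(
    n_event_bin: float,
    n_nonevent_bin: float,
    n_event_total: float,
    n_nonevent_total: float,
    smoothing: float = 0.5,
    n_bins: int = 1,
) -> float:
    """Smoothed weight of evidence of a single bin.

    Returns ``ln[((e+s)/(E+s*B)) / ((ne+s)/(NE+s*B))]`` where ``B`` is the
    total number of bins in the scheme.  With ``smoothing == 0`` a zero
    count in either class is an error rather than an infinite value.
    """
    if n_event_total <= 0 or n_nonevent_total <= 0:
        raise ValueError("class totals must be positive")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    if n_event_bin > n_event_total or n_nonevent_bin > n_nonevent_total:
        raise ValueError("bin counts exceed totals")
    if smoothing == 0 and (n_event_bin == 0 or n_nonevent_bin == 0):
        raise ValueError(
            "zero count in a bin with smoothing 0; use a positive smoothing"
        )
    p_event = (n_event_bin + smoothing) / (n_event_total + smoothing * n_bins)
    p_nonevent = (n_nonevent_bin + smoothing) / (n_nonevent_total + smoothing * n_bins)
    return math.log(p_event / p_nonevent)


def _smoothed_proportions(
    ev: np.ndarray, ne: np.ndarray, smoothing: float
) -> tuple[np.ndarray, np.ndarray]:
    n_bins = len(ev)
    p_e = (ev + smoothing) / (ev.sum() + smoothing * n_bins)
    p_n = (ne + smoothing) / (ne.sum() + smoothing * n_bins)
    return p_e, p_n


def information_value(scheme: BinningScheme) -> float:
    """Total IV = sum over bins of (p_event - p_nonevent) * WoE, with the
    same smoothing used for the WoE values themselves.  Non-negative."""
    ev = np.array([b.n_event for b in scheme.bins], dtype=float)
    ne = np.array([b.n_nonevent for b in scheme.bins], dtype=float)
    p_e, p_n = _smoothed_proportions(ev, ne, scheme.smoothing)
    return float(np.sum((p_e - p_n) * np.log(p_e / p_n)))


def _iv_of_partition(
    ev: np.ndarray, ne: np.ndarray, smoothing: float
) -> float:
    p_e, p_n = _smoothed_proportions(ev, ne, smoothing)
    return float(np.sum((p_e - p_n) * np.log(p_e / p_n)))


def _best_contiguous_partition(
    cell_ev: np.ndarray,
    cell_ne: np.ndarray,
    extra_ev: float,
    extra_ne: float,
    has_missing: bool,
    params: BinningParams,
) -> list[int]:
    """Exact DP over contiguous partitions of pre-bin cells maximizing IV.

    Because the smoothing denominators depend on the total number of bins B,
    the DP is run once per candidate bin count k (with B = k + missing bin)
    and the best k wins.  Returns the list of cut indices (cell boundaries),
    i.e. a partition into len(cuts)+1 groups of cells.
    """
    m = len(cell_ev)
    n_obs = float(cell_ev.sum() + cell_ne.sum())
    e_tot = float(cell_ev.sum())
    n_tot = float(cell_ne.sum())
    min_count = params.min_bin_fraction * n_obs
    # prefix sums for O(1) group counts
    pe = np.concatenate([[0.0], np.cumsum(cell_ev)])
    pn = np.concatenate([[0.0], np.cumsum(cell_ne)])

    best_iv = -math.inf
    best_cuts: list[int] = []
    s = params.smoothing
    for k in range(1, min(params.max_bins, m) + 1):
        n_bins = k + (1 if has_missing else 0)
        denom_e = e_tot + extra_ev + s * n_bins
        denom_n = n_tot + extra_ne + s * n_bins

        def contrib(a: int, b: int) -> float:
            """IV contribution of one bin made of cells a..b-1."""
            ge = pe[b] - pe[a]
            gn = pn[b] - pn[a]
            if ge + gn < min_count - 1e-9:
                return -math.inf
            q_e = (ge + s) / denom_e
            q_n = (gn + s) / denom_n
            return (q_e - q_n) * math.log(q_e / q_n)

        NEG = -math.inf
        # dp[j][i]: best IV over first i cells split into j groups
        dp = np.full((k + 1, m + 1), NEG)
        back = np.zeros((k + 1, m + 1), dtype=int)
        dp[0][0] = 0.0
        for j in range(1, k + 1):
            for i in range(j, m + 1):
                for a in range(j - 1, i):
                    if dp[j - 1][a] == NEG:
                        continue
                    c = contrib(a, i)
                    if c == NEG:
                        continue
                    cand = dp[j - 1][a] + c
                    if cand > dp[j][i]:
                        dp[j][i] = cand
                        back[j][i] = a
        if dp[k][m] == NEG:
            continue
        total = dp[k][m]
        if has_missing:
            q_e = (extra_ev + s) / denom_e
            q_n = (extra_ne + s) / denom_n
            total += (q_e - q_n) * math.log(q_e / q_n)
        # prefer fewer bins on (numerical) ties
        if total > best_iv + 1e-12:
            best_iv = total
            cuts = []
            i = m
            for j in range(k, 0, -1):
                a = int(back[j][i])
                if a > 0:
                    cuts.append(a)
                i = a
            best_cuts = sorted(cuts)
    return best_cuts


def _fingerprint(y: np.ndarray) -> str:
    return f"n={y.size};events={int(y.sum())}"


def fit_binning(
    values: Sequence,
    outcome: Sequence[int],
    kind: str = "continuous",
    params: BinningParams | None = None,
    variable: str = "",
) -> BinningScheme:
    """Fit an IV-optimal binning scheme for one variable on training data.

    Continuous variables are quantile pre-binned into at most
    ``params.pre_bins`` cells and merged by exact DP; categorical variables
    are ordered by event rate (ties broken by level name) and grouped by the
    same DP.  Missing values (NaN/None) always form their own bin when
    present.  Only the supplied (training) data is used.
    """
    params = params or BinningParams()
    y = np.asarray(outcome, dtype=int)
    vals = pd.Series(list(values))
    if vals.size != y.size:
        raise ValueError("values and outcome must be aligned")
    if y.min() == y.max() and y.size > 0:
        raise ValueError("both outcome classes must be present to fit bins")
    miss = vals.isna().to_numpy()
    extra_ev = int(y[miss].sum())
    extra_ne = int(miss.sum() - extra_ev)
    has_missing = bool(miss.any())
    s = params.smoothing

    obs_y = y[~miss]
    e_tot, n_tot = int(obs_y.sum()), int((~miss).sum() - obs_y.sum())

    bins: list[Bin] = []
    if miss.all():
        # degenerate: only the missing bin
        woe = woe_value(extra_ev, extra_ne, extra_ev, extra_ne, s, 1)
        bins = [Bin(n_event=extra_ev, n_nonevent=extra_ne, woe=woe, is_missing=True)]
        scheme = BinningScheme(variable, kind, bins, 0.0, s, _fingerprint(y))
        scheme.iv = information_value(scheme)
        return scheme

    if kind == "continuous":
        v = pd.to_numeric(vals[~miss]).to_numpy(dtype=float)
        qs = np.linspace(0, 1, params.pre_bins + 1)[1:-1]
        edges = np.unique(np.quantile(v, qs))
        cell_idx = np.searchsorted(edges, v, side="right")
        n_cells = len(edges) + 1
        cell_ev = np.bincount(cell_idx, weights=obs_y, minlength=n_cells)
        cell_ne = np.bincount(cell_idx, weights=1 - obs_y, minlength=n_cells)
        keep = (cell_ev + cell_ne) > 0
        cell_ev, cell_ne = cell_ev[keep], cell_ne[keep]
        # right boundary of each kept cell (last one is +inf)
        bounds = np.append(edges, np.inf)[keep]
        cuts = _best_contiguous_partition(
            cell_ev, cell_ne, extra_ev, extra_ne, has_missing, params
        )
        group_bounds = [0] + cuts + [len(cell_ev)]
        n_bins = len(group_bounds) - 1 + (1 if has_missing else 0)
        lo = -math.inf
        for g in range(len(group_bounds) - 1):
            a, b = group_bounds[g], group_bounds[g + 1]
            ge, gn = int(cell_ev[a:b].sum()), int(cell_ne[a:b].sum())
            hi = math.inf if b == len(cell_ev) else float(bounds[b - 1])
            woe = woe_value(ge, gn, e_tot + extra_ev, n_tot + extra_ne, s, n_bins)
            bins.append(Bin(n_event=ge, n_nonevent=gn, woe=woe, lo=lo, hi=hi))
            lo = hi
    elif kind in ("categorical", "binary"):
        lv = vals[~miss].astype(str)
        tab = pd.crosstab(lv, obs_y)
        for c in (0, 1):
            if c not in tab.columns:
                tab[c] = 0
        rate = tab[1] / (tab[0] + tab[1])
        order = sorted(tab.index, key=lambda l: (rate[l], l))
        cell_ev = np.array([tab.loc[l, 1] for l in order], dtype=float)
        cell_ne = np.array([tab.loc[l, 0] for l in order], dtype=float)
        cuts = _best_contiguous_partition(
            cell_ev, cell_ne, extra_ev, extra_ne, has_missing, params
        )
        group_bounds = [0] + cuts + [len(order)]
        n_bins = len(group_bounds) - 1 + (1 if has_missing else 0)
        for g in range(len(group_bounds) - 1):
            a, b = group_bounds[g], group_bounds[g + 1]
            ge, gn = int(cell_ev[a:b].sum()), int(cell_ne[a:b].sum())
            woe = woe_value(ge, gn, e_tot + extra_ev, n_tot + extra_ne, s, n_bins)
            bins.append(
                Bin(n_event=ge, n_nonevent=gn, woe=woe, levels=tuple(order[a:b]))
            )
    else:
        raise ValueError(f"unknown variable kind {kind!r}")

    if has_missing:
        woe = woe_value(
            extra_ev, extra_ne, e_tot + extra_ev, n_tot + extra_ne, s, len(bins) + 1
        )
        bins.append(Bin(n_event=extra_ev, n_nonevent=extra_ne, woe=woe, is_missing=True))

    scheme = BinningScheme(variable, "categorical" if kind == "binary" else kind,
                           bins, 0.0, s, _fingerprint(y))
    scheme.iv = information_value(scheme)
    return scheme


def transform(scheme: BinningScheme, values: Sequence) -> np.ndarray:
    """Replace each value by its bin's WoE.

    Missing values get the missing bin's WoE if that bin was fitted, else 0;
    category levels unseen in training get 0 (neutral evidence).  The output
    contains no missing entries.
    """
    vals = pd.Series(list(values))
    miss = vals.isna().to_numpy()
    out = np.zeros(vals.size, dtype=float)
    mb = scheme.missing_bin
    out[miss] = mb.woe if mb is not None else 0.0

    regular = [b for b in scheme.bins if not b.is_missing]
    if not regular:
        return out
    if regular[0].lo is not None:
        edges = np.array([b.hi for b in regular[:-1]], dtype=float)
        woes = np.array([b.woe for b in regular])
        v = pd.to_numeric(vals[~miss]).to_numpy(dtype=float)
        idx = np.searchsorted(edges, v, side="right")
        out[~miss] = woes[idx]
    else:
        lookup = {lvl: b.woe for b in regular for lvl in (b.levels or ())}
        out[~miss] = [lookup.get(str(x), 0.0) for x in vals[~miss]]
    return out


def fit_all(cohort, params: BinningParams | None = None) -> dict[str, BinningScheme]:
    """Fit one scheme per variable of a training cohort.

    Variables that cannot be binned are excluded with a logged reason rather
    than aborting the whole fit.
    """
    params = params or BinningParams()
    schemes: dict[str, BinningScheme] = {}
    for spec in cohort.specs:
        try:
            schemes[spec.name] = fit_binning(
                cohort.values[spec.name],
                cohort.outcome,
                kind="continuous" if spec.kind == "continuous" else spec.kind,
                params=params,
                variable=spec.name,
            )
        except Exception as exc:  # noqa: BLE001 - per-variable isolation
            logger.warning("excluding variable %r from binning: %s", spec.name, exc)
    return schemes


def iv_manifest(schemes: Mapping[str, BinningScheme]) -> pd.DataFrame:
    """Per-variable IV table sorted descending (name breaks ties)."""
    rows = [(name, s.iv, len(s.bins)) for name, s in schemes.items()]
    df = pd.DataFrame(rows, columns=["variable", "iv", "n_bins"])
    return df.sort_values(["iv", "variable"], ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# serialization (bit-exact text round trip)

def _bin_to_dict(b: Bin) -> dict:
    d = asdict(b)
    for key in ("lo", "hi"):
        if d[key] is not None and not math.isfinite(d[key]):
            d[key] = "inf" if d[key] > 0 else "-inf"
    if d["levels"] is not None:
        d["levels"] = list(d["levels"])
    return d


def _bin_from_dict(d: dict) -> Bin:
    for key in ("lo", "hi"):
        if isinstance(d[key], str):
            d[key] = float(d[key])
    if d["levels"] is not None:
        d["levels"] = tuple(d["levels"])
    return Bin(**d)


def save_schemes(schemes: Mapping[str, BinningScheme], path) -> None:
    payload = {
        name: {
            "variable": s.variable,
            "kind": s.kind,
            "iv": s.iv,
            "smoothing": s.smoothing,
            "fitted_on": s.fitted_on,
            "bins": [_bin_to_dict(b) for b in s.bins],
        }
        for name, s in schemes.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_schemes(path) -> dict[str, BinningScheme]:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for name, d in payload.items():
        out[name] = BinningScheme(
            variable=d["variable"],
            kind=d["kind"],
            bins=[_bin_from_dict(b) for b in d["bins"]],
            iv=d["iv"],
            smoothing=d["smoothing"],
            fitted_on=d["fitted_on"],
        )
    return out
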