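"""Cohort data model: variable dictionary, table loading, difference
features, stratified splits and Table-1-style summaries.

A cohort is a subjects-by-variables table of mixed continuous / categorical
/ binary clinical variables with missing entries, a binary outcome (1 =
musculoskeletal injury within a year of return to participation), and an
optional per-subject group label such as Sport.  Variables carry a
timepoint: the pre-injury Baseline, the Acute (<48 h) visit, the
Asymptomatic visit, the return-to-participation (RTP) visit, or ``static``
for demographics that have no timepoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "VariableSpec",
    "CohortTable",
    "SplitResult",
    "SchemaError",
    "load_cohort",
    "build_difference_features",
    "stratified_split",
    "cohort_summary",
]

KINDS = ("continuous", "categorical", "binary")
TIMEPOINTS = ("baseline", "acute", "asymptomatic", "rtp", "static")
TIMEPOINT_LABELS = {
    "baseline": "Baseline",
    "acute": "Acute",
    "asymptomatic": "Asymptomatic",
    "rtp": "RTP",
}
DEFAULT_MISSING_SENTINELS = ("", "NA", "NaN")


class SchemaError(ValueError):
    """A table does not match its variable dictionary."""


@dataclass(frozen=True)
class VariableSpec:
    """Declared name, kind and timepoint of one predictive variable.

    ``measure`` is the timepoint-free base name used to pair Baseline and
    post-injury columns when building difference features; by default it is
    the part of ``name`` before an ``@`` separator ("CRT@Acute" -> "CRT").
    ``higher_is_worse`` and ``tags`` are documentation/selection metadata
    only (a "sport" tag marks sport-informative variables for ablations).
    """

    name: str
    kind: str
    timepoint: str = "static"
    measure: str | None = None
    higher_is_worse: bool | None = None
    tags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.timepoint not in TIMEPOINTS:
            raise SchemaError(
                f"unknown timepoint {self.timepoint!r} for {self.name!r}"
            )

    @property
    def base_measure(self) -> str:
        if self.measure:
            return self.measure
        return self.name.split("@")[0].strip()


@dataclass
class CohortTable:
    """N subjects x P variables with missingness, binary outcome and an
    optional group label."""

    subject_ids: list[str]
    values: pd.DataFrame
    outcome: np.ndarray
    specs: list[VariableSpec]
    group: pd.Series | None = None

    def __post_init__(self):
        self.outcome = np.asarray(self.outcome, dtype=int)
        if pd.isna(self.outcome).any():
            raise SchemaError("outcome must have no missing entries")
        if not np.isin(self.outcome, (0, 1)).all():
            raise SchemaError("outcome must be binary 0/1")
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in dictionary")
        missing_cols = [n for n in names if n not in self.values.columns]
        if missing_cols:
            raise SchemaError(f"columns missing from table: {missing_cols}")
        self.values = self.values[names].reset_index(drop=True)
        if self.group is not None:
            self.group = pd.Series(list(self.group)).reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def p(self) -> int:
        return len(self.specs)

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def subset(self, rows: Sequence[int]) -> "CohortTable":
        rows = list(rows)
        return CohortTable(
            subject_ids=[self.subject_ids[i] for i in rows],
            values=self.values.iloc[rows].reset_index(drop=True),
            outcome=self.outcome[rows],
            specs=list(self.specs),
            group=None if self.group is None else self.group.iloc[rows],
        )

    def drop_variables(self, names: Sequence[str]) -> "CohortTable":
        drop = set(names)
        keep = [s for s in self.specs if s.name not in drop]
        return CohortTable(
            subject_ids=list(self.subject_ids),
            values=self.values[[s.name for s in keep]].copy(),
            outcome=self.outcome.copy(),
            specs=keep,
            group=None if self.group is None else self.group.copy(),
        )


@dataclass
class SplitResult:
    train: CohortTable
    test: CohortTable
    seed: int
    rejected_attempts: int = 0


def _read_dictionary(dictionary_file) -> dict:
    with open(dictionary_file) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "variables" not in cfg:
        raise SchemaError("dictionary must define a 'variables' mapping")
    if "outcome" not in cfg:
        raise SchemaError("dictionary must declare the outcome column")
    return cfg


def _spec_from_entry(name: str, entry: Mapping) -> VariableSpec:
    return VariableSpec(
        name=name,
        kind=entry.get("kind", "continuous"),
        timepoint=entry.get("timepoint", "static"),
        measure=entry.get("measure"),
        higher_is_worse=entry.get("higher_is_worse"),
        tags=tuple(entry.get("tags", ())),
    )


def _validate_column(col: pd.Series, spec: VariableSpec) -> pd.Series:
    if spec.kind == "continuous":
        try:
            return pd.to_numeric(col)
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"continuous column {spec.name!r} has non-numeric entries: {exc}"
            ) from None
    levels = col.dropna().unique()
    if spec.kind == "binary" and len(levels) > 2:
        raise SchemaError(
            f"binary column {spec.name!r} has {len(levels)} non-missing levels"
        )
    return col


def load_cohort(table_file, dictionary_file) -> CohortTable:
    """Load a delimited-text cohort table against its variable dictionary.

    Comma-delimited by default; tab accepted (sniffed from the header).
    Missing sentinels (empty cell, "NA", "NaN" by default; configurable via
    the dictionary's ``missing_values`` list) are normalized to a single
    missing state.  Column kinds are validated against the dictionary.
    """
    cfg = _read_dictionary(dictionary_file)
    sentinels = [str(s) for s in cfg.get("missing_values", DEFAULT_MISSING_SENTINELS)]
    with open(table_file) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(
        table_file, sep=sep, na_values=sentinels, keep_default_na=False,
        dtype=object,
    )

    outcome_col = cfg["outcome"]
    if outcome_col not in df.columns:
        raise SchemaError(f"outcome column {outcome_col!r} missing from table")
    try:
        outcome = pd.to_numeric(df[outcome_col]).to_numpy()
    except (ValueError, TypeError):
        raise SchemaError(f"outcome column {outcome_col!r} is not numeric") from None
    if pd.isna(outcome).any() or not np.isin(outcome, (0, 1)).all():
        raise SchemaError("outcome column must be binary 0/1 with no missing entries")

    specs = [_spec_from_entry(n, e or {}) for n, e in cfg["variables"].items()]
    for spec in specs:
        if spec.name not in df.columns:
            raise SchemaError(f"declared column {spec.name!r} missing from table")
        df[spec.name] = _validate_column(df[spec.name], spec)

    id_col = cfg.get("subject_id")
    if id_col and id_col in df.columns:
        subject_ids = [str(x) for x in df[id_col]]
    else:
        subject_ids = [f"S{i:04d}" for i in range(len(df))]

    group_col = cfg.get("group")
    group = df[group_col] if group_col and group_col in df.columns else None

    cohort = CohortTable(
        subject_ids=subject_ids,
        values=df,
        outcome=outcome.astype(int),
        specs=specs,
        group=group,
    )
    logger.info("loaded cohort: %d subjects, %d variables", cohort.n, cohort.p)
    return cohort


def build_difference_features(cohort: CohortTable) -> CohortTable:
    """Append baseline-minus-later-timepoint difference features.

    For every continuous measure present at Baseline and at a later
    timepoint, a new continuous column equal to the Baseline value minus the
    later value is appended, named ``"<Measure> Difference Baseline
    <Timepoint>"``.  If either operand is missing, the difference is
    missing.  Measures lacking a baseline counterpart are skipped.
    """
    by_measure: dict[str, dict[str, VariableSpec]] = {}
    for s in cohort.specs:
        if s.kind != "continuous" or s.timepoint == "static":
            continue
        by_measure.setdefault(s.base_measure, {})[s.timepoint] = s

    values = cohort.values.copy()
    specs = list(cohort.specs)
    existing = {s.name for s in specs}
    for measure, tps in sorted(by_measure.items()):
        base = tps.get("baseline")
        if base is None:
            if tps:
                logger.info("measure %r has no baseline column; skipped", measure)
            continue
        for tp in ("acute", "asymptomatic", "rtp"):
            later = tps.get(tp)
            if later is None:
                continue
            name = f"{measure} Difference Baseline {TIMEPOINT_LABELS[tp]}"
            if name in existing:
                logger.info("difference column %r already present; skipped", name)
                continue
            diff = pd.to_numeric(values[base.name]) - pd.to_numeric(values[later.name])
            values[name] = diff
            specs.append(
                VariableSpec(name=name, kind="continuous", timepoint=tp,
                             measure=measure, tags=base.tags)
            )
            existing.add(name)
    return CohortTable(
        subject_ids=list(cohort.subject_ids),
        values=values,
        outcome=cohort.outcome.copy(),
        specs=specs,
        group=None if cohort.group is None else cohort.group.copy(),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _test_only_levels(train: CohortTable, test: CohortTable) -> str | None:
    """Name of the first categorical/binary level seen only in test, if any."""
    for s in train.specs:
        if s.kind not in ("categorical", "binary"):
            continue
        train_levels = set(train.values[s.name].dropna().astype(str))
        test_levels = set(test.values[s.name].dropna().astype(str))
        only = test_levels - train_levels
        if only:
            return f"{s.name}={sorted(only)[0]}"
    return None


def stratified_split(
    cohort: CohortTable,
    test_fraction: float,
    seed: int,
    max_retries: int = 1000,
) -> SplitResult:
    """Outcome-stratified train/test split with the unique-level rejection
    rule.

    Per outcome class with ``n_c`` members the test set receives
    ``round(n_c * test_fraction)`` members (round half up) chosen uniformly
    at random under ``seed``.  A draw in which any level of a categorical or
    binary variable occurs only in the test set is rejected and redrawn;
    after ``max_retries`` rejections an error names the offending level.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    y = cohort.outcome
    for c in (0, 1):
        if (y == c).sum() < 2:
            raise ValueError("both classes need at least 2 members")
    rng = np.random.default_rng(seed)
    idx_by_class = {c: np.flatnonzero(y == c) for c in (0, 1)}
    n_test = {c: _round_half_up(len(idx) * test_fraction)
              for c, idx in idx_by_class.items()}

    offender = None
    for attempt in range(max_retries + 1):
        test_idx: list[int] = []
        for c in (0, 1):
            pick = rng.choice(idx_by_class[c], size=n_test[c], replace=False)
            test_idx.extend(int(i) for i in pick)
        test_idx = sorted(test_idx)
        train_idx = sorted(set(range(cohort.n)) - set(test_idx))
        train, test = cohort.subset(train_idx), cohort.subset(test_idx)
        offender = _test_only_levels(train, test)
        if offender is None:
            return SplitResult(train=train, test=test, seed=seed,
                               rejected_attempts=attempt)
        logger.info("split seed %d attempt %d rejected: level %s only in test",
                    seed, attempt, offender)
    raise RuntimeError(
        f"stratified split failed after {max_retries} redraws; "
        f"level {offender} cannot be kept out of a test-only position"
    )


def cohort_summary(
    cohort: CohortTable,
    group_by: str | Sequence[str],
) -> pd.DataFrame:
    """Per-group injury counts and event rates, plus mean/sd of static
    continuous demographics (a Table-1-style summary).

    Event rate = events / (events + non-events), rounded to 3 decimals.
    Empty groups are omitted.
    """
    group_cols = [group_by] if isinstance(group_by, str) else list(group_by)
    frame = pd.DataFrame({"__y": cohort.outcome})
    for g in group_cols:
        if g in cohort.values.columns:
            frame[g] = cohort.values[g].to_numpy()
        elif cohort.group is not None and g == (cohort.group.name or "group"):
            frame[g] = cohort.group.to_numpy()
        else:
            raise KeyError(f"group column {g!r} not found")

    demo = [s.name for s in cohort.specs
            if s.kind == "continuous" and s.timepoint == "static"]
    for d in demo:
        frame[d] = pd.to_numeric(cohort.values[d]).to_numpy()

    rows = []
    for key, sub in frame.groupby(group_cols, dropna=False, sort=True):
        if len(sub) == 0:
            logger.warning("empty group %r omitted", key)
            continue
        key = key if isinstance(key, tuple) else (key,)
        n_event = int(sub["__y"].sum())
        n_nonevent = int(len(sub) - n_event)
        row = dict(zip(group_cols, key))
        row["n_nonevent"] = n_nonevent
        row["n_event"] = n_event
        row["event_rate"] = round(n_event / (n_event + n_nonevent), 3)
        for d in demo:
            row[f"{d}_mean"] = float(sub[d].mean())
            row[f"{d}_sd"] = float(sub[d].std(ddof=1)) if len(sub) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
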