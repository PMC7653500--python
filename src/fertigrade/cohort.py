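"""Cohort data model, CSV input/output and the cleaning step.

A cohort is one record per couple undergoing IVF with fresh embryo
transfer: up to seven numeric indicators (woman's age, BMI, baseline FSH,
antral follicle count, AMH, number of oocytes retrieved, endometrial
thickness) and a binary pregnancy outcome.  Cleaning handles implausible
values by range rules (drop or clip) and imputes remaining missing values
with the column mean (continuous indicators) or mode (integer counts),
with imputation statistics computed after the range step so outliers
cannot contaminate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CohortError

#: Canonical indicator column names, in table order.
INDICATORS: tuple[str, ...] = ("age", "bmi", "fsh", "afc", "amh", "oocytes", "emt")

#: Indicators recorded as integer counts (mode-imputed by default).
INTEGER_INDICATORS: frozenset[str] = frozenset({"afc", "oocytes"})

#: Binary outcome column name.
OUTCOME: str = "pregnant"

#: Units for reports.
UNITS: Mapping[str, str] = {
    "age": "years",
    "bmi": "kg/m^2",
    "fsh": "mIU/mL",
    "afc": "count",
    "amh": "ng/mL",
    "oocytes": "count",
    "emt": "mm",
}


@dataclass(frozen=True)
class CleaningRule:
    """Plausible-range rule plus imputation method for one indicator.

    ``action`` is applied to out-of-range values: ``"drop-record"`` removes
    the whole record, ``"clip-to-bound"`` replaces the value with the
    violated bound.  ``imputation`` fills values still missing afterwards.
    """

    indicator: str
    minimum: float
    maximum: float
    action: str = "drop-record"
    imputation: str = "mean"

    _ACTIONS = ("drop-record", "clip-to-bound")
    _IMPUTATIONS = ("mean", "mode")

    def __post_init__(self) -> None:
        if not self.minimum < self.maximum:
            raise CohortError(
                f"rule for {self.indicator!r}: minimum must be < maximum"
            )
        if self.action not in self._ACTIONS:
            raise CohortError(f"unknown out-of-range action {self.action!r}")
        if self.imputation not in self._IMPUTATIONS:
            raise CohortError(f"unknown imputation method {self.imputation!r}")


def default_cleaning_rules() -> list[CleaningRule]:
    """Shipped plausible ranges (all overridable in config).

    Integer count indicators are mode-imputed, continuous ones
    mean-imputed.
    """
    ranges = {
        "age": (18.0, 55.0),
        "bmi": (10.0, 60.0),
        "fsh": (0.0, 100.0),
        "afc": (0.0, 100.0),
        "amh": (0.0, 30.0),
        "oocytes": (0.0, 60.0),
        "emt": (0.0, 30.0),
    }
    return [
        CleaningRule(
            indicator=name,
            minimum=lo,
            maximum=hi,
            action="drop-record",
            imputation="mode" if name in INTEGER_INDICATORS else "mean",
        )
        for name, (lo, hi) in ranges.items()
    ]


@dataclass
class CohortTable:
    """Ordered collection of patient records backed by a DataFrame.

    ``provenance`` is ``"raw"`` before cleaning and ``"cleaned"`` after.
    The outcome column is strictly binary (0/1); indicator columns may
    contain missing values only while raw.
    """

    data: pd.DataFrame
    provenance: str = "raw"
    units: Mapping[str, str] = field(default_factory=lambda: dict(UNITS))

    def __post_init__(self) -> None:
        if OUTCOME not in self.data.columns:
            raise CohortError(f"cohort lacks outcome column {OUTCOME!r}")
        if not self.indicator_columns:
            raise CohortError("cohort has no indicator columns")
        out = self.data[OUTCOME]
        if out.isna().any():
            raise CohortError("outcome column contains missing values")
        if not out.isin((0, 1)).all():
            raise CohortError("outcome column must be strictly binary (0/1)")
        if self.provenance not in ("raw", "cleaned"):
            raise CohortError(f"unknown provenance {self.provenance!r}")

    @property
    def indicator_columns(self) -> list[str]:
        return [c for c in self.data.columns if c in INDICATORS]

    @property
    def n(self) -> int:
        return len(self.data)

    def outcome(self) -> np.ndarray:
        return self.data[OUTCOME].to_numpy(dtype=int)

    def values(self, indicator: str) -> np.ndarray:
        if indicator not in self.data.columns:
            raise CohortError(f"indicator {indicator!r} not in cohort")
        return self.data[indicator].to_numpy(dtype=float)


def read_cohort_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> CohortTable:
    """Read a raw cohort from a comma-separated, UTF-8, headered CSV.

    ``column_map`` maps canonical names (``age`` ... ``pregnant``) to the
    file's header names.  Unparseable numeric cells become missing values,
    never silent zeros.  A missing outcome column or an empty file is
    fatal.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=",", encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise CohortError(f"{path}: empty cohort file") from exc
    if frame.empty:
        raise CohortError(f"{path}: cohort file has no data rows")

    if column_map:
        missing = [src for src in column_map.values() if src not in frame.columns]
        if missing:
            raise CohortError(f"{path}: mapped columns absent from header: {missing}")
        frame = frame.rename(columns={v: k for k, v in column_map.items()})

    if OUTCOME not in frame.columns:
        raise CohortError(f"{path}: outcome column {OUTCOME!r} missing from header")

    keep = [c for c in frame.columns if c in INDICATORS or c == OUTCOME]
    frame = frame[keep].copy()
    for col in keep:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    if frame[OUTCOME].isna().any():
        raise CohortError(f"{path}: outcome column contains unparseable cells")
    return CohortTable(frame.reset_index(drop=True), provenance="raw")


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort back to CSV (canonical column order)."""
    cols = [c for c in INDICATORS if c in cohort.data.columns] + [OUTCOME]
    cohort.data[cols].to_csv(path, index=False)


def _impute_column(col: pd.Series, method: str) -> pd.Series:
    observed = col.dropna()
    if observed.empty:
        raise CohortError(f"column {col.name!r} has no observed values to impute from")
    if method == "mean":
        fill = float(observed.mean())
    else:  # mode, ties broken toward the smaller value
        counts = observed.value_counts()
        top = counts[counts == counts.max()].index
        fill = float(min(top))
    return col.fillna(fill)


def clean_cohort(cohort: CohortTable, rules: Sequence[CleaningRule]) -> CohortTable:
    """Apply range rules then impute; idempotent on its own output.

    Every indicator column present in the cohort must have exactly one
    rule; a rule naming an unknown indicator is fatal.  Records are
    dropped only by ``drop-record`` rules, so the output record count is
    at most the input count.
    """
    present = set(cohort.indicator_columns)
    by_name: dict[str, CleaningRule] = {}
    for rule in rules:
        if rule.indicator not in present:
            raise CohortError(
                f"cleaning rule references unknown indicator {rule.indicator!r}"
            )
        if rule.indicator in by_name:
            raise CohortError(f"duplicate cleaning rule for {rule.indicator!r}")
        by_name[rule.indicator] = rule
    uncovered = present - set(by_name)
    if uncovered:
        raise CohortError(f"indicators without a cleaning rule: {sorted(uncovered)}")

    frame = cohort.data.copy()

    # Range step first: drop or clip, so imputation statistics are
    # computed on in-range values only.
    keep_mask = pd.Series(True, index=frame.index)
    for name, rule in by_name.items():
        col = frame[name]
        bad = col.notna() & ((col < rule.minimum) | (col > rule.maximum))
        if rule.action == "drop-record":
            keep_mask &= ~bad
        else:
            frame[name] = col.clip(lower=rule.minimum, upper=rule.maximum)
    frame = frame.loc[keep_mask].reset_index(drop=True)
    if frame.empty:
        raise CohortError("cleaning removed every record")

    for name, rule in by_name.items():
        if frame[name].isna().any():
            frame[name] = _impute_column(frame[name], rule.imputation)

    cleaned = CohortTable(frame, provenance="cleaned", units=dict(cohort.units))
    return cleaned


def append_records(cohort: CohortTable, extra: CohortTable) -> CohortTable:
    """Extend a cohort with new records (the dynamic-update entry point).

    Returns a raw cohort; the system is refreshed simply by rebuilding on
    the extended cohort.
    """
    if set(extra.data.columns) != set(cohort.data.columns):
        raise CohortError("appended records must have the same columns")
    merged = pd.concat(
        [cohort.data, extra.data[cohort.data.columns]], ignore_index=True
    )
    return CohortTable(merged, provenance="raw", units=dict(cohort.units))
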