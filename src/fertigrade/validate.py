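"""Stability validation, interval pregnancy rates and exclusion audit.

Classification consistency is defined as grade agreement: a reference
system is built on the full cohort; for each of k folds a system is
rebuilt on the other k-1 folds and the held-out records are graded by
both.  A fold's consistency is the fraction of its records receiving
the same grade from both systems; the overall figure is the
record-weighted mean with a normal-approximation 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import AuditError, FertigradeError
from .system import BuildConfig, ScoringSystem, build_system, clean_cohort, score_cohort


@dataclass(frozen=True)
class ConsistencyResult:
    """k-fold grade-agreement summary."""

    per_fold: tuple[float, ...]
    overall: float
    ci_low: float
    ci_high: float
    fold_sizes: tuple[int, ...]

    @property
    def k(self) -> int:
        return len(self.per_fold)


@dataclass(frozen=True)
class RateRow:
    """One interval row of the grading table: counts and pregnancy rate.

    ``rate`` is a percentage rounded half-up to 2 decimals; ``None``
    marks an undefined rate (empty interval), never 0.
    """

    indicator: str
    label: str
    total: int
    pregnant: int
    rate: float | None

    def __post_init__(self) -> None:
        if self.pregnant > self.total:
            raise AuditError("pregnant count exceeds total")


def round_rate(pregnant: int, total: int) -> float | None:
    """100*pregnant/total, rounded half-up to 2 decimals; None if empty."""
    if total == 0:
        return None
    frac = Decimal(int(100 * pregnant)) / Decimal(int(total))
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compute_interval_rates(
    source: CohortTable | Mapping[str, Sequence[tuple[str, int, int]]],
    system: ScoringSystem,
) -> list[RateRow]:
    """Per-interval totals, pregnant counts and rates for every scheme.

    ``source`` is either a cohort (counted through the system's
    intervals) or pre-tabulated fixture counts: a mapping
    indicator -> [(interval label, total, pregnant), ...] in interval
    order.
    """
    rows: list[RateRow] = []
    if isinstance(source, CohortTable):
        outcome = source.outcome()
        for scheme in system.schemes:
            values = source.values(scheme.indicator)
            idx = scheme.interval_indices(values)
            k = scheme.n_intervals
            totals = np.bincount(idx, minlength=k)
            preg = np.bincount(idx, weights=outcome, minlength=k).astype(int)
            for lab, t, p in zip(scheme.interval_labels(), totals, preg):
                rows.append(
                    RateRow(scheme.indicator, lab, int(t), int(p), round_rate(p, t))
                )
        return rows
    for scheme in system.schemes:
        if scheme.indicator not in source:
            raise AuditError(f"fixture counts lack indicator {scheme.indicator!r}")
        for lab, total, pregnant in source[scheme.indicator]:
            rows.append(
                RateRow(scheme.indicator, lab, int(total), int(pregnant),
                        round_rate(int(pregnant), int(total)))
            )
    return rows


def rates_frame(rows: Sequence[RateRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "indicator": [r.indicator for r in rows],
            "interval": [r.label for r in rows],
            "total": [r.total for r in rows],
            "pregnant": [r.pregnant for r in rows],
            "rate_pct": [r.rate for r in rows],
        }
    )


def fold_assignment(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded random fold labels 0..k-1, maximally equal sizes."""
    if k < 2:
        raise FertigradeError("need at least 2 folds")
    if k > n:
        raise FertigradeError("more folds than records (a fold would be empty)")
    base, extra = divmod(n, k)  # first n % k folds get one extra record
    sizes = [base + (1 if i < extra else 0) for i in range(k)]
    labels = np.repeat(np.arange(k), sizes)
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(n)]


def tenfold_consistency(
    cohort: CohortTable,
    config: BuildConfig,
    k: int = 10,
    seed: int = 0,
) -> ConsistencyResult:
    """k-fold classification-consistency of the fitted system.

    Requires that a system can be rebuilt on every k-1 fold subset;
    degenerate folds (zero records) are fatal.
    """
    rules = [r for r in config.cleaning_rules if r.indicator in cohort.indicator_columns]
    cleaned = cohort if cohort.provenance == "cleaned" else clean_cohort(cohort, rules)
    reference = build_system(cleaned, config)
    ref_grades = score_cohort(cleaned, reference)["grade"].to_numpy()

    folds = fold_assignment(cleaned.n, k, seed)
    per_fold: list[float] = []
    sizes: list[int] = []
    agree_all = np.zeros(cleaned.n, dtype=bool)
    for f in range(k):
        held = folds == f
        if not held.any():
            raise FertigradeError(f"fold {f} is empty")
        train = CohortTable(
            cleaned.data.loc[~held].reset_index(drop=True), provenance="cleaned"
        )
        fold_system = build_system(train, config)
        held_cohort = CohortTable(
            cleaned.data.loc[held].reset_index(drop=True), provenance="cleaned"
        )
        fold_grades = score_cohort(held_cohort, fold_system)["grade"].to_numpy()
        agree = fold_grades == ref_grades[held]
        agree_all[held] = agree
        per_fold.append(float(np.mean(agree)))
        sizes.append(int(held.sum()))

    overall = float(np.mean(agree_all))
    se = float(np.sqrt(overall * (1 - overall) / cleaned.n))
    ci = (overall - 1.96 * se, overall + 1.96 * se)
    return ConsistencyResult(tuple(per_fold), overall, ci[0], ci[1], tuple(sizes))


@dataclass(frozen=True)
class ExclusionAudit:
    """Record-exclusion arithmetic with a retained audit trail."""

    initial: int
    exclusions: tuple[tuple[str, int], ...]
    remaining: int


def exclusion_audit(initial: int, exclusions: Mapping[str, int]) -> ExclusionAudit:
    """initial - sum(exclusions); a negative remainder is fatal."""
    if initial < 0 or any(v < 0 for v in exclusions.values()):
        raise AuditError("counts must be non-negative")
    remaining = initial - sum(exclusions.values())
    if remaining < 0:
        raise AuditError(
            f"exclusions ({sum(exclusions.values())}) exceed initial ({initial})"
        )
    return ExclusionAudit(initial, tuple(exclusions.items()), remaining)
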