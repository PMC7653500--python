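"""Fitted scoring system: categorize, score, grade, serialize, build.

A fitted system holds one discretization scheme per indicator, the
normalized indicator weights and a grade scheme.  A record's total score
is the weighted mean of its per-indicator points, hence always in
[1, 4]; the total is stratified into ordered prognostic grades (best A
down to E for five grades) by the same entropy/MDL discretizer applied
to (total score, outcome).  Grade bands are upper-inclusive on the worst
side: grade E is total <= tau1, the best grade is total > tau_max, and a
total exactly at an intermediate threshold takes the lower grade.

``build_system`` runs the full pipeline — clean, screen, discretize,
weight, stratify — so adding records and rebuilding is the dynamic
update mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    INTEGER_INDICATORS,
    OUTCOME,
    CleaningRule,
    CohortTable,
    clean_cohort,
    default_cleaning_rules,
)
from .discretize import (
    DiscretizationScheme,
    build_scheme,
    discretize_indicator,
    who_bmi_scheme,
)
from .errors import GradeError, StratificationError, SystemSchemaError
from .screen import select_indicators
from .weights import WeightVector, compute_weights

SCHEMA_VERSION = 1

#: Default orientation of each indicator's points profile.
DEFAULT_ORIENTATIONS: Mapping[str, str] = {
    "age": "monotone_decreasing",
    "fsh": "monotone_decreasing",
    "afc": "monotone_increasing",
    "amh": "monotone_increasing",
    "emt": "monotone_increasing",
    "oocytes": "medium",
    "bmi": "fixed_who",
}

#: Maximum interval counts by orientation class.
DEFAULT_MAX_INTERVALS: Mapping[str, int] = {
    "monotone_increasing": 4,
    "monotone_decreasing": 4,
    "medium": 7,
}

GRADE_LABELS = ("A", "B", "C", "D", "E", "F", "G")


@dataclass(frozen=True)
class GradeScheme:
    """Ordered grade thresholds on the 1-4 total-score scale.

    ``thresholds`` are strictly increasing and lie in (1, 4); an entry
    may be ``None`` for a threshold known to exist but not published
    (fixture use) — such bands cannot be resolved by ``assign_grade``.
    ``labels`` run best to worst and number one more than the thresholds.
    """

    thresholds: tuple[float | None, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.thresholds) + 1:
            raise GradeError("labels must number thresholds + 1")
        known = [t for t in self.thresholds if t is not None]
        if not known:
            raise GradeError("at least one threshold must be known")
        if any(b <= a for a, b in zip(known, known[1:])):
            raise GradeError("thresholds must be strictly increasing")
        if any(not 1.0 < t < 4.0 for t in known):
            raise GradeError("thresholds must lie strictly inside (1, 4)")
        if self.thresholds[0] is None or self.thresholds[-1] is None:
            raise GradeError("outermost thresholds must be known")

    @property
    def n_grades(self) -> int:
        return len(self.labels)

    @property
    def fully_resolved(self) -> bool:
        return all(t is not None for t in self.thresholds)


def assign_grade(total: float, grades: GradeScheme) -> str:
    """Grade label for a total score; bands are (low, high].

    total <= first threshold -> worst label; total > last threshold ->
    best label; an unresolved intermediate threshold makes middle bands
    unassignable.
    """
    if not 1.0 <= total <= 4.0:
        raise GradeError(f"total score {total} outside [1, 4]")
    ts = grades.thresholds
    if total <= ts[0]:
        return grades.labels[-1]
    if total > ts[-1]:
        return grades.labels[0]
    if not grades.fully_resolved:
        raise GradeError(
            "intermediate grade thresholds are unresolved (unpublished); "
            "rebuild the grade scheme from data to grade this score"
        )
    idx = int(np.searchsorted(np.asarray(ts, dtype=float), total, side="left"))
    return grades.labels[len(grades.labels) - 1 - idx]


def try_assign_grade(total: float, grades: GradeScheme) -> str | None:
    """Like assign_grade but None for unresolvable middle bands."""
    try:
        return assign_grade(total, grades)
    except GradeError:
        if not grades.fully_resolved and 1.0 <= total <= 4.0:
            return None
        raise


def stratify_total_scores(
    scores: Sequence[float],
    outcomes: Sequence[int],
    n_grades: int = 5,
) -> GradeScheme:
    """Entropy-stratify total scores into ``n_grades`` ordered grades.

    Reuses the MDLP discretizer on (scores, outcomes) with
    ``max_intervals = n_grades``; fails with an explicit error when the
    outcome rate carries too little structure to support the requested
    number of grades (e.g. a constant rate).
    """
    s = np.asarray(scores, dtype=float)
    if n_grades < 2:
        raise StratificationError("need at least 2 grades")
    if np.unique(s).size < n_grades:
        raise StratificationError(
            f"only {np.unique(s).size} distinct scores for {n_grades} grades"
        )
    cuts = discretize_indicator(s, np.asarray(outcomes), max_intervals=n_grades)
    if len(cuts) != n_grades - 1:
        raise StratificationError(
            f"entropy stratification supports only {len(cuts) + 1} grades "
            f"on these scores, not {n_grades} (outcome rate too flat)"
        )
    return GradeScheme(tuple(cuts), GRADE_LABELS[:n_grades])


@dataclass(frozen=True)
class ScoredRecord:
    """Per-indicator categories/points plus the weighted total and grade."""

    categories: Mapping[str, str]
    points: Mapping[str, int]
    total: float
    grade: str | None


@dataclass(frozen=True)
class ScoringSystem:
    """The complete fitted grading system (serializable artifact)."""

    schemes: tuple[DiscretizationScheme, ...]
    weights: WeightVector
    grades: GradeScheme | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        scheme_names = tuple(s.indicator for s in self.schemes)
        if scheme_names != self.weights.indicators:
            raise SystemSchemaError(
                "schemes and weights must cover identical indicators in order"
            )

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(s.indicator for s in self.schemes)

    def scheme(self, indicator: str) -> DiscretizationScheme:
        for s in self.schemes:
            if s.indicator == indicator:
                return s
        raise KeyError(indicator)


def score_record(record: Mapping[str, float], system: ScoringSystem) -> ScoredRecord:
    """Categorize, point-score and grade a single cleaned record."""
    cats: dict[str, str] = {}
    pts: dict[str, int] = {}
    total = 0.0
    for scheme, w in zip(system.schemes, system.weights.weights):
        name = scheme.indicator
        if name not in record or record[name] is None or (
            isinstance(record[name], float) and np.isnan(record[name])
        ):
            raise GradeError(f"record lacks indicator {name!r}")
        value = float(record[name])
        cats[name] = scheme.category_for(value)
        p = scheme.points_for(value)
        pts[name] = p
        total += w * p
    total = float(min(max(total, 1.0), 4.0))  # clear float noise at the bounds
    grade = None
    if system.grades is not None:
        grade = try_assign_grade(total, system.grades)
    return ScoredRecord(cats, pts, total, grade)


def score_cohort(cohort: CohortTable, system: ScoringSystem) -> pd.DataFrame:
    """Vectorized scoring of a cohort; one row per record.

    Columns: per-indicator points/category, ``total``, ``grade`` (empty
    when the system has no grade scheme).
    """
    out: dict[str, object] = {}
    total = np.zeros(cohort.n)
    for scheme, w in zip(system.schemes, system.weights.weights):
        name = scheme.indicator
        values = cohort.values(name)
        if np.isnan(values).any():
            raise GradeError(f"cohort column {name!r} contains missing values")
        idx = scheme.interval_indices(values)
        pts = np.asarray(scheme.points)[idx]
        out[f"{name}_points"] = pts
        out[f"{name}_category"] = np.asarray(scheme.categories)[idx]
        total += w * pts
    total = np.clip(total, 1.0, 4.0)  # clear float noise at the bounds
    out["total"] = total
    if system.grades is not None:
        out["grade"] = [try_assign_grade(t, system.grades) for t in total]
    frame = pd.DataFrame(out)
    if OUTCOME in cohort.data.columns:
        frame[OUTCOME] = cohort.outcome()
    return frame


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _scheme_to_dict(s: DiscretizationScheme) -> dict:
    return {
        "indicator": s.indicator,
        "cuts": list(s.cuts),
        "points": list(s.points),
        "categories": list(s.categories),
        "orientation": s.orientation,
        "labels": list(s.labels),
    }


def _scheme_from_dict(d: Mapping) -> DiscretizationScheme:
    return DiscretizationScheme(
        indicator=d["indicator"],
        cuts=tuple(d["cuts"]),
        points=tuple(d["points"]),
        categories=tuple(d["categories"]),
        orientation=d["orientation"],
        labels=tuple(d.get("labels", ())),
    )


def system_to_dict(system: ScoringSystem) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "schemes": [_scheme_to_dict(s) for s in system.schemes],
        "weights": {
            "indicators": list(system.weights.indicators),
            "weights": list(system.weights.weights),
            "provenance": dict(system.weights.provenance),
        },
        "grades": None
        if system.grades is None
        else {
            "thresholds": list(system.grades.thresholds),
            "labels": list(system.grades.labels),
        },
        "metadata": dict(system.metadata),
    }


def system_from_dict(payload: Mapping) -> ScoringSystem:
    if not isinstance(payload, Mapping) or "schema_version" not in payload:
        raise SystemSchemaError("not a scoring-system document (no schema_version)")
    version = payload["schema_version"]
    if version != SCHEMA_VERSION:
        raise SystemSchemaError(
            f"unsupported schema version {version!r}; this build reads "
            f"version {SCHEMA_VERSION}"
        )
    try:
        schemes = tuple(_scheme_from_dict(d) for d in payload["schemes"])
        w = payload["weights"]
        weights = WeightVector(
            tuple(w["indicators"]), tuple(w["weights"]), dict(w.get("provenance", {}))
        )
        grades = None
        if payload.get("grades") is not None:
            g = payload["grades"]
            grades = GradeScheme(
                tuple(None if t is None else float(t) for t in g["thresholds"]),
                tuple(g["labels"]),
            )
        metadata = dict(payload.get("metadata", {}))
    except (KeyError, TypeError) as exc:
        raise SystemSchemaError(f"malformed scoring-system document: {exc}") from exc
    return ScoringSystem(schemes, weights, grades, metadata)


def save_system(system: ScoringSystem, path: str | Path) -> None:
    """Write the system as schema-versioned, key-sorted JSON."""
    Path(path).write_text(
        json.dumps(system_to_dict(system), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def load_system(path: str | Path) -> ScoringSystem:
    """Read a system JSON; schema mismatch or truncation is fatal."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SystemSchemaError(f"{path}: not valid JSON ({exc})") from exc
    return system_from_dict(payload)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class BuildConfig:
    """Everything ``build_system`` needs, with pipeline defaults.

    ``seed`` is the single reproducibility knob: stage seeds are fanned
    out from it deterministically.
    """

    cleaning_rules: Sequence[CleaningRule] = field(
        default_factory=default_cleaning_rules
    )
    candidates: Sequence[str] = ()
    forced: Sequence[str] = ("bmi",)
    alpha: float = 0.01
    orientations: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ORIENTATIONS)
    )
    max_intervals: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MAX_INTERVALS)
    )
    n_trees: int = 500
    train_fraction: float = 0.8
    rf_on_points: bool = True
    n_grades: int = 5
    seed: int = 0
    allow_empty_intervals: bool = False


def build_system(cohort: CohortTable, config: BuildConfig) -> ScoringSystem:
    """Run clean -> screen -> discretize -> weight -> stratify.

    Rebuilding on an extended cohort is the dynamic-update path: the same
    call refreshes intervals, weights and grade thresholds without
    manual intervention.
    """
    rules = list(config.cleaning_rules)
    present = set(cohort.indicator_columns)
    rules = [r for r in rules if r.indicator in present]
    cleaned = cohort if cohort.provenance == "cleaned" else clean_cohort(cohort, rules)

    candidates = list(config.candidates) or cleaned.indicator_columns
    forced = [f for f in config.forced if f in candidates]
    screen = select_indicators(cleaned, candidates, config.alpha, forced)
    selected = [r.indicator for r in screen if r.selected]
    if not selected:
        raise StratificationError("no indicator survived the screen")

    outcome = cleaned.outcome()
    schemes: list[DiscretizationScheme] = []
    for name in selected:
        orientation = config.orientations.get(name, "monotone_increasing")
        if orientation == "fixed_who":
            schemes.append(who_bmi_scheme())
            continue
        values = cleaned.values(name)
        max_iv = config.max_intervals.get(
            orientation, DEFAULT_MAX_INTERVALS.get(orientation, 4)
        )
        cuts = discretize_indicator(values, outcome, max_intervals=max_iv)
        schemes.append(
            build_scheme(
                values,
                outcome,
                cuts,
                orientation,
                indicator=name,
                allow_empty=config.allow_empty_intervals,
            )
        )

    # Feature matrix for the forest: discretized points by default.
    if config.rf_on_points:
        feat = {
            s.indicator: np.asarray(s.points)[
                s.interval_indices(cleaned.values(s.indicator))
            ]
            for s in schemes
        }
    else:
        feat = {s.indicator: cleaned.values(s.indicator) for s in schemes}
    feat_frame = pd.DataFrame(feat)
    feat_frame[OUTCOME] = outcome
    feat_cohort = CohortTable(feat_frame, provenance="cleaned")
    weights = compute_weights(
        feat_cohort,
        [s.indicator for s in schemes],
        outcome=OUTCOME,
        train_fraction=config.train_fraction,
        n_trees=config.n_trees,
        seed=config.seed * 1009 % (2**31 - 1),
    )

    ungraded = ScoringSystem(tuple(schemes), weights, None, {})
    scored = score_cohort(cleaned, ungraded)
    grades = stratify_total_scores(
        scored["total"].to_numpy(), outcome, n_grades=config.n_grades
    )
    metadata = {
        "cohort_size": cleaned.n,
        "seed": config.seed,
        "n_grades": config.n_grades,
        "screen": [
            {
                "indicator": r.indicator,
                "F": r.f_statistic,
                "p": r.p_value,
                "selected": r.selected,
                "reason": r.reason,
            }
            for r in screen
        ],
    }
    return ScoringSystem(tuple(schemes), weights, grades, metadata)
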