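"""Seeded synthetic cohorts calibrated to the reference grading table.

No patient-level data accompany the published system, so every pipeline
stage is exercised on synthetic cohorts instead.  The generator draws
each indicator independently: an interval is chosen with the reference
table's marginal frequencies, then a value uniform within the interval
(open-ended extreme intervals are truncated at the plausible-range
bounds; count indicators draw integers).  The outcome is Bernoulli with
probability logistic in the record's weighted points score, with
intercept and slope calibrated once — deterministically, by weighted
least squares on the exact rest-score convolution — so that the
category-wise marginal pregnancy rates approximate the table's printed
rates and the score→rate relation is monotone.

``plant_structure`` swaps in user-planted rate change-points on chosen
indicators (values then uniform over the whole plausible range, outcome
rate piecewise-constant across the planted strata), which is what the
discretizer-recovery tests use.

The independence-by-interval assumption is a documented simplification:
real indicators are correlated (e.g. AMH with age), so passing tests
demonstrate procedure correctness, not clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .cohort import INTEGER_INDICATORS, OUTCOME, CohortTable
from .errors import SyntheticConfigError
from .reference import (
    REFERENCE_TABLE_COUNTS,
    reference_schemes,
    reference_system,
    reference_weights,
)

#: Plausible value bounds used to truncate open-ended intervals.
PLAUSIBLE_BOUNDS: Mapping[str, tuple[float, float]] = {
    "age": (18.0, 55.0),
    "bmi": (10.0, 60.0),
    "fsh": (0.0, 100.0),
    "afc": (0.0, 100.0),
    "amh": (0.0, 30.0),
    "oocytes": (0.0, 60.0),
    "emt": (0.0, 30.0),
}

#: Internal deterministic seed for the one-off calibration draw-free fit.
_CALIBRATION_GRID = 64


@dataclass(frozen=True)
class IndicatorModel:
    """Marginal sampling model for one indicator."""

    name: str
    bounds: tuple[float, float]
    cuts: tuple[float, ...]
    proportions: tuple[float, ...]
    integer: bool = False

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise SyntheticConfigError(
                f"{self.name}: cuts must be strictly increasing "
                "(overlapping intervals)"
            )
        if self.cuts and (
            self.cuts[0] <= self.bounds[0] or self.cuts[-1] >= self.bounds[1]
        ):
            raise SyntheticConfigError(
                f"{self.name}: cuts must lie strictly inside the bounds"
            )
        if len(self.proportions) != len(self.cuts) + 1:
            raise SyntheticConfigError(
                f"{self.name}: one proportion per interval required"
            )
        if any(p < 0 for p in self.proportions):
            raise SyntheticConfigError(f"{self.name}: negative proportion")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise SyntheticConfigError(f"{self.name}: proportions must sum to 1")

    def interval_bounds(self) -> list[tuple[float, float]]:
        edges = [self.bounds[0], *self.cuts, self.bounds[1]]
        return list(zip(edges[:-1], edges[1:]))


@dataclass(frozen=True)
class PlantedRates:
    """Piecewise-constant outcome rates across strata of one indicator."""

    cuts: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise SyntheticConfigError(
                "planted change-points must be strictly increasing "
                "(overlapping planted intervals)"
            )
        if len(self.rates) != len(self.cuts) + 1:
            raise SyntheticConfigError("one planted rate per stratum required")
        if any(not 0.0 < r < 1.0 for r in self.rates):
            raise SyntheticConfigError("planted rates must lie in (0, 1)")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic cohort draw."""

    n: int
    seed: int
    indicators: tuple[IndicatorModel, ...]
    logistic_intercept: float
    logistic_slope: float
    planted: Mapping[str, PlantedRates] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise SyntheticConfigError("cohort size must be non-negative")
        names = {m.name for m in self.indicators}
        unknown = set(self.planted) - names
        if unknown:
            raise SyntheticConfigError(f"planted overrides name unknown indicators: {sorted(unknown)}")


def _table_proportions(indicator: str) -> tuple[float, ...]:
    rows = REFERENCE_TABLE_COUNTS[indicator]
    totals = np.array([t for _, t, _ in rows], dtype=float)
    return tuple(totals / totals.sum())


def _points_distribution(indicator: str) -> np.ndarray:
    """P(points = 1..4) implied by the table's interval frequencies."""
    scheme = next(s for s in reference_schemes() if s.indicator == indicator)
    props = _table_proportions(indicator)
    dist = np.zeros(4)
    for p, w in zip(scheme.points, props):
        dist[p - 1] += w
    return dist


def _calibrate_logistic() -> tuple[float, float]:
    """Fit (intercept, slope) so category rates match the table.

    For each table cell (indicator i, interval j) the model's marginal
    pregnancy rate is E[sigmoid(a + b*(w_i*p_ij + R_i))], where R_i is
    the weighted points score of the other indicators.  R_i's exact
    distribution follows by discrete convolution of the per-indicator
    points distributions, so the fit is deterministic (no sampling).
    Cells are weighted by the square root of their frequency.
    """
    schemes = reference_schemes()
    w = reference_weights().as_dict()
    names = [s.indicator for s in schemes]
    dists = {n: _points_distribution(n) for n in names}
    pts = np.arange(1, 5, dtype=float)

    rest: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for excl in names:
        vals = np.zeros(1)
        probs = np.ones(1)
        for n in names:
            if n == excl:
                continue
            vals = (vals[:, None] + w[n] * pts[None, :]).ravel()
            probs = (probs[:, None] * dists[n][None, :]).ravel()
        rest[excl] = (vals, probs)

    cells: list[tuple[str, float, float, float]] = []  # (name, w*p, rate, freq)
    for scheme in schemes:
        props = _table_proportions(scheme.indicator)
        rows = REFERENCE_TABLE_COUNTS[scheme.indicator]
        for (label, total, preg), p, freq in zip(rows, scheme.points, props):
            if total == 0:
                continue
            cells.append(
                (scheme.indicator, w[scheme.indicator] * p, preg / total, freq)
            )

    weights = np.sqrt(np.array([c[3] for c in cells]))
    targets = np.array([c[2] for c in cells])

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b = theta
        pred = np.empty(len(cells))
        for i, (name, own, _, _) in enumerate(cells):
            vals, probs = rest[name]
            pred[i] = float(probs @ expit(a + b * (own + vals)))
        return weights * (pred - targets)

    overall = 15_021 / 60_648
    fit = least_squares(residuals, x0=[float(logit(overall)), 1.0], method="lm")
    a, b = fit.x
    return float(a), float(b)


_CALIBRATION_CACHE: dict[str, tuple[float, float]] = {}


def calibrated_logistic_params() -> tuple[float, float]:
    """Cached deterministic calibration of the outcome model."""
    if "ab" not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE["ab"] = _calibrate_logistic()
    return _CALIBRATION_CACHE["ab"]


def default_config(n: int, seed: int, slope_scale: float = 1.0) -> SyntheticConfig:
    """Table-calibrated configuration for a cohort of ``n`` records.

    ``slope_scale`` multiplies the calibrated logistic slope while
    pivoting around the expected score, so a larger slope steepens the
    score->rate relation (widening the gap between the best- and
    worst-grade pregnancy rates) without saturating the overall rate.
    """
    a, b = calibrated_logistic_params()
    if slope_scale != 1.0:
        w = reference_weights().as_dict()
        pts = np.arange(1, 5, dtype=float)
        mean_score = sum(
            w[name] * float(pts @ _points_distribution(name)) for name in w
        )
        a = a + b * mean_score * (1.0 - slope_scale)
    models = tuple(
        IndicatorModel(
            name=s.indicator,
            bounds=PLAUSIBLE_BOUNDS[s.indicator],
            cuts=s.cuts,
            proportions=_table_proportions(s.indicator),
            integer=s.indicator in INTEGER_INDICATORS,
        )
        for s in reference_schemes()
    )
    return SyntheticConfig(
        n=n,
        seed=seed,
        indicators=models,
        logistic_intercept=a,
        logistic_slope=b * slope_scale,
    )


def plant_structure(
    overrides: Mapping[str, PlantedRates | tuple],
    n: int = 10_000,
    seed: int = 0,
) -> SyntheticConfig:
    """Config with user-planted change-points for recovery tests.

    Planted indicators draw values uniformly over their plausible range
    and the outcome rate is the mean of the planted stratum rates across
    the planted indicators.  With no overrides the table-calibrated
    default config is returned.
    """
    base = default_config(n, seed)
    if not overrides:
        return base
    planted: dict[str, PlantedRates] = {}
    models = []
    for model in base.indicators:
        if model.name in overrides:
            ov = overrides[model.name]
            pr = ov if isinstance(ov, PlantedRates) else PlantedRates(*map(tuple, ov))
            lo, hi = PLAUSIBLE_BOUNDS[model.name]
            if pr.cuts and (pr.cuts[0] <= lo or pr.cuts[-1] >= hi):
                raise SyntheticConfigError(
                    f"{model.name}: planted change-points outside plausible range"
                )
            planted[model.name] = pr
            k = len(pr.rates)
            models.append(
                IndicatorModel(
                    name=model.name,
                    bounds=(lo, hi),
                    cuts=pr.cuts,
                    proportions=tuple([1.0 / k] * k),
                    integer=model.integer,
                )
            )
        else:
            models.append(model)
    unknown = set(overrides) - {m.name for m in base.indicators}
    if unknown:
        raise SyntheticConfigError(f"unknown indicators in overrides: {sorted(unknown)}")
    return SyntheticConfig(
        n=n,
        seed=seed,
        indicators=tuple(models),
        logistic_intercept=base.logistic_intercept,
        logistic_slope=base.logistic_slope,
        planted=planted,
    )


def _sample_indicator(
    model: IndicatorModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    k = len(model.proportions)
    idx = rng.choice(k, size=n, p=np.asarray(model.proportions))
    bounds = model.interval_bounds()
    lo = np.array([b[0] for b in bounds])[idx]
    hi = np.array([b[1] for b in bounds])[idx]
    if model.integer:
        lo_i = np.ceil(lo).astype(int)
        hi_i = np.floor(np.nextafter(hi, -np.inf)).astype(int)
        # closed top bound for the last interval
        top = idx == k - 1
        hi_i[top] = int(np.floor(model.bounds[1]))
        hi_i = np.maximum(hi_i, lo_i)
        return lo_i + (rng.random(n) * (hi_i - lo_i + 1)).astype(int)
    return lo + rng.random(n) * (hi - lo)


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw a reproducible cohort under ``config`` (seeded)."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    data: dict[str, np.ndarray] = {}
    for model in config.indicators:
        data[model.name] = _sample_indicator(model, n, rng)

    if n == 0:
        frame = pd.DataFrame({**{m.name: [] for m in config.indicators}, OUTCOME: []})
        frame[OUTCOME] = frame[OUTCOME].astype(int)
        return CohortTable(frame, provenance="raw")

    if config.planted:
        prob = np.zeros(n)
        for name, pr in config.planted.items():
            stratum = np.searchsorted(np.asarray(pr.cuts), data[name], side="right")
            prob += np.asarray(pr.rates)[stratum]
        prob /= len(config.planted)
    else:
        system = reference_system()
        total = np.zeros(n)
        for scheme, wgt in zip(system.schemes, system.weights.weights):
            idx = scheme.interval_indices(data[scheme.indicator])
            total += wgt * np.asarray(scheme.points)[idx]
        prob = expit(config.logistic_intercept + config.logistic_slope * total)

    outcome = (rng.random(n) < prob).astype(int)
    frame = pd.DataFrame(data)
    frame[OUTCOME] = outcome
    return CohortTable(frame, provenance="raw")
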