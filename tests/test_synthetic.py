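import numpy as np
import pandas as pd
import pytest

import fertigrade as fg
from fertigrade.synthetic import PLAUSIBLE_BOUNDS, calibrated_logistic_params


def test_empty_cohort():
    cohort = fg.generate_cohort(fg.default_config(0, seed=1))
    assert cohort.n == 0


def test_same_seed_is_reproducible():
    a = fg.generate_cohort(fg.default_config(500, seed=9))
    b = fg.generate_cohort(fg.default_config(500, seed=9))
    pd.testing.assert_frame_equal(a.data, b.data)
    c = fg.generate_cohort(fg.default_config(500, seed=10))
    assert not a.data.equals(c.data)


def test_category_frequencies_match_table_within_3se(ref_system):
    n = 60_000
    cohort = fg.generate_cohort(fg.default_config(n, seed=2))
    for scheme in ref_system.schemes:
        rows = fg.REFERENCE_TABLE_COUNTS[scheme.indicator]
        grand = sum(t for _, t, _ in rows)
        idx = scheme.interval_indices(cohort.values(scheme.indicator))
        observed = np.bincount(idx, minlength=scheme.n_intervals)
        for j, (_, total, _) in enumerate(rows):
            p = total / grand
            se = np.sqrt(max(p * (1 - p) / n, 1e-12))
            assert abs(observed[j] / n - p) <= 3 * se + 1e-9, (
                scheme.indicator,
                j,
            )


def test_calibrated_outcome_rate_is_plausible():
    cohort = fg.generate_cohort(fg.default_config(30_000, seed=3))
    overall = cohort.outcome().mean()
    # table overall pregnancy rate ~ 24.8%
    assert 0.20 < overall < 0.30
    a, b = calibrated_logistic_params()
    assert b > 0  # higher score, higher pregnancy probability


def test_planted_stratum_rates_within_3se():
    cuts, rates = (7.5, 15.0, 22.5), (0.05, 0.20, 0.35, 0.50)
    config = fg.plant_structure({"amh": (cuts, rates)}, n=40_000, seed=5)
    cohort = fg.generate_cohort(config)
    values = cohort.values("amh")
    outcome = cohort.outcome()
    strata = np.searchsorted(np.asarray(cuts), values, side="right")
    for j, r in enumerate(rates):
        mask = strata == j
        se = np.sqrt(r * (1 - r) / mask.sum())
        assert abs(outcome[mask].mean() - r) <= 3 * se


def test_no_overrides_returns_calibrated_default():
    base = fg.default_config(100, seed=0)
    assert fg.plant_structure({}, n=100, seed=0) == base
    assert not base.planted


def test_overlapping_planted_intervals_fatal():
    with pytest.raises(fg.SyntheticConfigError, match="increasing|overlap"):
        fg.plant_structure({"amh": ((10.0, 5.0), (0.1, 0.2, 0.3))}, n=100, seed=0)


def test_unknown_planted_indicator_fatal():
    with pytest.raises(fg.SyntheticConfigError):
        fg.plant_structure({"height": ((5.0,), (0.1, 0.2))}, n=100, seed=0)


def test_rate_count_mismatch_fatal():
    with pytest.raises(fg.SyntheticConfigError):
        fg.plant_structure({"amh": ((5.0,), (0.1, 0.2, 0.3))}, n=100, seed=0)


def test_values_respect_plausible_bounds():
    cohort = fg.generate_cohort(fg.default_config(5_000, seed=6))
    for name, (lo, hi) in PLAUSIBLE_BOUNDS.items():
        vals = cohort.values(name)
        assert vals.min() >= lo and vals.max() <= hi
    for name in fg.INTEGER_INDICATORS:
        vals = cohort.values(name)
        assert np.all(vals == np.round(vals))


def test_steeper_slope_widens_grade_rate_gap(ref_system):
    """Raising the outcome-model slope separates best and worst bands."""

    def gap(slope_scale, seed):
        cohort = fg.generate_cohort(
            fg.default_config(30_000, seed=seed, slope_scale=slope_scale)
        )
        ungraded = fg.ScoringSystem(ref_system.schemes, ref_system.weights, None, {})
        scored = fg.score_cohort(cohort, ungraded)
        y = cohort.outcome()
        best = scored["total"] > 3.84
        worst = scored["total"] <= 2.38
        return y[best].mean() - y[worst].mean()

    for seed in (11, 12):
        assert gap(2.0, seed) > gap(1.0, seed)


def test_pipeline_recovers_calibrated_boundaries(calibrated_cohort, ref_system):
    """build_system cuts land near the generator's true interval edges.

    Every recovered cut for a monotone indicator must lie within one
    adjacent-interval width of a true boundary (tolerance equal to the
    narrower neighbouring interval).
    """
    config = fg.BuildConfig(n_trees=60, n_grades=2, seed=7)
    system = fg.build_system(calibrated_cohort, config)
    for scheme in system.schemes:
        if not scheme.orientation.startswith("monotone"):
            continue
        true_scheme = ref_system.scheme(scheme.indicator)
        lo, hi = PLAUSIBLE_BOUNDS[scheme.indicator]
        edges = [lo, *true_scheme.cuts, hi]
        for cut in scheme.cuts:
            tolerances = []
            for b_idx, boundary in enumerate(true_scheme.cuts):
                width = min(
                    boundary - edges[b_idx], edges[b_idx + 2] - boundary
                )
                tolerances.append(abs(cut - boundary) <= width)
            assert any(tolerances), (scheme.indicator, cut)
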