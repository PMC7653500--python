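import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import fertigrade as fg
from fertigrade.system import system_to_dict, try_assign_grade

from conftest import invariant_build_config, make_invariant_cohort


# --- scoring algebra -------------------------------------------------------

BEST = dict(age=30, fsh=5, afc=15, amh=6.0, bmi=21.0, oocytes=13, emt=12.0)
WORST = dict(age=45, fsh=40, afc=1, amh=0.2, bmi=12.0, oocytes=0, emt=5.0)


def test_all_best_scores_four(ref_system):
    assert fg.score_record(BEST, ref_system).total == pytest.approx(4.0, abs=1e-9)


def test_all_worst_scores_one(ref_system):
    assert fg.score_record(WORST, ref_system).total == pytest.approx(1.0, abs=1e-9)


def test_single_deviation_weighted_means(ref_system):
    # AMH two points below best, published weight 16.16%
    amh_c = dict(BEST, amh=1.0)
    assert fg.score_record(amh_c, ref_system).total == pytest.approx(3.6768, abs=1e-6)
    # age one point below best, published weight 17.48%
    age_b = dict(BEST, age=36)
    assert fg.score_record(age_b, ref_system).total == pytest.approx(3.8252, abs=1e-6)


@given(
    st.fixed_dictionaries(
        {
            "age": st.floats(18, 55),
            "bmi": st.floats(10, 60),
            "fsh": st.floats(0, 100),
            "afc": st.integers(0, 100),
            "amh": st.floats(0, 30),
            "oocytes": st.integers(0, 60),
            "emt": st.floats(0, 30),
        }
    )
)
def test_total_is_convex_combination_of_points(ref_system, record):
    scored = fg.score_record(record, ref_system)
    assert min(scored.points.values()) <= scored.total <= max(scored.points.values())
    assert 1.0 <= scored.total <= 4.0


# --- grade assignment ------------------------------------------------------


def test_published_grade_endpoints(ref_system):
    grades = ref_system.grades
    assert fg.assign_grade(2.00, grades) == "E"
    assert fg.assign_grade(2.38, grades) == "E"  # upper-inclusive
    assert fg.assign_grade(3.90, grades) == "A"
    assert fg.assign_grade(4.00, grades) == "A"


def test_exact_intermediate_threshold_takes_lower_grade():
    grades = fg.GradeScheme((2.0, 2.5, 3.0, 3.5), ("A", "B", "C", "D", "E"))
    assert fg.assign_grade(2.5, grades) == "D"
    assert fg.assign_grade(2.5000001, grades) == "C"


def test_out_of_range_total_is_fatal(ref_system):
    with pytest.raises(fg.GradeError):
        fg.assign_grade(4.2, ref_system.grades)
    with pytest.raises(fg.GradeError):
        fg.assign_grade(0.5, ref_system.grades)


def test_unpublished_middle_band_unresolvable(ref_system):
    with pytest.raises(fg.GradeError, match="unpublished|unresolved"):
        fg.assign_grade(3.0, ref_system.grades)
    assert try_assign_grade(3.0, ref_system.grades) is None


# --- stratification --------------------------------------------------------


def test_two_cluster_scores_split_between_clusters():
    rng = np.random.default_rng(3)
    lo = rng.uniform(1.5, 2.0, 800)
    hi = rng.uniform(3.0, 3.5, 800)
    scores = np.r_[lo, hi]
    outcomes = np.r_[
        (rng.random(800) < 0.05).astype(int), (rng.random(800) < 0.60).astype(int)
    ]
    grades = fg.stratify_total_scores(scores, outcomes, n_grades=2)
    (threshold,) = grades.thresholds
    # the threshold separates the clusters: all low-cluster scores below,
    # essentially no high-cluster scores below (boundary-point cuts may
    # sit a hair inside the high cluster's edge)
    assert threshold > lo.max()
    assert np.mean(hi < threshold) < 0.01
    assert grades.labels == ("A", "B")


def test_five_grades_structure():
    rng = np.random.default_rng(4)
    scores = rng.uniform(1, 4, 6000).round(2)
    # four-level staircase in the score
    rate = np.asarray([0.05, 0.2, 0.35, 0.5])[np.digitize(scores, [1.75, 2.5, 3.25])]
    outcomes = (rng.random(6000) < rate).astype(int)
    grades = fg.stratify_total_scores(scores, outcomes, n_grades=4)
    assert len(grades.thresholds) == 3
    assert all(a < b for a, b in zip(grades.thresholds, grades.thresholds[1:]))
    assert all(1 < t < 4 for t in grades.thresholds)


def test_constant_rate_fails_gracefully():
    rng = np.random.default_rng(5)
    scores = rng.uniform(1, 4, 500)
    outcomes = (rng.random(500) < 0.3).astype(int)
    with pytest.raises(fg.StratificationError):
        fg.stratify_total_scores(scores, outcomes, n_grades=5)


def test_too_few_distinct_scores_fatal():
    with pytest.raises(fg.StratificationError):
        fg.stratify_total_scores([2.0, 3.0], [0, 1], n_grades=5)


# --- serialization ---------------------------------------------------------


def test_save_load_round_trip(ref_system, tmp_path):
    path = tmp_path / "system.json"
    fg.save_system(ref_system, path)
    loaded = fg.load_system(path)
    assert system_to_dict(loaded) == system_to_dict(ref_system)


def test_bundled_fixture_content(ref_system, tmp_path):
    path = tmp_path / "system.json"
    fg.save_system(ref_system, path)
    loaded = fg.load_system(path)
    assert len(loaded.schemes) == 7
    for name, pct in fg.REFERENCE_WEIGHTS_PCT.items():
        assert 100 * loaded.weights.as_dict()[name] == pytest.approx(pct, abs=0.005)


def test_truncated_file_is_schema_error(ref_system, tmp_path):
    path = tmp_path / "system.json"
    fg.save_system(ref_system, path)
    path.write_text(path.read_text()[: 40])
    with pytest.raises(fg.SystemSchemaError):
        fg.load_system(path)


def test_schema_version_mismatch(ref_system, tmp_path):
    payload = system_to_dict(ref_system)
    payload["schema_version"] = 99
    path = tmp_path / "system.json"
    path.write_text(json.dumps(payload))
    with pytest.raises(fg.SystemSchemaError, match="version"):
        fg.load_system(path)


# --- full pipeline ---------------------------------------------------------


def test_build_system_structure_and_determinism():
    cohort = make_invariant_cohort(n=1000, seed=2)
    config = invariant_build_config()
    sys1 = fg.build_system(cohort, config)
    sys2 = fg.build_system(cohort, config)
    assert json.dumps(system_to_dict(sys1), sort_keys=True) == json.dumps(
        system_to_dict(sys2), sort_keys=True
    )
    assert sum(sys1.weights.weights) == pytest.approx(1.0, abs=1e-9)
    for scheme in sys1.schemes:
        if scheme.orientation.startswith("monotone"):
            assert scheme.n_intervals <= 4


def test_dynamic_update_by_appending_records():
    cohort = make_invariant_cohort(n=600, seed=2)
    extra = make_invariant_cohort(n=200, seed=7)
    extended = fg.append_records(cohort, extra)
    system = fg.build_system(extended, invariant_build_config())
    assert system.metadata["cohort_size"] == 800


def test_grade_rates_increase_from_worst_to_best(ref_system, calibrated_cohort):
    """Grade-wise pregnancy rates rise from grade E to grade A.

    The fixture system scores a table-calibrated cohort; thresholds are
    refit on those totals since the fixture middles are unpublished.
    """
    ungraded = fg.ScoringSystem(ref_system.schemes, ref_system.weights, None, {})
    scored = fg.score_cohort(calibrated_cohort, ungraded)
    outcome = calibrated_cohort.outcome()
    grades = fg.stratify_total_scores(scored["total"].to_numpy(), outcome, n_grades=5)
    labels = [fg.assign_grade(t, grades) for t in scored["total"]]
    frame = pd.DataFrame({"grade": labels, "pregnant": outcome})
    rates = frame.groupby("grade")["pregnant"].mean()
    ordered = [rates[g] for g in reversed(grades.labels)]  # E ... A
    assert all(a < b for a, b in zip(ordered, ordered[1:]))
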