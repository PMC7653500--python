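import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fertigrade as fg
from fertigrade.discretize import DiscretizationScheme

from _oracle import oracle_cuts, oracle_entropy


# --- class entropy ---------------------------------------------------------


@pytest.mark.parametrize(
    "labels, expected",
    [
        ([1, 1, 1, 1], 0.0),
        ([0, 1], 1.0),
        ([1, 1, 0], 0.9182958340544896),
    ],
)
def test_entropy_closed_forms(labels, expected):
    assert fg.class_entropy(labels) == pytest.approx(expected, abs=1e-9)


def test_entropy_empty_is_fatal():
    with pytest.raises(fg.DiscretizationError):
        fg.class_entropy([])


@given(st.integers(0, 40), st.integers(0, 40))
def test_entropy_extremes_characterize_balance(pos, neg):
    if pos + neg == 0:
        return
    h = fg.class_entropy([1] * pos + [0] * neg)
    assert 0.0 <= h <= 1.0
    if pos == 0 or neg == 0:
        assert h == 0.0
    elif pos == neg:
        assert h == pytest.approx(1.0)
    else:
        assert h < 1.0
        assert h == pytest.approx(oracle_entropy(pos, pos + neg), abs=1e-12)


# --- evaluate_cut ----------------------------------------------------------


def test_perfect_separation_cut():
    split = fg.evaluate_cut([1, 2, 3, 4], [0, 0, 1, 1], 2.5)
    assert (split.n_left, split.n_right) == (2, 2)
    assert split.entropy_left == split.entropy_right == 0.0
    assert split.gain == pytest.approx(1.0)


def test_uneven_cut_weighted_entropy():
    split = fg.evaluate_cut([1, 2, 3, 4], [0, 0, 1, 1], 1.5)
    weighted = (1 / 4) * 0.0 + (3 / 4) * 0.9182958340544896
    assert weighted == pytest.approx(0.688722, abs=1e-6)
    assert split.gain == pytest.approx(1.0 - weighted, abs=1e-9)


def test_pure_labels_zero_gain_everywhere():
    for cut in (1.5, 2.5, 3.5):
        assert fg.evaluate_cut([1, 2, 3, 4], [1, 1, 1, 1], cut).gain == 0.0


def test_cut_outside_range_is_fatal():
    with pytest.raises(fg.DiscretizationError):
        fg.evaluate_cut([1, 2, 3], [0, 1, 0], 5.0)


# --- MDL acceptance --------------------------------------------------------


def test_mdlp_accepts_perfect_split():
    labels = [0, 0, 1, 1]
    split = fg.evaluate_cut([1, 2, 3, 4], labels, 2.5)
    # threshold = log2(3)/4 + (log2(7) - 2)/4 ~ 0.598 < gain 1.0
    threshold = math.log2(3) / 4 + (math.log2(7) - 2) / 4
    assert threshold == pytest.approx(0.5981, abs=1e-4)
    assert fg.mdlp_accept(split, labels)


def test_mdlp_rejects_zero_gain():
    labels = [1, 1, 1, 1]
    split = fg.evaluate_cut([1, 2, 3, 4], labels, 2.5)
    assert split.gain == 0.0
    assert not fg.mdlp_accept(split, labels)


@given(st.data())
def test_mdlp_decision_matches_direct_inequality(data):
    n = data.draw(st.integers(3, 12))
    values = data.draw(
        st.lists(st.integers(0, 6), min_size=n, max_size=n).map(
            lambda xs: [float(x) for x in xs]
        )
    )
    labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    v = np.asarray(values)
    if v.min() == v.max():
        return
    cut = (v.min() + v.max()) / 2
    if not (v.min() < cut < v.max()):
        return
    split = fg.evaluate_cut(values, labels, cut)
    # independent evaluation of the same inequality
    npar = len(labels)
    h = oracle_entropy(sum(labels), npar)
    k = 1 if sum(labels) in (0, npar) else 2
    left = [y for x, y in zip(values, labels) if x < cut]
    right = [y for x, y in zip(values, labels) if x >= cut]
    k1 = 1 if sum(left) in (0, len(left)) else 2
    k2 = 1 if sum(right) in (0, len(right)) else 2
    delta = math.log2(3**k - 2) - (
        k * h
        - k1 * oracle_entropy(sum(left), len(left))
        - k2 * oracle_entropy(sum(right), len(right))
    )
    expected = split.gain > math.log2(npar - 1) / npar + delta / npar
    assert fg.mdlp_accept(split, labels) == expected


# --- recursive discretization ---------------------------------------------


def test_constant_outcome_rate_yields_no_cuts():
    rng = np.random.default_rng(0)
    values = rng.uniform(0, 10, 400)
    labels = (rng.random(400) < 0.3).astype(int)
    # no relation between value and rate: MDLP should find nothing
    assert fg.discretize_indicator(values, labels, max_intervals=4) == []


def test_constant_values_yield_no_cuts():
    assert fg.discretize_indicator([3.0] * 10, [0, 1] * 5) == []


def test_planted_change_points_recovered():
    rng = np.random.default_rng(42)
    rates = [0.05, 0.15, 0.25, 0.35]
    values, labels = [], []
    for j, r in enumerate(rates):
        x = rng.uniform(10 * j, 10 * (j + 1), 2000)
        values.append(x)
        labels.append((rng.random(2000) < r).astype(int))
    values = np.concatenate(values)
    labels = np.concatenate(labels)
    cuts = fg.discretize_indicator(values, labels, max_intervals=4)
    assert len(cuts) == 3
    # each cut within one stratum width (10) of its true boundary
    for cut, true in zip(cuts, [10.0, 20.0, 30.0]):
        assert abs(cut - true) < 10.0


@given(st.data())
def test_small_instances_match_exhaustive_oracle(data):
    n = data.draw(st.integers(2, 12))
    values = data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
    labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    max_iv = data.draw(st.integers(2, 4))
    got = fg.discretize_indicator(
        [float(v) for v in values], labels, max_intervals=max_iv
    )
    expected = oracle_cuts(values, labels, max_iv)
    assert got == pytest.approx(expected)


# --- scheme construction ---------------------------------------------------


def _stratified_sample(rng, edges, rates, n_per):
    values, labels = [], []
    for (lo, hi), r in zip(zip(edges[:-1], edges[1:]), rates):
        x = rng.uniform(lo, hi, n_per)
        values.append(x)
        labels.append((rng.random(n_per) < r).astype(int))
    return np.concatenate(values), np.concatenate(labels)


def test_medium_indicator_unimodal_points():
    rng = np.random.default_rng(7)
    edges = [0, 3, 6, 11, 16, 31, 46, 60]
    rates = [0.05, 0.17, 0.29, 0.34, 0.23, 0.08, 0.02]
    values, labels = _stratified_sample(rng, edges, rates, 500)
    scheme = fg.build_scheme(
        values, labels, edges[1:-1], "medium", indicator="oocytes"
    )
    assert scheme.points == (1, 2, 3, 4, 3, 2, 1)
    assert scheme.categories == ("D", "C", "B", "A", "B", "C", "D")


def test_monotone_increasing_points():
    rng = np.random.default_rng(8)
    values, labels = _stratified_sample(
        rng, [0, 3, 7, 11, 30], [0.04, 0.11, 0.23, 0.29], 500
    )
    scheme = fg.build_scheme(values, labels, [3, 7, 11], "monotone_increasing")
    assert scheme.points == (1, 2, 3, 4)
    assert scheme.categories == ("D", "C", "B", "A")


def test_equal_rate_tie_prefers_larger_sample():
    # two intervals, identical rates, right interval larger -> higher points
    values = np.r_[np.zeros(10), np.ones(20)]
    labels = np.r_[np.tile([0, 1], 5), np.tile([0, 1], 10)]
    scheme = fg.build_scheme(values, labels, [0.5], "monotone_increasing")
    assert scheme.points == (3, 4)
    # mirrored: larger sample on the left -> decreasing profile
    values2 = np.r_[np.zeros(20), np.ones(10)]
    labels2 = np.r_[np.tile([0, 1], 10), np.tile([0, 1], 5)]
    scheme2 = fg.build_scheme(values2, labels2, [0.5], "monotone_decreasing")
    assert scheme2.points == (4, 3)


def test_empty_interval_is_fatal_without_fallback():
    values = np.array([1.0, 2.0, 10.0, 11.0])
    labels = np.array([0, 1, 0, 1])
    with pytest.raises(fg.DiscretizationError, match="zero records"):
        fg.build_scheme(values, labels, [3.0, 5.0, 9.0], "monotone_increasing")


@given(st.floats(allow_nan=False, allow_infinity=False, width=32))
def test_scheme_intervals_tile_the_line(ref_system, value):
    for scheme in ref_system.schemes:
        idx = scheme.interval_index(float(value))
        assert 0 <= idx < scheme.n_intervals


@pytest.mark.parametrize(
    "bmi, category, points",
    [(21.0, "A", 4), (27.0, "B", 3), (12.0, "D", 1), (16.0, "B", 3)],
)
def test_who_bmi_bands(bmi, category, points):
    scheme = fg.who_bmi_scheme()
    assert scheme.category_for(bmi) == category
    assert scheme.points_for(bmi) == points


def test_scheme_validation_rejects_inconsistent_profiles():
    with pytest.raises(fg.DiscretizationError):
        DiscretizationScheme(
            indicator="x",
            cuts=(1.0, 2.0),
            points=(1, 3, 2),
            categories=("D", "B", "C"),
            orientation="monotone_increasing",
        )
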