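"""Entropy-based supervised discretization with MDL stopping.

The discretizer recursively splits an indicator's range at the
boundary-point cut of maximal class-information gain, accepting a split
only when the gain clears the minimum-description-length criterion of
Fayyad & Irani.  Accepted cuts define half-open intervals [lo, hi); each
interval is then assigned a category letter A-D and 4-1 points from its
observed pregnancy rate, with a monotone points profile for indicators
whose prognosis improves (or worsens) steadily along the scale and a
unimodal profile for "medium-sized" indicators whose optimum lies in a
middle range (oocyte count, BMI).  BMI itself uses the fixed WHO bands
rather than data-driven cuts.

All entropies are in bits (log base 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DiscretizationError

ORIENTATIONS = ("monotone_increasing", "monotone_decreasing", "medium", "fixed_who")

_POINTS_TO_LETTER = {4: "A", 3: "B", 2: "C", 1: "D"}


def class_entropy(labels: Sequence[int]) -> float:
    """Shannon entropy of a label multiset in bits; 0*log0 == 0.

    For binary labels the value lies in [0, 1]: zero for a pure set,
    one when the classes are balanced.
    """
    y = np.asarray(labels)
    if y.size == 0:
        raise DiscretizationError("class_entropy of an empty multiset")
    _, counts = np.unique(y, return_counts=True)
    p = counts / y.size
    return float(-(p * np.log2(p)).sum()) + 0.0  # avoid -0.0 on pure sets


def _entropy_from_counts(pos: float, n: float) -> float:
    if n == 0:
        return 0.0
    p = pos / n
    h = 0.0
    if 0.0 < p < 1.0:
        h = -(p * math.log2(p) + (1 - p) * math.log2(1 - p))
    return h


@dataclass(frozen=True)
class EntropySplit:
    """A candidate binary partition of labelled values at ``cut``.

    Left is {v < cut}, right is {v >= cut}.  ``gain`` is the parent class
    entropy minus the size-weighted mean of the child entropies and is
    always >= 0.  ``n_classes_*`` count distinct outcome classes in each
    part (needed by the MDL acceptance rule).
    """

    cut: float
    n_left: int
    n_right: int
    entropy_left: float
    entropy_right: float
    gain: float
    n_classes_parent: int = 2
    n_classes_left: int = 1
    n_classes_right: int = 1


def evaluate_cut(
    values: Sequence[float], labels: Sequence[int], cut: float
) -> EntropySplit:
    """Evaluate one cut strictly inside the observed value range."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.size != y.size or v.size == 0:
        raise DiscretizationError("values and labels must be equal-length, non-empty")
    if not (v.min() < cut < v.max()):
        raise DiscretizationError(
            f"cut {cut} is not strictly inside the observed range "
            f"[{v.min()}, {v.max()}]"
        )
    left = y[v < cut]
    right = y[v >= cut]
    h_parent = class_entropy(y)
    h_left = class_entropy(left)
    h_right = class_entropy(right)
    n = v.size
    gain = h_parent - (left.size / n) * h_left - (right.size / n) * h_right
    return EntropySplit(
        cut=float(cut),
        n_left=int(left.size),
        n_right=int(right.size),
        entropy_left=h_left,
        entropy_right=h_right,
        gain=float(gain),
        n_classes_parent=int(np.unique(y).size),
        n_classes_left=int(np.unique(left).size),
        n_classes_right=int(np.unique(right).size),
    )


def mdlp_accept(split: EntropySplit, parent_labels: Sequence[int]) -> bool:
    """Fayyad-Irani MDL acceptance test for a candidate split.

    The split is kept iff

        gain > log2(N-1)/N + Delta/N,
        Delta = log2(3^k - 2) - [k*H(S) - k1*H(S1) - k2*H(S2)]

    where N is the parent size, k/k1/k2 the distinct class counts in the
    parent and the two children, and H the class entropies in bits.
    """
    y = np.asarray(parent_labels)
    n = y.size
    if n != split.n_left + split.n_right:
        raise DiscretizationError("split was not computed from parent_labels")
    if n < 2:
        return False
    h_parent = class_entropy(y)
    k = split.n_classes_parent
    k1, k2 = split.n_classes_left, split.n_classes_right
    delta = math.log2(3**k - 2) - (
        k * h_parent - k1 * split.entropy_left - k2 * split.entropy_right
    )
    threshold = math.log2(n - 1) / n + delta / n
    return split.gain > threshold


# ---------------------------------------------------------------------------
# Recursive discretization (vectorized over distinct-value blocks)
# ---------------------------------------------------------------------------


class _Blocks:
    """Distinct-value run-length view of a sorted labelled sample."""

    def __init__(self, values: np.ndarray, labels: np.ndarray):
        order = np.argsort(values, kind="mergesort")
        v = values[order]
        y = labels[order]
        starts = np.flatnonzero(np.r_[True, v[1:] != v[:-1]])
        ends = np.r_[starts[1:], v.size]
        self.uniq = v[starts]  # distinct values, ascending
        self.n = (ends - starts).astype(np.int64)  # block sizes
        pos = np.cumsum(y == 1)
        tot_pos = np.r_[0, pos][ends]
        self.pos = np.diff(np.r_[0, tot_pos])  # positives per block
        self.cum_n = np.cumsum(self.n)
        self.cum_pos = np.cumsum(self.pos)

    def seg_counts(self, b0: int, b1: int) -> tuple[int, int]:
        """Total size and positive count of blocks [b0, b1)."""
        n = self.cum_n[b1 - 1] - (self.cum_n[b0 - 1] if b0 > 0 else 0)
        p = self.cum_pos[b1 - 1] - (self.cum_pos[b0 - 1] if b0 > 0 else 0)
        return int(n), int(p)


def _vec_entropy(pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, pos / np.maximum(n, 1), 0.0)
        h = np.zeros_like(p, dtype=float)
        mask = (p > 0) & (p < 1)
        pm = p[mask]
        h[mask] = -(pm * np.log2(pm) + (1 - pm) * np.log2(1 - pm))
    return h


def _boundary_edges(blocks: _Blocks, b0: int, b1: int) -> np.ndarray:
    """Internal edges e (split before block e) that are class boundaries.

    An edge between adjacent distinct-value blocks is a boundary point
    unless both blocks are pure in the same class.
    """
    e = np.arange(b0 + 1, b1)
    if e.size == 0:
        return e
    ln, lp = blocks.n[e - 1], blocks.pos[e - 1]
    rn, rp = blocks.n[e], blocks.pos[e]
    left_pure0 = lp == 0
    left_pure1 = lp == ln
    right_pure0 = rp == 0
    right_pure1 = rp == rn
    same_pure = (left_pure0 & right_pure0) | (left_pure1 & right_pure1)
    return e[~same_pure]


def _best_split(blocks: _Blocks, b0: int, b1: int):
    """Best-gain boundary split of blocks [b0, b1); None if no candidate.

    Ties in gain break toward the smaller cut value (edges are scanned in
    ascending order and a strictly greater gain is required to displace
    the incumbent).
    """
    edges = _boundary_edges(blocks, b0, b1)
    if edges.size == 0:
        return None
    n_tot, p_tot = blocks.seg_counts(b0, b1)
    base = blocks.cum_n[b0 - 1] if b0 > 0 else 0
    base_p = blocks.cum_pos[b0 - 1] if b0 > 0 else 0
    n_left = blocks.cum_n[edges - 1] - base
    p_left = blocks.cum_pos[edges - 1] - base_p
    n_right = n_tot - n_left
    p_right = p_tot - p_left
    h_parent = _entropy_from_counts(p_tot, n_tot)
    h_l = _vec_entropy(p_left, n_left)
    h_r = _vec_entropy(p_right, n_right)
    gains = h_parent - (n_left * h_l + n_right * h_r) / n_tot
    i = int(np.argmax(gains))  # argmax returns the first (smallest cut) maximum
    e = int(edges[i])
    cut = (blocks.uniq[e - 1] + blocks.uniq[e]) / 2.0

    def n_classes(p: float, n: float) -> int:
        return 1 if (p == 0 or p == n) else 2

    split = EntropySplit(
        cut=float(cut),
        n_left=int(n_left[i]),
        n_right=int(n_right[i]),
        entropy_left=float(h_l[i]),
        entropy_right=float(h_r[i]),
        gain=float(gains[i]),
        n_classes_parent=n_classes(p_tot, n_tot),
        n_classes_left=n_classes(p_left[i], n_left[i]),
        n_classes_right=n_classes(p_right[i], n_right[i]),
    )
    return e, split


def _mdlp_accept_counts(split: EntropySplit, p_tot: int, n_tot: int) -> bool:
    h_parent = _entropy_from_counts(p_tot, n_tot)
    k = split.n_classes_parent
    delta = math.log2(3**k - 2) - (
        k * h_parent
        - split.n_classes_left * split.entropy_left
        - split.n_classes_right * split.entropy_right
    )
    threshold = math.log2(n_tot - 1) / n_tot + delta / n_tot
    return split.gain > threshold


def discretize_indicator(
    values: Sequence[float],
    labels: Sequence[int],
    max_intervals: int = 4,
) -> list[float]:
    """Recursive MDLP discretization; returns strictly increasing cuts.

    Candidate cuts are midpoints between adjacent distinct values whose
    class composition differs (boundary points).  Recursion continues on
    both sides of every accepted cut; when more than ``max_intervals - 1``
    cuts are accepted, only the highest-gain ones are kept.  Constant
    values yield an empty cut list.
    """
    if max_intervals < 2:
        raise DiscretizationError("max_intervals must be >= 2")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.size != y.size or v.size == 0:
        raise DiscretizationError("values and labels must be equal-length, non-empty")
    blocks = _Blocks(v, y)
    if blocks.uniq.size < 2:
        return []

    accepted: list[tuple[float, float]] = []  # (cut, gain) in acceptance order

    def recurse(b0: int, b1: int) -> None:
        if b1 - b0 < 2:
            return
        found = _best_split(blocks, b0, b1)
        if found is None:
            return
        e, split = found
        n_tot, p_tot = blocks.seg_counts(b0, b1)
        if n_tot < 2 or not _mdlp_accept_counts(split, p_tot, n_tot):
            return
        accepted.append((split.cut, split.gain))
        recurse(b0, e)
        recurse(e, b1)

    recurse(0, blocks.uniq.size)

    keep = accepted
    if len(keep) > max_intervals - 1:
        ranked = sorted(
            range(len(keep)), key=lambda i: (-keep[i][1], i)
        )[: max_intervals - 1]
        keep = [keep[i] for i in sorted(ranked)]
    return sorted(c for c, _ in keep)


# ---------------------------------------------------------------------------
# Interval schemes: categories, points, orientation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscretizationScheme:
    """Fitted interval scheme for one indicator.

    ``cuts`` define ``len(cuts) + 1`` half-open intervals [lo, hi) that
    tile the real line.  ``points`` (1-4, one per interval) encode the
    degree of abnormality: 4 is normal/best prognosis, 1 extreme.
    Category letters mirror the points (4=A ... 1=D).  ``labels`` are
    display names for report tables.
    """

    indicator: str
    cuts: tuple[float, ...]
    points: tuple[int, ...]
    categories: tuple[str, ...]
    orientation: str
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise DiscretizationError(f"unknown orientation {self.orientation!r}")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise DiscretizationError("cuts must be strictly increasing")
        if len(self.points) != len(self.cuts) + 1:
            raise DiscretizationError("need one points entry per interval")
        if len(self.categories) != len(self.points):
            raise DiscretizationError("need one category letter per interval")
        if any(p not in (1, 2, 3, 4) for p in self.points):
            raise DiscretizationError("points must be in {1, 2, 3, 4}")
        if self.labels and len(self.labels) != len(self.points):
            raise DiscretizationError("need one label per interval")
        if self.orientation == "monotone_increasing":
            ok = all(a <= b for a, b in zip(self.points, self.points[1:]))
        elif self.orientation == "monotone_decreasing":
            ok = all(a >= b for a, b in zip(self.points, self.points[1:]))
        else:  # medium / fixed_who: rise then fall (unimodal)
            peak = self.points.index(max(self.points))
            ok = all(
                a <= b for a, b in zip(self.points[: peak + 1], self.points[1 : peak + 1])
            ) and all(a >= b for a, b in zip(self.points[peak:], self.points[peak + 1 :]))
        if not ok:
            raise DiscretizationError(
                f"points profile {self.points} violates orientation "
                f"{self.orientation!r}"
            )

    @property
    def n_intervals(self) -> int:
        return len(self.points)

    def interval_index(self, value: float) -> int:
        """Index of the unique half-open interval containing ``value``."""
        return int(np.searchsorted(np.asarray(self.cuts), value, side="right"))

    def interval_indices(self, values: np.ndarray) -> np.ndarray:
        return np.searchsorted(np.asarray(self.cuts), values, side="right")

    def points_for(self, value: float) -> int:
        return self.points[self.interval_index(value)]

    def category_for(self, value: float) -> str:
        return self.categories[self.interval_index(value)]

    def interval_labels(self) -> tuple[str, ...]:
        if self.labels:
            return self.labels
        edges = [-math.inf, *self.cuts, math.inf]
        out = []
        for lo, hi in zip(edges, edges[1:]):
            if math.isinf(lo):
                out.append(f"< {hi:g}")
            elif math.isinf(hi):
                out.append(f">= {lo:g}")
            else:
                out.append(f"[{lo:g}, {hi:g})")
        return tuple(out)


def _interval_stats(
    values: np.ndarray, labels: np.ndarray, cuts: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    idx = np.searchsorted(np.asarray(cuts, dtype=float), values, side="right")
    k = len(cuts) + 1
    totals = np.bincount(idx, minlength=k).astype(int)
    pregnant = np.bincount(idx, weights=labels, minlength=k).astype(int)
    return totals, pregnant


def _monotone_points(rates: np.ndarray, totals: np.ndarray) -> list[int]:
    k = rates.size
    first, last = rates[0], rates[-1]
    if first == last:
        # Equal-rate tie: the side with the larger sample gets the higher
        # points (deterministic tie rule).
        increasing = totals[-1] >= totals[0]
    else:
        increasing = last > first
    # Best interval gets 4 points; each step away decreases by 1, floor 1.
    pts = [max(1, 4 - d) for d in range(k)][::-1]  # ascending toward the end
    return pts if increasing else pts[::-1]


def _medium_points(rates: np.ndarray, totals: np.ndarray) -> list[int]:
    best = np.max(rates)
    tied = np.flatnonzero(rates == best)
    # Rate tie at the peak: larger sample wins, then the smaller index.
    peak = int(tied[np.argmax(totals[tied])])
    return [max(1, 4 - abs(i - peak)) for i in range(rates.size)]


def build_scheme(
    values: Sequence[float],
    labels: Sequence[int],
    cuts: Sequence[float],
    orientation: str,
    indicator: str = "",
    interval_labels: Sequence[str] = (),
    allow_empty: bool = False,
) -> DiscretizationScheme:
    """Assign categories/points to intervals from observed pregnancy rates.

    Monotone orientations receive a monotone 1-4 profile directed by the
    end-interval rates; the medium orientation puts 4 points on the
    maximum-rate interval and decreases points symmetrically outward
    (e.g. 1,2,3,4,3,2,1 over 7 intervals).  An interval with zero records
    is fatal unless ``allow_empty``.
    """
    if orientation not in ORIENTATIONS:
        raise DiscretizationError(f"unknown orientation {orientation!r}")
    if orientation == "fixed_who":
        raise DiscretizationError("use who_bmi_scheme() for the fixed WHO bands")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    cuts = tuple(float(c) for c in cuts)
    totals, pregnant = _interval_stats(v, y, cuts)
    if not allow_empty and (totals == 0).any():
        raise DiscretizationError(
            f"{indicator or 'indicator'}: interval with zero records "
            f"(totals {totals.tolist()}); configure a fallback or revise cuts"
        )
    with np.errstate(invalid="ignore"):
        rates = np.where(totals > 0, pregnant / np.maximum(totals, 1), -1.0)

    if orientation == "medium":
        pts = _medium_points(rates, totals)
    else:
        # The declared tag picks the monotone family; the realized
        # direction follows the observed rates (and the sample-size tie
        # rule), so the stored orientation reflects the data.
        pts = _monotone_points(rates, totals)
        orientation = (
            "monotone_increasing" if pts[-1] >= pts[0] else "monotone_decreasing"
        )
    cats = tuple(_POINTS_TO_LETTER[p] for p in pts)
    return DiscretizationScheme(
        indicator=indicator,
        cuts=cuts,
        points=tuple(pts),
        categories=cats,
        orientation=orientation,
        labels=tuple(interval_labels),
    )


def who_bmi_scheme() -> DiscretizationScheme:
    """Fixed BMI scheme on the WHO bands (normal 18.5-25 is best).

    Pregnancy rate varies little with BMI, so entropy splitting is not
    applicable; the bands and their unimodal 1-4 points profile are fixed.
    """
    return DiscretizationScheme(
        indicator="bmi",
        cuts=(13.0, 15.0, 18.5, 25.0, 35.0, 40.0),
        points=(1, 2, 3, 4, 3, 2, 1),
        categories=("D", "C", "B", "A", "B", "C", "D"),
        orientation="fixed_who",
        labels=("<13.0", "13.0-14.9", "15.0-18.4", "18.5-24.9",
                "25.0-34.9", "35.0-39.9", ">=40.0"),
    )
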