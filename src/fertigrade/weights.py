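"""Indicator weights from random-forest out-of-bag permutation importance.

A bagged forest of CART trees is grown on a stratified 80/20 split of
the cohort.  For every tree, the records left out of its bootstrap
sample (the out-of-bag set) provide an honest accuracy estimate; the
importance of a feature is the mean decrease in that out-of-bag accuracy
when the feature's values are permuted (the classic unscaled
mean-decrease-in-accuracy measure).  Negative raw importances are floored
at zero and the vector is normalized to sum to one — these normalized
importances are the indicator weights of the grading system.  The forest
itself is never shipped as a predictor; only its importances are used.

By default the forest sees the discretized 1-4 points of each indicator,
not the raw values, since discretization precedes weight determination
in the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .cohort import CohortTable
from .errors import WeightError


@dataclass(frozen=True)
class WeightVector:
    """Normalized per-indicator weights plus fitting provenance."""

    indicators: tuple[str, ...]
    weights: tuple[float, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.indicators) != len(self.weights):
            raise WeightError("one weight per indicator required")
        if any(w < 0 for w in self.weights):
            raise WeightError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise WeightError("weights must sum to 1 within 1e-9")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.indicators, self.weights))

    def __getitem__(self, indicator: str) -> float:
        return self.as_dict()[indicator]


def normalize_weights(
    raw: Sequence[float],
    indicators: Sequence[str] | None = None,
    provenance: Mapping[str, object] | None = None,
) -> WeightVector:
    """Divide a non-negative importance vector by its total."""
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0:
        raise WeightError("empty importance vector")
    if (arr < 0).any():
        raise WeightError("raw importances must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise WeightError("all importances are zero; weights are undefined")
    names = tuple(indicators) if indicators else tuple(f"f{i}" for i in range(arr.size))
    return WeightVector(names, tuple(arr / total), dict(provenance or {}))


def _canonical_order(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Stable row order independent of input record order."""
    return np.lexsort((y, *reversed(x.T)))


def _forest_oob_importance(
    x: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Raw OOB permutation importances and ensemble OOB accuracy."""
    n, p = x.shape
    drops = np.zeros(p)
    drop_counts = np.zeros(p)
    votes = np.zeros((n, 2))
    max_features = max(1, int(round(np.sqrt(p))))
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[boot] = True
        oob = np.flatnonzero(~in_bag)
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(x[boot], y[boot])
        if oob.size == 0:
            continue
        pred = tree.predict(x[oob])
        votes[oob, 0] += pred == 0
        votes[oob, 1] += pred == 1
        base_acc = float(np.mean(pred == y[oob]))
        for j in range(p):
            xp = x[oob].copy()
            xp[:, j] = xp[rng.permutation(oob.size), j]
            perm_acc = float(np.mean(tree.predict(xp) == y[oob]))
            drops[j] += base_acc - perm_acc
            drop_counts[j] += 1
    if not drop_counts.all():
        raise WeightError("a feature received no out-of-bag evaluations")
    seen = votes.sum(axis=1) > 0
    oob_pred = np.argmax(votes[seen], axis=1)
    oob_accuracy = float(np.mean(oob_pred == y[seen])) if seen.any() else float("nan")
    return drops / drop_counts, oob_accuracy


def _ensemble_accuracy(
    trees_x: np.ndarray, trees_y: np.ndarray, test_x: np.ndarray,
    test_y: np.ndarray, n_trees: int, rng: np.random.Generator,
) -> float:
    """Held-out accuracy of a fresh forest vote (diagnostic only)."""
    n = trees_x.shape[0]
    votes = np.zeros((test_x.shape[0], 2))
    max_features = max(1, int(round(np.sqrt(trees_x.shape[1]))))
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(trees_x[boot], trees_y[boot])
        pred = tree.predict(test_x)
        votes[np.arange(test_x.shape[0]), pred.astype(int)] += 1
    return float(np.mean(np.argmax(votes, axis=1) == test_y))


def compute_weights(
    cohort: CohortTable,
    system_features: Sequence[str],
    outcome: str = "pregnant",
    train_fraction: float = 0.8,
    n_trees: int = 500,
    seed: int = 0,
    holdout_diagnostic: bool = False,
) -> WeightVector:
    """Fit the forest and return normalized OOB permutation importances.

    The split is stratified on the outcome.  Rows are put into a
    canonical sort order first so the result depends only on the multiset
    of records, not their order in the file.  Constant features get
    weight zero with a warning; an all-zero importance vector is fatal.
    """
    if not 0.0 < train_fraction < 1.0:
        raise WeightError("train_fraction must lie in (0, 1)")
    if n_trees < 1:
        raise WeightError("need at least one tree")
    features = list(system_features)
    if not features:
        raise WeightError("empty feature list")
    missing = [f for f in features if f not in cohort.data.columns]
    if missing:
        raise WeightError(f"features absent from cohort: {missing}")

    x = cohort.data[features].to_numpy(dtype=float)
    y = cohort.data[outcome].to_numpy(dtype=int)
    order = _canonical_order(x, y)
    x, y = x[order], y[order]

    constant = [f for f, col in zip(features, x.T) if np.all(col == col[0])]
    if constant:
        warnings.warn(
            f"constant features receive weight 0: {constant}", stacklevel=2
        )

    rng = np.random.default_rng(seed)
    split_seed = int(rng.integers(2**31 - 1))
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, train_size=train_fraction, stratify=y, random_state=split_seed
    )
    raw, oob_acc = _forest_oob_importance(x_tr, y_tr, n_trees, rng)
    raw = np.maximum(raw, 0.0)
    for f in constant:
        raw[features.index(f)] = 0.0
    if raw.sum() <= 0:
        raise WeightError("all features have zero importance; cannot weight")

    provenance: dict[str, object] = {
        "n_trees": n_trees,
        "seed": seed,
        "train_fraction": train_fraction,
        "n_train": int(y_tr.size),
        "n_test": int(y_te.size),
        "oob_accuracy": oob_acc,
        "raw_importances": {f: float(v) for f, v in zip(features, raw)},
    }
    if holdout_diagnostic:
        provenance["holdout_accuracy"] = _ensemble_accuracy(
            x_tr, y_tr, x_te, y_te, n_trees, np.random.default_rng(seed + 1)
        )
    return normalize_weights(raw, features, provenance)
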