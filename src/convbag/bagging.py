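"""Bootstrap-aggregated classification with sign-of-sum voting.

The ensemble trains ``T`` base learners on independent bootstrap resamples of
an ``n x d`` feature matrix with labels in {-1, +1} and combines them as

    H(x) = sign( sum_i h_i(x) ),

a plain majority vote.  A zero vote sum (possible only for even ``T``) breaks
to +1 — in the clinical framing the positive class is the event of interest,
so ties are resolved conservatively for recall — and is counted in a reported
tie statistic.

The default base learner is a depth-limited CART: Gini-impurity splits over
axis-aligned midpoint thresholds, majority-label leaves with ties to +1.  Any
object exposing ``fit(X, y)`` / ``predict(X) -> {-1,+1}`` qualifies as a base
learner, so externally supplied classifiers can be bagged as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from .errors import ConfigurationError, DegenerateLabelError

__all__ = ["LabeledFeatureSet", "BaseLearner", "CartTree", "EnsembleModel",
           "bootstrap_sample", "bootstrap_indices", "fit_bagging", "vote_predict",
           "fit_decision_tree", "gini_impurity"]

_SEED_CAP = 2**31 - 1


@dataclass
class LabeledFeatureSet:
    """Feature matrix plus labels restricted to the {-1, +1} convention."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ConfigurationError(f"X must be 2-D, got shape {self.X.shape}")
        if len(self.y) != len(self.X):
            raise ConfigurationError("X and y lengths differ")
        if not np.isin(self.y, (-1, 1)).all():
            raise ConfigurationError("labels must be -1 or +1")
        self.y = self.y.astype(np.int64)

    @property
    def n(self) -> int:
        return len(self.X)

    def subset(self, idx: np.ndarray) -> "LabeledFeatureSet":
        return LabeledFeatureSet(self.X[idx], self.y[idx])


@runtime_checkable
class BaseLearner(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaseLearner": ...
    def predict(self, X: np.ndarray) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# CART base learner
# ---------------------------------------------------------------------------

def gini_impurity(n_pos: float, n_neg: float) -> float:
    """Gini impurity 1 - p+^2 - p-^2 of a node with the given label counts."""
    total = n_pos + n_neg
    if total == 0:
        return 0.0
    p = n_pos / total
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def _best_split(X: np.ndarray, pos: np.ndarray, min_leaf: int):
    """Exhaustive midpoint split search, vectorised over features.

    Returns (feature, threshold) or None.  Ties in weighted impurity break to
    the lowest feature index, then the smallest split position.
    """
    n, p = X.shape
    if n < 2 * min_leaf:
        return None
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    ys = pos[order]
    cum_pos = np.cumsum(ys, axis=0)
    total_pos = cum_pos[-1]

    sizes = np.arange(1, n, dtype=np.float64)[:, None]          # left sizes
    left_pos = cum_pos[:-1]
    right_pos = total_pos[None, :] - left_pos
    right_sizes = n - sizes
    p_l = left_pos / sizes
    p_r = right_pos / right_sizes
    g_l = 1.0 - p_l**2 - (1.0 - p_l) ** 2
    g_r = 1.0 - p_r**2 - (1.0 - p_r) ** 2
    weighted = (sizes * g_l + right_sizes * g_r) / n

    valid = (sizes >= min_leaf) & (right_sizes >= min_leaf) & (Xs[:-1] < Xs[1:])
    if not valid.any():
        return None
    weighted = np.where(valid, weighted, np.inf)
    flat = np.argmin(weighted.T)            # feature-major: lowest feature wins ties
    feat, split = divmod(flat, n - 1)
    parent = gini_impurity(float(total_pos[feat]), float(n - total_pos[feat]))
    if weighted.T.flat[flat] >= parent - 1e-12:
        return None                         # no impurity decrease
    thr = 0.5 * (Xs[split, feat] + Xs[split + 1, feat])
    return int(feat), float(thr)


class CartTree:
    """Binary CART classifier over {-1, +1} labels.

    Splits minimise weighted Gini impurity; split values are midpoints of
    adjacent sorted feature values; growth stops at ``max_depth``, when a
    child would fall under ``min_leaf`` rows, or when a node is pure.  Leaves
    predict the majority label, ties going to +1.

    ``max_features`` optionally restricts each split search to a random
    subset of that many features (drawn with ``seed``), which decorrelates
    bagged trees and counteracts masking of weak features by strong ones;
    the default considers every feature at every split.
    """

    def __init__(self, max_depth: int = 8, min_leaf: int = 5,
                 max_features: int | None = None, seed: int = 0):
        if max_depth < 0 or min_leaf < 1:
            raise ConfigurationError("max_depth must be >= 0 and min_leaf >= 1")
        if max_features is not None and max_features < 1:
            raise ConfigurationError("max_features must be >= 1 when given")
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.max_features = max_features
        self.seed = seed
        self.feature: np.ndarray | None = None

    # -- fitting -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "CartTree":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if len(X) < 1:
            raise ConfigurationError("cannot fit a tree on an empty dataset")
        p = X.shape[1]
        mtry = p if self.max_features is None else min(self.max_features, p)
        rng = np.random.default_rng(self.seed)
        feature: list[int] = []
        threshold: list[float] = []
        left: list[int] = []
        right: list[int] = []
        value: list[int] = []

        def leaf_label(rows: np.ndarray) -> int:
            s = int(y[rows].sum())
            return 1 if s >= 0 else -1

        def build(rows: np.ndarray, depth: int) -> int:
            idx = len(feature)
            feature.append(-1)
            threshold.append(np.nan)
            left.append(-1)
            right.append(-1)
            value.append(leaf_label(rows))
            pure = np.all(y[rows] == y[rows[0]])
            if pure or depth >= self.max_depth:
                return idx
            if mtry < p:
                cand = np.sort(rng.choice(p, size=mtry, replace=False))
            else:
                cand = np.arange(p)
            split = _best_split(
                X[np.ix_(rows, cand)], (y[rows] > 0).astype(np.float64), self.min_leaf
            )
            if split is None:
                return idx
            f, thr = split
            f = int(cand[f])
            go_left = X[rows, f] <= thr
            feature[idx] = f
            threshold[idx] = thr
            left[idx] = build(rows[go_left], depth + 1)
            right[idx] = build(rows[~go_left], depth + 1)
            return idx

        build(np.arange(len(X)), 0)
        self.feature = np.asarray(feature, dtype=np.int64)
        self.threshold = np.asarray(threshold, dtype=np.float64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.value = np.asarray(value, dtype=np.int64)
        return self

    @property
    def depth(self) -> int:
        if self.feature is None:
            return 0
        d = np.zeros(len(self.feature), dtype=int)
        for i in range(len(self.feature)):
            if self.feature[i] >= 0:
                d[self.left[i]] = d[i] + 1
                d[self.right[i]] = d[i] + 1
        return int(d.max())

    # -- prediction --------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.feature is None:
            raise ConfigurationError("tree is not fitted")
        X = np.asarray(X, dtype=np.float64)
        n = len(X)
        cur = np.zeros(n, dtype=np.int64)
        rows = np.arange(n)
        while True:
            internal = self.feature[cur] >= 0
            if not internal.any():
                break
            idx = rows[internal]
            nodes = cur[idx]
            go_left = X[idx, self.feature[nodes]] <= self.threshold[nodes]
            cur[idx] = np.where(go_left, self.left[nodes], self.right[nodes])
        return self.value[cur]

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "max_depth": self.max_depth,
            "min_leaf": self.min_leaf,
            "max_features": self.max_features,
            "seed": self.seed,
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CartTree":
        tree = cls(d["max_depth"], d["min_leaf"],
                   d.get("max_features"), d.get("seed", 0))
        tree.feature = np.asarray(d["feature"], dtype=np.int64)
        tree.threshold = np.asarray(d["threshold"], dtype=np.float64)
        tree.left = np.asarray(d["left"], dtype=np.int64)
        tree.right = np.asarray(d["right"], dtype=np.int64)
        tree.value = np.asarray(d["value"], dtype=np.int64)
        return tree


def fit_decision_tree(
    dataset: LabeledFeatureSet, max_depth: int = 8, min_leaf: int = 5
) -> CartTree:
    """Fit the default CART base learner on a labelled feature set."""
    return CartTree(max_depth, min_leaf).fit(dataset.X, dataset.y)


# ---------------------------------------------------------------------------
# bootstrap + voting
# ---------------------------------------------------------------------------

def bootstrap_indices(n: int, seed: int) -> np.ndarray:
    """n draws with replacement from range(n); deterministic per seed."""
    if n < 1:
        raise ConfigurationError("cannot bootstrap an empty dataset")
    return np.random.default_rng(seed).integers(0, n, size=n)


def bootstrap_sample(dataset: LabeledFeatureSet, seed: int) -> LabeledFeatureSet:
    """One bootstrap resample (size n, with replacement) of the dataset."""
    return dataset.subset(bootstrap_indices(dataset.n, seed))


@dataclass
class EnsembleModel:
    learners: list = field(repr=False)
    bootstrap_seeds: list[int] = field(default_factory=list)
    n_features: int = 0

    @property
    def T(self) -> int:
        return len(self.learners)


def fit_bagging(
    dataset: LabeledFeatureSet,
    T: int = 21,
    learner_factory: Callable[[], BaseLearner] | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Train ``T`` base learners on independent bootstrap resamples.

    Learners are trained independently of one another (the result cannot
    depend on execution order); a factory failure aborts with the replicate
    index.
    """
    if T < 1:
        raise ConfigurationError(f"T must be >= 1, got {T}")
    if len(np.unique(dataset.y)) < 2:
        raise DegenerateLabelError("bagging requires both labels present")
    if learner_factory is None:
        learner_factory = lambda: CartTree(max_depth=8, min_leaf=5)  # noqa: E731
    seeds = np.random.default_rng(seed).integers(0, _SEED_CAP, size=T)
    learners = []
    for i, s in enumerate(seeds):
        sample = bootstrap_sample(dataset, int(s))
        try:
            learner = learner_factory()
            learner.fit(sample.X, sample.y)
        except Exception as exc:  # pragma: no cover - contract path
            raise ConfigurationError(f"base learner {i} failed: {exc}") from exc
        learners.append(learner)
    return EnsembleModel(
        learners=learners,
        bootstrap_seeds=[int(s) for s in seeds],
        n_features=dataset.X.shape[1],
    )


def vote_predict(
    model: EnsembleModel, X: np.ndarray, return_details: bool = False
):
    """Sign-of-sum majority vote over the ensemble.

    A zero vote sum breaks to +1 and is counted; with ``return_details`` the
    vote sums and the tie count are returned alongside the labels.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ConfigurationError(
            f"expected {model.n_features} feature columns, got shape {X.shape}"
        )
    votes = np.zeros(len(X), dtype=np.int64)
    for learner in model.learners:
        votes += np.asarray(learner.predict(X), dtype=np.int64)
    labels = np.where(votes >= 0, 1, -1).astype(np.int64)
    n_ties = int(np.sum(votes == 0))
    if return_details:
        return labels, votes, n_ties
    return labels
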