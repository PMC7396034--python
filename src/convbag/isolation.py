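"""Isolation forest for screening gross recording errors out of a cohort.

Anomalies are points that are easy to isolate by random axis-aligned cuts.
Each tree recursively picks a uniform-random feature and a uniform-random
split value within the node's range until a point is alone or the height
limit ``ceil(log2 psi)`` is reached, where ``psi`` is the per-tree subsample
size.  The anomaly score of a point x over a forest is

    s(x) = 2 ** ( -E[h(x)] / c(psi) )

with h(x) the path length (extended below external nodes by the average
unsuccessful-search length ``c(size)`` of the node) and

    c(m) = 2 * H(m - 1) - 2 * (m - 1) / m,    H(i) = ln(i) + Euler gamma,

for m >= 2 and c(m) = 0 otherwise.  Scores lie in (0, 1); values near 1 mark
points isolated far earlier than average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, SchemaError
from .tables import FeatureTable

__all__ = ["average_path_length", "IsolationForestModel", "fit_isolation_forest",
           "anomaly_scores", "anomaly_filter", "OutlierReport"]

_EULER_GAMMA = 0.5772156649015329


def average_path_length(m: float) -> float:
    """Average unsuccessful-search path length ``c(m)`` in a binary tree of m points."""
    if m < 2:
        return 0.0
    return 2.0 * (math.log(m - 1.0) + _EULER_GAMMA) - 2.0 * (m - 1.0) / m


@dataclass
class _Tree:
    """Flat-array binary partition tree.

    ``feature[i] < 0`` marks an external node; ``size[i]`` is the number of
    training points that reached node i (used for the path-length extension).
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    size: np.ndarray

    def path_lengths(self, X: np.ndarray) -> np.ndarray:
        n = len(X)
        node = np.zeros(n, dtype=np.int64)
        depth = np.zeros(n, dtype=np.float64)
        while True:
            internal = self.feature[node] >= 0
            if not internal.any():
                break
            idx = np.where(internal)[0]
            cur = node[idx]
            go_left = X[idx, self.feature[cur]] < self.threshold[cur]
            node[idx] = np.where(go_left, self.left[cur], self.right[cur])
            depth[idx] += 1.0
        ext = np.array([average_path_length(s) for s in self.size[node]])
        return depth + ext


def _grow_tree(X: np.ndarray, height_limit: int, rng: np.random.Generator) -> _Tree:
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    size: list[int] = []

    def build(rows: np.ndarray, depth: int) -> int:
        idx = len(feature)
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        size.append(len(rows))
        if len(rows) <= 1 or depth >= height_limit:
            return idx
        sub = X[rows]
        lo, hi = sub.min(axis=0), sub.max(axis=0)
        splittable = np.where(hi > lo)[0]
        if splittable.size == 0:  # all remaining points identical
            return idx
        f = int(rng.choice(splittable))
        v = float(rng.uniform(lo[f], hi[f]))
        go_left = sub[:, f] < v
        if not go_left.any() or go_left.all():
            # uniform() can hit the boundary; nudge to the midpoint
            v = float((lo[f] + hi[f]) / 2.0)
            go_left = sub[:, f] < v
        feature[idx] = f
        threshold[idx] = v
        left[idx] = build(rows[go_left], depth + 1)
        right[idx] = build(rows[~go_left], depth + 1)
        return idx

    build(np.arange(len(X)), 0)
    return _Tree(
        np.asarray(feature, dtype=np.int64),
        np.asarray(threshold, dtype=np.float64),
        np.asarray(left, dtype=np.int64),
        np.asarray(right, dtype=np.int64),
        np.asarray(size, dtype=np.int64),
    )


@dataclass
class IsolationForestModel:
    n_trees: int
    subsample_size: int
    height_limit: int
    contamination: float
    column_names: list[str]
    trees: list[_Tree] = field(repr=False)

    def max_depth(self) -> int:
        """Deepest internal split over all trees (<= height_limit by construction)."""
        deepest = 0
        for t in self.trees:
            depth = np.zeros(len(t.feature), dtype=int)
            for i in range(len(t.feature)):
                if t.feature[i] >= 0:
                    depth[t.left[i]] = depth[i] + 1
                    depth[t.right[i]] = depth[i] + 1
            internal = t.feature >= 0
            if internal.any():
                deepest = max(deepest, int(depth[internal].max()))
        return deepest


def fit_isolation_forest(
    table: FeatureTable,
    n_trees: int = 100,
    subsample_size: int = 256,
    contamination: float = 0.05,
    seed: int = 0,
) -> IsolationForestModel:
    """Fit a forest of random partition trees on the feature columns.

    ``subsample_size`` (psi) is clamped to the number of rows; each tree sees
    an independent without-replacement subsample.
    """
    n = table.n_rows
    if n < 2:
        raise ConfigurationError("isolation forest needs at least 2 rows")
    if not 0.0 < contamination < 0.5:
        raise ConfigurationError(
            f"contamination must lie in (0, 0.5), got {contamination}"
        )
    X = table.values()
    if np.isnan(X).any():
        raise ConfigurationError("isolation forest input contains missing cells; clean first")
    psi = min(subsample_size, n)
    height_limit = math.ceil(math.log2(psi)) if psi > 1 else 1
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        rows = rng.choice(n, size=psi, replace=False)
        trees.append(_grow_tree(X[rows], height_limit, rng))
    return IsolationForestModel(
        n_trees=n_trees,
        subsample_size=psi,
        height_limit=height_limit,
        contamination=contamination,
        column_names=table.column_names,
        trees=trees,
    )


def anomaly_scores(model: IsolationForestModel, table: FeatureTable) -> np.ndarray:
    """Per-row anomaly score ``2**(-E[h]/c(psi))``, strictly inside (0, 1)."""
    if table.column_names != model.column_names:
        raise SchemaError(
            f"column mismatch: model fitted on {model.column_names[:5]}..., "
            f"got {table.column_names[:5]}..."
        )
    X = table.values()
    if np.isnan(X).any():
        raise ConfigurationError("cannot score rows with missing cells")
    paths = np.zeros(len(X))
    for tree in model.trees:
        paths += tree.path_lengths(X)
    mean_path = paths / model.n_trees
    return np.power(2.0, -mean_path / average_path_length(model.subsample_size))


@dataclass
class OutlierReport:
    removed_indices: list[int]
    removed_scores: list[float]
    threshold_score: float
    contamination: float


def anomaly_filter(
    model: IsolationForestModel, table: FeatureTable
) -> tuple[FeatureTable, OutlierReport]:
    """Drop the top ``contamination`` fraction of rows by anomaly score.

    The removed-row report lists original (0-based) row indices and their
    scores, most anomalous first.
    """
    scores = anomaly_scores(model, table)
    n = table.n_rows
    n_drop = int(round(model.contamination * n))
    if n_drop == 0:
        keep = np.arange(n)
        report = OutlierReport([], [], float("nan"), model.contamination)
        return table.select_rows(keep), report
    order = np.argsort(-scores, kind="stable")
    dropped = order[:n_drop]
    keep = np.setdiff1d(np.arange(n), dropped)
    report = OutlierReport(
        removed_indices=dropped.tolist(),
        removed_scores=scores[dropped].tolist(),
        threshold_score=float(scores[dropped].min()),
        contamination=model.contamination,
    )
    return table.select_rows(keep), report
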