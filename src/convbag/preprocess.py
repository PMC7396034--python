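"""Five-stage data preparation: clean, balance, rank/select, screen, encode.

The stages run in a fixed order — missing-value cleaning, oversampling to
class balance, importance-based feature selection down to 36 columns,
isolation-forest outlier screening, and finally encoding of the surviving
features as 6x6 single-channel grids for the convolutional network.

Importance ranking is permutation importance on a bagged-CART model: the
score of a feature is the mean decrease in out-of-bag accuracy when that
feature is permuted, averaged over trees.  Pure-noise columns score about
zero; scores are clipped at zero so the ranking invariant (nonnegative
scores) holds under resampling noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bagging import CartTree
from .errors import (ConfigurationError, DegenerateLabelError, EmptyOutputError)
from .isolation import (IsolationForestModel, OutlierReport, anomaly_filter,
                        anomaly_scores, average_path_length, fit_isolation_forest)
from .tables import FeatureTable, concat_tables

__all__ = [
    "CleaningPolicy", "CleaningLog", "clean_table",
    "balance_classes",
    "ImportanceRanking", "rank_feature_importance", "select_features",
    "GridBatch", "GridEncoder", "encode_grid",
    # re-exported outlier-screening surface
    "IsolationForestModel", "OutlierReport", "fit_isolation_forest",
    "anomaly_scores", "anomaly_filter", "average_path_length",
]

GRID_SIDE = 6
GRID_FEATURES = GRID_SIDE * GRID_SIDE


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CleaningPolicy:
    """Row-drop and imputation rules for missing cells."""

    max_missing_fraction: float = 0.5   # rows with strictly more are dropped

    def validate(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ConfigurationError(
                f"max_missing_fraction must lie in [0, 1], "
                f"got {self.max_missing_fraction}"
            )


@dataclass
class CleaningLog:
    n_rows_in: int
    n_rows_out: int
    n_dropped_missing_label: int
    n_dropped_sparse_rows: int
    n_imputed_cells: int
    global_medians: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_rows_in": self.n_rows_in,
            "n_rows_out": self.n_rows_out,
            "n_dropped_missing_label": self.n_dropped_missing_label,
            "n_dropped_sparse_rows": self.n_dropped_sparse_rows,
            "n_imputed_cells": self.n_imputed_cells,
            "global_medians": self.global_medians,
        }


def clean_table(
    raw: FeatureTable, policy: CleaningPolicy = CleaningPolicy()
) -> tuple[FeatureTable, CleaningLog]:
    """Remove or impute every missing marker.

    Rules, in order: rows with a missing label are dropped; rows with
    strictly more than ``policy.max_missing_fraction`` of their feature cells
    missing are dropped; any remaining missing cell is imputed by the
    class-conditional median of its column (global median as fallback when a
    class has no observed value).  The log records counts per rule and the
    global per-column medians, which fitted models reuse at prediction time.
    """
    policy.validate()
    if raw.n_rows < 1:
        raise EmptyOutputError("clean_table received an empty table")
    n_in = raw.n_rows

    keep_label = ~np.isnan(raw.label)
    n_bad_label = int((~keep_label).sum())
    feats = raw.features.loc[keep_label].reset_index(drop=True)
    label = raw.label[keep_label]

    missing = feats.isna().to_numpy()
    frac = missing.mean(axis=1) if feats.shape[1] else np.zeros(len(feats))
    keep_rows = frac <= policy.max_missing_fraction
    n_sparse = int((~keep_rows).sum())
    feats = feats.loc[keep_rows].reset_index(drop=True)
    label = label[keep_rows]

    if len(feats) == 0:
        raise EmptyOutputError("all rows were dropped during cleaning")

    n_imputed = int(feats.isna().to_numpy().sum())
    global_medians = feats.median(skipna=True)
    if n_imputed:
        for cls in (0.0, 1.0):
            mask = label == cls
            if not mask.any():
                continue
            med = feats.loc[mask].median(skipna=True).fillna(global_medians)
            feats.loc[mask] = feats.loc[mask].fillna(med)
        # columns entirely missing in both classes fall back to 0
        feats = feats.fillna(global_medians.fillna(0.0))

    log = CleaningLog(
        n_rows_in=n_in,
        n_rows_out=len(feats),
        n_dropped_missing_label=n_bad_label,
        n_dropped_sparse_rows=n_sparse,
        n_imputed_cells=n_imputed,
        global_medians={k: float(v) for k, v in global_medians.fillna(0.0).items()},
    )
    return FeatureTable(feats, label), log


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

def balance_classes(
    table: FeatureTable, method: str = "random_oversample", seed: int = 0
) -> FeatureTable:
    """Oversample the minority class until both class counts are exactly equal.

    Original rows are always preserved; appended rows are either replicated
    minority rows (``random_oversample``) or SMOTE interpolates
    ``x_i + lam * (x_nn - x_i)`` with ``lam ~ U[0,1]`` and ``x_nn`` one of the
    k=5 nearest minority neighbours (``smote``).
    """
    if method not in ("random_oversample", "smote"):
        raise ConfigurationError(
            f"unknown balance method {method!r}; use 'random_oversample' or 'smote'"
        )
    y = table.binary_label()
    n0, n1 = table.class_counts()
    if n0 == 0 or n1 == 0:
        raise DegenerateLabelError("balance_classes requires both classes present")
    if n0 == n1:
        return table
    minority = 1 if n1 < n0 else 0
    deficit = abs(n0 - n1)
    min_idx = np.where(y == minority)[0]
    rng = np.random.default_rng(seed)

    if method == "random_oversample":
        extra_idx = rng.choice(min_idx, size=deficit, replace=True)
        extra = table.select_rows(extra_idx)
        return concat_tables(table, extra)

    # SMOTE
    if len(min_idx) < 2:
        raise DegenerateLabelError(
            "smote needs at least 2 minority rows to form neighbour segments"
        )
    Xmin = table.features.iloc[min_idx].to_numpy(dtype=np.float64)
    if np.isnan(Xmin).any():
        raise ConfigurationError("smote requires a cleaned (no-missing) table")
    from sklearn.neighbors import NearestNeighbors

    k = min(5, len(min_idx) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    neigh = nn.kneighbors(Xmin, return_distance=False)[:, 1:]   # drop self
    base = rng.integers(0, len(min_idx), size=deficit)
    pick = neigh[base, rng.integers(0, k, size=deficit)]
    lam = rng.random(deficit)[:, None]
    synth = Xmin[base] + lam * (Xmin[pick] - Xmin[base])
    extra = FeatureTable(
        pd.DataFrame(synth, columns=table.column_names),
        np.full(deficit, float(minority)),
    )
    return concat_tables(table, extra)


# ---------------------------------------------------------------------------
# importance ranking / selection
# ---------------------------------------------------------------------------

@dataclass
class ImportanceRanking:
    """Nonnegative per-feature scores plus a deterministic descending ordering."""

    scores: dict[str, float]
    ordering: list[str]

    def __post_init__(self) -> None:
        if sorted(self.scores) != sorted(self.ordering):
            raise ConfigurationError("ordering must be a permutation of the scored columns")
        if any(v < 0 for v in self.scores.values()):
            raise ConfigurationError("importance scores must be nonnegative")


def rank_feature_importance(
    table: FeatureTable,
    seed: int = 0,
    n_trees: int = 100,
    max_depth: int = 8,
    min_leaf: int = 10,
    max_features: int | None = None,
    n_repeats: int = 3,
) -> ImportanceRanking:
    """Permutation importance on a bagged model of feature-subsampled CARTs.

    For each bootstrap tree the out-of-bag rows give a baseline accuracy;
    permuting one feature column at a time on those rows (``n_repeats``
    independent permutations, averaged) and re-predicting measures the
    accuracy decrease attributable to that feature.  Scores are tree-averaged
    decreases clipped at zero; ties in the descending ordering break by
    original column position.

    Each split search considers only ``max_features`` random candidate
    columns (default ``ceil(sqrt(p)/2)``): without this, strong features
    mask weak-but-informative ones, whose importance would then be
    indistinguishable from noise.
    """
    if table.n_features < 2:
        raise ConfigurationError("ranking needs at least 2 features")
    y01 = table.binary_label()
    if len(np.unique(y01)) < 2:
        raise DegenerateLabelError("ranking requires both classes present")
    X = table.values()
    if np.isnan(X).any():
        raise ConfigurationError("ranking requires a cleaned (no-missing) table")
    y = 2 * y01 - 1
    n, p = X.shape
    if max_features is None:
        max_features = max(1, int(np.ceil(np.sqrt(p) / 2.0)))
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    n_used = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tree = CartTree(
            max_depth=max_depth, min_leaf=min_leaf,
            max_features=max_features, seed=int(rng.integers(2**31 - 1)),
        ).fit(X[boot], y[boot])
        base_acc = float(np.mean(tree.predict(X[oob]) == y[oob]))
        X_oob = X[oob]
        for j in range(p):
            drop = 0.0
            for _rep in range(n_repeats):
                perm = rng.permutation(oob.size)
                Xp = X_oob.copy()
                Xp[:, j] = Xp[perm, j]
                drop += base_acc - float(np.mean(tree.predict(Xp) == y[oob]))
            drops[j] += drop / n_repeats
        n_used += 1
    if n_used == 0:  # pragma: no cover - astronomically unlikely
        raise ConfigurationError("no out-of-bag rows in any replicate")
    scores = np.maximum(drops / n_used, 0.0)
    names = table.column_names
    order = np.argsort(-scores, kind="stable")   # stable: ties keep column order
    return ImportanceRanking(
        scores={names[j]: float(scores[j]) for j in range(p)},
        ordering=[names[j] for j in order],
    )


def select_features(
    table: FeatureTable,
    ranking: ImportanceRanking,
    k: int = GRID_FEATURES,
    keep: list[str] | None = None,
) -> FeatureTable:
    """Keep the top-``k`` columns by importance, in ranking order.

    ``keep`` is an optional expert keep-list: those columns are always
    retained (at their ranking positions) and the remainder of the budget is
    filled from the top of the ranking.
    """
    p = table.n_features
    if k > p:
        raise ConfigurationError(f"cannot select k={k} from {p} features")
    keep = list(keep or [])
    unknown = [c for c in keep if c not in table.column_names]
    if unknown:
        raise ConfigurationError(f"keep-list columns not in table: {unknown}")
    if len(keep) > k:
        raise ConfigurationError(f"keep-list has {len(keep)} columns but k={k}")
    chosen = set(keep)
    for name in ranking.ordering:
        if len(chosen) == k:
            break
        chosen.add(name)
    ordered = [c for c in ranking.ordering if c in chosen]
    return FeatureTable(table.features[ordered].copy(), table.label.copy())


# ---------------------------------------------------------------------------
# grid encoding
# ---------------------------------------------------------------------------

@dataclass
class GridBatch:
    """``n x 6 x 6 x 1`` standardized grids plus the row-major feature order."""

    data: np.ndarray
    feature_order: list[str]

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[1:] != (GRID_SIDE, GRID_SIDE, 1):
            raise ConfigurationError(
                f"grid batch must have shape (n, {GRID_SIDE}, {GRID_SIDE}, 1), "
                f"got {self.data.shape}"
            )
        if len(self.feature_order) != GRID_FEATURES:
            raise ConfigurationError(
                f"feature_order must list exactly {GRID_FEATURES} names"
            )

    @property
    def n(self) -> int:
        return len(self.data)


class GridEncoder:
    """Standardize 36 features and lay them out row-major on a 6x6 grid.

    Per-feature mean and standard deviation are computed once on the fitting
    (training) table and reused verbatim at prediction time.  Zero-variance
    columns encode to all zeros (with a warning at fit time).  Grid cell
    (r, c) holds the feature at position ``6*r + c`` of the fitted column
    order, so the mapping is exactly invertible.
    """

    def __init__(self) -> None:
        self.feature_order: list[str] | None = None
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, table: FeatureTable) -> "GridEncoder":
        if table.n_features != GRID_FEATURES:
            raise ConfigurationError(
                f"grid encoding needs exactly {GRID_FEATURES} feature columns, "
                f"got {table.n_features}"
            )
        X = table.values()
        if np.isnan(X).any():
            raise ConfigurationError("grid encoding requires a cleaned table")
        self.feature_order = table.column_names
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        zero_var = sd == 0.0
        if zero_var.any():
            bad = [self.feature_order[j] for j in np.where(zero_var)[0]]
            warnings.warn(
                f"zero-variance columns encoded as zeros: {bad}", stacklevel=2
            )
        self.sd_ = np.where(zero_var, 1.0, sd)
        self._zero_var = zero_var
        return self

    def transform(self, table: FeatureTable) -> GridBatch:
        if self.feature_order is None:
            raise ConfigurationError("GridEncoder is not fitted")
        if table.column_names != self.feature_order:
            missing = [c for c in self.feature_order if c not in table.column_names]
            raise ConfigurationError(
                f"column mismatch with fitted order; missing: {missing}"
            )
        X = table.values()
        if np.isnan(X).any():
            raise ConfigurationError("grid encoding requires a cleaned table")
        Z = (X - self.mean_) / self.sd_
        Z[:, self._zero_var] = 0.0
        grids = Z.reshape(len(Z), GRID_SIDE, GRID_SIDE, 1)
        return GridBatch(grids, list(self.feature_order))

    def fit_transform(self, table: FeatureTable) -> GridBatch:
        return self.fit(table).transform(table)

    def decode(self, batch: GridBatch) -> np.ndarray:
        """Inverse of the grid layout: the ``n x 36`` standardized matrix."""
        return batch.data.reshape(batch.n, GRID_FEATURES)

    def state_dict(self) -> dict:
        return {
            "feature_order": self.feature_order,
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "zero_var": self._zero_var.tolist(),
        }

    @classmethod
    def from_state(cls, d: dict) -> "GridEncoder":
        enc = cls()
        enc.feature_order = list(d["feature_order"])
        enc.mean_ = np.asarray(d["mean"], dtype=np.float64)
        enc.sd_ = np.asarray(d["sd"], dtype=np.float64)
        enc._zero_var = np.asarray(d["zero_var"], dtype=bool)
        return enc


def encode_grid(table: FeatureTable) -> GridBatch:
    """One-shot grid encoding (fits standardization on the given table)."""
    return GridEncoder().fit_transform(table)
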