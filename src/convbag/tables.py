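"""The tabular currency of the package: named numeric features plus a binary label.

A :class:`FeatureTable` wraps a pandas DataFrame of float64 feature columns
(``NaN`` marks a missing cell) together with a label vector.  Before cleaning
the label may itself contain ``NaN``; every downstream stage requires a strict
{0, 1} label, obtained through :meth:`FeatureTable.binary_label`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError


@dataclass
class FeatureTable:
    """Rows of named numeric features plus a per-row binary label.

    Parameters
    ----------
    features:
        ``n x p`` DataFrame, float64; ``NaN`` encodes a missing cell.
    label:
        Length-``n`` float array; values must be 0, 1 or ``NaN`` (missing).
    """

    features: pd.DataFrame
    label: np.ndarray = field()

    def __post_init__(self) -> None:
        self.features = self.features.astype(np.float64, copy=False)
        self.label = np.asarray(self.label, dtype=np.float64)
        if self.label.ndim != 1 or len(self.label) != len(self.features):
            raise SchemaError(
                f"label length {self.label.shape} does not match "
                f"{len(self.features)} rows"
            )
        cols = list(self.features.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise SchemaError(f"duplicate feature columns: {dupes}")
        finite = self.label[~np.isnan(self.label)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            bad = np.where(~np.isnan(self.label) & ~np.isin(self.label, (0.0, 1.0)))[0]
            raise SchemaError(
                f"label must be binary; offending rows (0-based): {bad[:10].tolist()}"
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def column_names(self) -> list[str]:
        return list(self.features.columns)

    def binary_label(self) -> np.ndarray:
        """Return the label as strict int {0,1}; raise if any label is missing."""
        if np.isnan(self.label).any():
            n_bad = int(np.isnan(self.label).sum())
            raise ConfigurationError(
                f"{n_bad} rows have a missing label; run clean_table first"
            )
        return self.label.astype(np.int64)

    def class_counts(self) -> tuple[int, int]:
        """(count of label 0, count of label 1), ignoring missing labels."""
        y = self.label
        return int(np.sum(y == 0.0)), int(np.sum(y == 1.0))

    def values(self) -> np.ndarray:
        """Feature matrix as a float64 ndarray (shared memory not guaranteed)."""
        return self.features.to_numpy(dtype=np.float64)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.label.copy())

    def select_rows(self, index: np.ndarray) -> "FeatureTable":
        """Positional row subset / resample (bootstrap indices allowed)."""
        return FeatureTable(
            self.features.iloc[index].reset_index(drop=True),
            self.label[np.asarray(index)],
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        """Features plus the label as one DataFrame (for CSV round-trips)."""
        if label_column in self.features.columns:
            raise SchemaError(f"label column name {label_column!r} clashes with a feature")
        out = self.features.copy()
        out[label_column] = self.label
        return out

    def equals(self, other: "FeatureTable") -> bool:
        return self.features.equals(other.features) and np.array_equal(
            self.label, other.label, equal_nan=True
        )


def concat_tables(first: FeatureTable, second: FeatureTable) -> FeatureTable:
    """Stack two tables with identical columns (used by oversampling)."""
    if list(first.features.columns) != list(second.features.columns):
        raise SchemaError("cannot concatenate tables with different columns")
    feats = pd.concat([first.features, second.features], ignore_index=True)
    return FeatureTable(feats, np.concatenate([first.label, second.label]))
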