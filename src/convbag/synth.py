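"""Synthetic readmission-style tabular data with known ground truth.

The generator emulates the structure of a hospital-readmission cohort: a few
dozen mixed-type feature columns, a rare binary outcome, missing cells, and a
small fraction of rows corrupted by gross recording errors.  Every nuisance is
injected with a known flag so that each preprocessing stage can be tested
against the truth.

Label mechanism
---------------
Labels follow a latent-variable logistic model.  Informative columns are
standard normal; with coefficients ``beta`` the latent score of a row is

    u = beta . x + eps,     eps ~ Logistic(0, noise_sd)

and the label is ``1`` when ``u`` exceeds a threshold chosen so that the
marginal positive fraction equals ``imbalance_ratio``.  With ``noise_sd = 0``
the classes are exactly linearly separable in the informative features; with
``noise_sd > 0`` labels are Bernoulli draws from a shifted logistic of the
linear score, which keeps the signal recoverable by a plain logistic fit.

Corruption model
----------------
* a documented subset of the non-informative columns is discretised into small
  integer codes to emulate categorical clinical fields;
* ``outlier_rate`` of the rows are corrupted records: a block of 6-12
  features is displaced to at least six class-conditional standard deviations
  from its class mean (a row-shift or unit-system error hitting a panel of
  fields), flagged ``is_outlier``;
* ``missing_rate`` of the remaining cells are masked completely at random,
  flagged ``had_missing`` per row.  Outlier rows are exempt from masking so
  that each injected anomaly stays observable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .tables import FeatureTable

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset", "make_fixture",
           "FIXTURES"]

#: number of latent draws used to locate the label threshold
_THRESHOLD_DRAWS = 200_000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    ``n_categorical`` non-informative columns are discretised into integer
    codes; ``coef_low``/``coef_high`` bound the absolute generating
    coefficients of the informative columns.
    """

    n_samples: int
    n_features_raw: int = 49
    n_informative: int = 36
    imbalance_ratio: float = 0.2
    missing_rate: float = 0.05
    outlier_rate: float = 0.02
    noise_sd: float = 1.0
    seed: int = 0
    n_categorical: int = 12
    coef_low: float = 0.5
    coef_high: float = 1.5

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError(f"n_samples must be positive, got {self.n_samples}")
        if self.n_features_raw < 1:
            raise ConfigurationError(
                f"n_features_raw must be positive, got {self.n_features_raw}"
            )
        if not 1 <= self.n_informative <= self.n_features_raw:
            raise ConfigurationError(
                f"n_informative must lie in [1, n_features_raw]; got "
                f"n_informative={self.n_informative}, n_features_raw={self.n_features_raw}"
            )
        if not 0.0 < self.imbalance_ratio <= 0.5:
            raise ConfigurationError(
                f"imbalance_ratio must lie in (0, 0.5], got {self.imbalance_ratio}"
            )
        if not 0.0 <= self.missing_rate <= 0.3:
            raise ConfigurationError(
                f"missing_rate must lie in [0, 0.3], got {self.missing_rate}"
            )
        if not 0.0 <= self.outlier_rate <= 0.2:
            raise ConfigurationError(
                f"outlier_rate must lie in [0, 0.2], got {self.outlier_rate}"
            )
        if self.noise_sd < 0.0:
            raise ConfigurationError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if self.n_categorical < 0:
            raise ConfigurationError(
                f"n_categorical must be nonnegative, got {self.n_categorical}"
            )
        if not 0.0 < self.coef_low <= self.coef_high:
            raise ConfigurationError(
                f"coefficient range must satisfy 0 < coef_low <= coef_high; "
                f"got ({self.coef_low}, {self.coef_high})"
            )


@dataclass
class SyntheticDataset:
    """A generated cohort plus its generating truth."""

    table: FeatureTable
    clean_label: np.ndarray
    is_outlier: np.ndarray
    had_missing: np.ndarray
    informative_feature_names: list[str]
    categorical_feature_names: list[str]
    generating_coefficients: np.ndarray
    label_threshold: float
    spec: SyntheticSpec = field(repr=False)

    def truth_dict(self) -> dict:
        """Truth sidecar in JSON-serialisable form."""
        return {
            "clean_label": self.clean_label.astype(int).tolist(),
            "is_outlier": self.is_outlier.astype(bool).tolist(),
            "had_missing": self.had_missing.astype(bool).tolist(),
            "informative_feature_names": self.informative_feature_names,
            "categorical_feature_names": self.categorical_feature_names,
            "generating_coefficients": self.generating_coefficients.tolist(),
            "label_threshold": self.label_threshold,
            "spec": asdict(self.spec),
        }

    def write(self, csv_path: str | Path, truth_path: str | Path | None = None) -> None:
        """Write the table as CSV (header row) and the truth sidecar as JSON."""
        csv_path = Path(csv_path)
        self.table.to_frame().to_csv(csv_path, index=False)
        if truth_path is not None:
            Path(truth_path).write_text(json.dumps(self.truth_dict(), indent=1))


def _label_threshold(beta: np.ndarray, noise_sd: float, ratio: float,
                     seed_seq: np.random.SeedSequence) -> float:
    """Quantile of the latent-score distribution giving the target positive rate.

    Estimated on an auxiliary sample drawn from an independent stream so that
    the labels of the returned cohort remain stochastic given the features.
    """
    rng = np.random.default_rng(seed_seq)
    x = rng.standard_normal((_THRESHOLD_DRAWS, beta.size))
    u = x @ beta
    if noise_sd > 0:
        u += rng.logistic(0.0, noise_sd, size=_THRESHOLD_DRAWS)
    return float(np.quantile(u, 1.0 - ratio))


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate one cohort; deterministic for a fixed spec (seed included)."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ss_thresh, ss_data = root.spawn(2)
    rng = np.random.default_rng(ss_data)

    n, p, k = spec.n_samples, spec.n_features_raw, spec.n_informative
    names = [f"x{j:02d}" for j in range(p)]
    informative_idx = np.sort(rng.choice(p, size=k, replace=False))
    informative = [names[j] for j in informative_idx]

    beta = rng.uniform(spec.coef_low, spec.coef_high, size=k)
    beta *= rng.choice([-1.0, 1.0], size=k)

    X = rng.standard_normal((n, p))
    score = X[:, informative_idx] @ beta
    eps = rng.logistic(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
    threshold = _label_threshold(beta, spec.noise_sd, spec.imbalance_ratio, ss_thresh)
    y = (score + eps > threshold).astype(np.int64)

    # categorical emulation: small integer codes on non-informative columns,
    # so the continuous generating signal stays intact
    non_informative = np.setdiff1d(np.arange(p), informative_idx)
    n_cat = min(spec.n_categorical, non_informative.size)
    cat_idx = np.sort(rng.choice(non_informative, size=n_cat, replace=False))
    bins = np.array([-1.5, -0.5, 0.5, 1.5])
    for j in cat_idx:
        X[:, j] = np.digitize(X[:, j], bins).astype(np.float64)
    categorical = [names[j] for j in cat_idx]

    # corrupted records: displace a block of 6-12 features far outside the
    # class-conditional range (>= 6 SD guaranteed, 8-12 SD drawn)
    is_outlier = np.zeros(n, dtype=bool)
    n_out = int(round(spec.outlier_rate * n))
    if n_out:
        out_rows = rng.choice(n, size=n_out, replace=False)
        is_outlier[out_rows] = True
        class_mean = np.empty((2, p))
        class_sd = np.empty((2, p))
        for c in (0, 1):
            mask = y == c
            if mask.any():
                class_mean[c] = X[mask].mean(axis=0)
                class_sd[c] = X[mask].std(axis=0)
            else:  # degenerate single-class draw; fall back to global stats
                class_mean[c] = X.mean(axis=0)
                class_sd[c] = X.std(axis=0)
        class_sd = np.maximum(class_sd, 1e-8)
        for row in out_rows:
            n_feats = int(rng.integers(6, min(13, p + 1)))
            feats = rng.choice(p, size=n_feats, replace=False)
            sign = rng.choice([-1.0, 1.0], size=n_feats)
            mag = rng.uniform(8.0, 12.0, size=n_feats)
            c = y[row]
            X[row, feats] = class_mean[c, feats] + sign * mag * class_sd[c, feats]

    # completely-at-random masking of non-outlier cells
    had_missing = np.zeros(n, dtype=bool)
    if spec.missing_rate > 0:
        mask = rng.random((n, p)) < spec.missing_rate
        mask[is_outlier] = False
        X[mask] = np.nan
        had_missing = mask.any(axis=1)

    table = FeatureTable(pd.DataFrame(X, columns=names), y.astype(np.float64))
    return SyntheticDataset(
        table=table,
        clean_label=y,
        is_outlier=is_outlier,
        had_missing=had_missing,
        informative_feature_names=informative,
        categorical_feature_names=categorical,
        generating_coefficients=beta,
        label_threshold=threshold,
        spec=spec,
    )


#: versioned fixture catalogue used by the test and acceptance suites
FIXTURES: dict[str, SyntheticSpec] = {
    # noise-free, balanced, linearly separable in 6 strong informative
    # features -- the sanity benchmark for learners
    "separable_small": SyntheticSpec(
        n_samples=400, n_features_raw=49, n_informative=6,
        imbalance_ratio=0.5, missing_rate=0.0, outlier_rate=0.0,
        noise_sd=0.0, coef_low=1.2, coef_high=2.0, seed=20201,
    ),
    # the main end-to-end benchmark: rare outcome, mild corruption,
    # readmission-like weak-to-moderate signal
    "imbalanced_benchmark": SyntheticSpec(
        n_samples=4000, n_features_raw=49, n_informative=36,
        imbalance_ratio=0.2, missing_rate=0.03, outlier_rate=0.02,
        noise_sd=3.0, seed=20202,
    ),
    # clean labels, 5% gross outliers, no missingness: isolates the
    # anomaly-screening stage
    "outlier_screen": SyntheticSpec(
        n_samples=2000, n_features_raw=49, n_informative=36,
        imbalance_ratio=0.5, missing_rate=0.0, outlier_rate=0.05,
        noise_sd=1.0, seed=20203,
    ),
    # balanced but heavily label-noised: exercises variance reduction of the
    # ensemble
    "noisy_benchmark": SyntheticSpec(
        n_samples=2000, n_features_raw=49, n_informative=36,
        imbalance_ratio=0.5, missing_rate=0.0, outlier_rate=0.0,
        noise_sd=6.0, seed=20204,
    ),
}


def make_fixture(name: str) -> SyntheticDataset:
    """Generate a catalogued, seed-fixed dataset by name."""
    try:
        spec = FIXTURES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return generate_dataset(spec)
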