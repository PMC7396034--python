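"""End-to-end orchestration: preprocess, train the network, bag its features.

``train_cnnplus`` runs the full training flow — clean, balance, rank/select
36 features, screen outliers, encode 6x6 grids, train the convolutional
network, extract its 128-dimensional penultimate activations, and fit a
bagging ensemble on those activations with labels mapped {0 -> -1, 1 -> +1}.
``predict_cnnplus`` replays the *stored* preprocessing state (imputation
medians, selected columns, scaler statistics, grid order) on new rows — no
balancing, no outlier removal, and no refitting at prediction time — and
maps the ensemble vote back to {0, 1}.

``run_benchmark`` is the comparison harness: repeated stratified train/test
splits, optional balancing of the training split only, and per-model
mean/variance of accuracy, recall and precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .bagging import (CartTree, EnsembleModel, LabeledFeatureSet, fit_bagging,
                      vote_predict)
from .convnet import (Network, TrainConfig, TrainingHistory, default_network_spec,
                      extract_features, predict_softmax, train_network)
from .errors import ConfigurationError, DegenerateLabelError, SchemaError
from .preprocess import (CleaningLog, CleaningPolicy, GridEncoder,
                         ImportanceRanking, OutlierReport, anomaly_filter,
                         balance_classes, clean_table, fit_isolation_forest,
                         rank_feature_importance, select_features)
from .tables import FeatureTable

__all__ = ["CnnPlusConfig", "CnnPlusModel", "train_cnnplus", "predict_cnnplus",
           "MetricsReport", "evaluate", "aggregate_reports",
           "run_benchmark", "BenchmarkResult", "default_model_factories",
           "SklearnTableClassifier", "CnnPlusClassifier"]

_SEED_CAP = 2**31 - 1


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CnnPlusConfig:
    """Everything the training flow needs, with documented defaults."""

    cleaning: CleaningPolicy = field(default_factory=CleaningPolicy)
    balance_method: str = "random_oversample"      # or "smote" / "none"
    select_k: int = 36
    keep_features: tuple[str, ...] = ()
    ranking_trees: int = 30                        # lighter than the standalone default
    ranking_repeats: int = 1
    iforest_trees: int = 100
    iforest_subsample: int = 256
    contamination: float = 0.05
    train: TrainConfig = field(default_factory=TrainConfig)
    ensemble_size: int = 21
    tree_max_depth: int = 8
    tree_min_leaf: int = 5
    seed: int = 0

    def validate(self) -> None:
        self.cleaning.validate()
        self.train.validate()
        if self.balance_method not in ("random_oversample", "smote", "none"):
            raise ConfigurationError(
                f"balance_method must be 'random_oversample', 'smote' or 'none', "
                f"got {self.balance_method!r}"
            )
        if self.ensemble_size < 1:
            raise ConfigurationError("ensemble_size must be >= 1")


# ---------------------------------------------------------------------------
# the fitted model
# ---------------------------------------------------------------------------

@dataclass
class CnnPlusModel:
    """Fitted preprocessing state + network + ensemble.

    The prediction path only ever applies stored state; it never refits
    anything on incoming data.
    """

    imputation_medians: dict[str, float]
    selected_features: list[str]
    encoder: GridEncoder
    network: Network
    ensemble: EnsembleModel
    ranking: ImportanceRanking
    cleaning_log: CleaningLog
    outlier_report: OutlierReport
    history: TrainingHistory
    config: CnnPlusConfig

    def _prepare(self, table: FeatureTable) -> np.ndarray:
        missing_cols = [c for c in self.selected_features
                        if c not in table.column_names]
        if missing_cols:
            raise SchemaError(f"table is missing selected columns: {missing_cols}")
        feats = table.features[self.selected_features].copy()
        for col in self.selected_features:
            feats[col] = feats[col].fillna(self.imputation_medians[col])
        prepared = FeatureTable(feats, np.zeros(len(feats)))
        return self.encoder.transform(prepared).data

    def features_128(self, table: FeatureTable) -> np.ndarray:
        """Penultimate-layer representation of arbitrary rows."""
        return extract_features(self.network, self._prepare(table))

    def predict(self, table: FeatureTable) -> np.ndarray:
        votes = vote_predict(self.ensemble, self.features_128(table))
        return (votes > 0).astype(np.int64)

    def predict_softmax_head(self, table: FeatureTable) -> np.ndarray:
        """Predictions of the plain softmax output layer (the unbagged network)."""
        labels, _ = predict_softmax(self.network, self._prepare(table))
        return labels


def train_cnnplus(train_table: FeatureTable, config: CnnPlusConfig | None = None
                  ) -> CnnPlusModel:
    """Run the full training flow and persist every piece of fitted state."""
    config = config or CnnPlusConfig()
    config.validate()
    seeds = np.random.default_rng(config.seed).integers(0, _SEED_CAP, size=4)
    seed_balance, seed_rank, seed_iforest, seed_bag = (int(s) for s in seeds)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    cleaned, cleaning_log = stage("clean", clean_table, train_table, config.cleaning)
    if len(np.unique(cleaned.binary_label())) < 2:
        raise DegenerateLabelError("training table has a single class after cleaning")

    if config.balance_method != "none":
        balanced = stage("balance", balance_classes, cleaned,
                         config.balance_method, seed_balance)
    else:
        balanced = cleaned

    ranking = stage("rank", rank_feature_importance, balanced, seed=seed_rank,
                    n_trees=config.ranking_trees, n_repeats=config.ranking_repeats)
    selected = stage("select", select_features, balanced, ranking,
                     k=config.select_k, keep=list(config.keep_features))

    forest = stage("outlier_screen", fit_isolation_forest, selected,
                   n_trees=config.iforest_trees,
                   subsample_size=config.iforest_subsample,
                   contamination=config.contamination, seed=seed_iforest)
    screened, outlier_report = stage("outlier_screen", anomaly_filter, forest, selected)

    encoder = GridEncoder()
    grids = stage("encode", encoder.fit_transform, screened)
    y = screened.binary_label()
    y_onehot = np.eye(2)[y]
    network, history = stage("train_network", train_network,
                             default_network_spec(), grids.data, y_onehot,
                             config.train)

    feats = extract_features(network, grids.data)
    dataset = LabeledFeatureSet(feats, 2 * y - 1)
    factory = lambda: CartTree(config.tree_max_depth, config.tree_min_leaf)  # noqa: E731
    ensemble = stage("fit_bagging", fit_bagging, dataset, T=config.ensemble_size,
                     learner_factory=factory, seed=seed_bag)

    return CnnPlusModel(
        imputation_medians=cleaning_log.global_medians,
        selected_features=list(grids.feature_order),
        encoder=encoder,
        network=network,
        ensemble=ensemble,
        ranking=ranking,
        cleaning_log=cleaning_log,
        outlier_report=outlier_report,
        history=history,
        config=config,
    )


def predict_cnnplus(model: CnnPlusModel, table: FeatureTable) -> np.ndarray:
    """Labels in {0,1} from the stored preprocessing + ensemble vote."""
    return model.predict(table)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Confusion counts and the four derived classification metrics.

    ``accuracy = (TP+TN)/(P+N)``, ``recall = TP/P`` with P the *actual*
    positives, ``precision = TP/(TP+FP)``, ``f_measure = 2TP/(2TP+FP+FN)``.
    A zero denominator yields 0 with a warning.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    recall: float
    precision: float
    f_measure: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "tn", "fp", "fn", "accuracy", "recall", "precision",
                 "f_measure")}


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} denominator is 0; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def evaluate(labels_true, labels_pred) -> MetricsReport:
    """Confusion-count metrics for {0,1} labels of equal length."""
    y = np.asarray(labels_true)
    yhat = np.asarray(labels_pred)
    if y.shape != yhat.shape:
        raise ConfigurationError(
            f"label length mismatch: {y.shape} vs {yhat.shape}"
        )
    for arr, what in ((y, "true"), (yhat, "predicted")):
        if not np.isin(arr, (0, 1)).all():
            raise ConfigurationError(f"{what} labels must be in {{0,1}}")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=_safe_div(tp + tn, tp + tn + fp + fn, "accuracy"),
        recall=_safe_div(tp, tp + fn, "recall"),
        precision=_safe_div(tp, tp + fp, "precision"),
        f_measure=_safe_div(2 * tp, 2 * tp + fp + fn, "f_measure"),
    )


def aggregate_reports(reports: list[MetricsReport]) -> dict[str, dict[str, float]]:
    """Mean and (population) variance of each metric over repeated runs."""
    out = {}
    for metric in ("accuracy", "recall", "precision", "f_measure"):
        vals = np.array([getattr(r, metric) for r in reports], dtype=float)
        out[metric] = {"mean": float(vals.mean()), "variance": float(vals.var())}
    return out


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

class SklearnTableClassifier:
    """Adapter putting an sklearn-style estimator behind the table contract.

    Fitting cleans the table (class-conditional median imputation), optionally
    oversamples the training rows to balance, and fits the estimator on the
    raw feature matrix; prediction imputes with the stored training medians.
    """

    def __init__(self, estimator, balance_method: str = "none", seed: int = 0):
        self.estimator = estimator
        self.balance_method = balance_method
        self.seed = seed
        self._medians: dict[str, float] | None = None
        self._columns: list[str] | None = None

    def fit(self, table: FeatureTable) -> "SklearnTableClassifier":
        cleaned, log = clean_table(table)
        if self.balance_method != "none":
            cleaned = balance_classes(cleaned, self.balance_method, self.seed)
        self._medians = log.global_medians
        self._columns = cleaned.column_names
        self.estimator.fit(cleaned.values(), cleaned.binary_label())
        return self

    def predict(self, table: FeatureTable) -> np.ndarray:
        if self._columns is None:
            raise ConfigurationError("classifier is not fitted")
        missing = [c for c in self._columns if c not in table.column_names]
        if missing:
            raise SchemaError(f"table is missing columns: {missing}")
        feats = table.features[self._columns].copy()
        for col in self._columns:
            feats[col] = feats[col].fillna(self._medians.get(col, 0.0))
        return np.asarray(self.estimator.predict(feats.to_numpy()), dtype=np.int64)


class CnnPlusClassifier:
    """Table classifier wrapping the full training flow.

    ``head="ensemble"`` predicts with the bagging vote; ``head="softmax"``
    predicts with the plain softmax output layer of the same architecture,
    i.e. the unmodified network baseline.
    """

    def __init__(self, config: CnnPlusConfig | None = None,
                 head: str = "ensemble"):
        if head not in ("ensemble", "softmax"):
            raise ConfigurationError(f"unknown head {head!r}")
        self.config = config or CnnPlusConfig()
        self.head = head
        self.model: CnnPlusModel | None = None

    def fit(self, table: FeatureTable) -> "CnnPlusClassifier":
        self.model = train_cnnplus(table, self.config)
        return self

    def predict(self, table: FeatureTable) -> np.ndarray:
        if self.model is None:
            raise ConfigurationError("classifier is not fitted")
        if self.head == "ensemble":
            return self.model.predict(table)
        return self.model.predict_softmax_head(table)


def default_model_factories(
    base_config: CnnPlusConfig | None = None,
) -> dict:
    """The comparison roster: hybrid model, plain network, and three baselines.

    Each entry maps a model name to ``factory(balanced, seed) -> classifier``;
    the ``balanced`` flag switches training-split oversampling on or off
    inside each model's own flow.
    """
    base_config = base_config or CnnPlusConfig()

    def cnn_like(head):
        def make(balanced: bool, seed: int):
            cfg = replace(
                base_config,
                balance_method="random_oversample" if balanced else "none",
                seed=seed,
                train=replace(base_config.train, seed=seed),
            )
            return CnnPlusClassifier(cfg, head=head)
        return make

    def sklearn_like(builder):
        def make(balanced: bool, seed: int):
            return SklearnTableClassifier(
                builder(seed),
                balance_method="random_oversample" if balanced else "none",
                seed=seed,
            )
        return make

    from sklearn.ensemble import RandomForestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.tree import DecisionTreeClassifier

    return {
        "cnn_bagging": cnn_like("ensemble"),
        "cnn": cnn_like("softmax"),
        "decision_tree": sklearn_like(
            lambda s: DecisionTreeClassifier(max_depth=8, min_samples_leaf=5,
                                             random_state=s)),
        "random_forest": sklearn_like(
            lambda s: RandomForestClassifier(n_estimators=100, random_state=s)),
        "naive_bayes": sklearn_like(lambda s: GaussianNB()),
    }


@dataclass
class BenchmarkResult:
    """Per-model per-repetition reports plus mean/variance summaries."""

    reports: dict[str, list[MetricsReport]]
    summary: dict[str, dict[str, dict[str, float]]]
    errors: dict[str, list[str]]
    repetitions: int
    balanced: bool
    seed: int

    def to_dict(self) -> dict:
        return {
            "repetitions": self.repetitions,
            "balanced": self.balanced,
            "seed": self.seed,
            "summary": self.summary,
            "per_run": {m: [r.to_dict() for r in rs]
                        for m, rs in self.reports.items()},
            "errors": self.errors,
        }

    def summary_rows(self) -> list[dict]:
        rows = []
        for model, metrics in self.summary.items():
            row = {"model": model}
            for metric, stats in metrics.items():
                row[f"{metric}_mean"] = stats["mean"]
                row[f"{metric}_variance"] = stats["variance"]
            rows.append(row)
        return rows


def stratified_split(y: np.ndarray, test_fraction: float, seed: int):
    """Deterministic stratified train/test index split (per-class shuffles)."""
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in (0, 1):
        idx = np.where(y == cls)[0]
        perm = rng.permutation(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.append(perm[:n_test])
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(len(y)), test)
    return train, test


def run_benchmark(
    dataset: FeatureTable,
    models: dict | None = None,
    repetitions: int = 5,
    balanced: bool = True,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> BenchmarkResult:
    """Repeated stratified-split comparison of classifier factories.

    For every repetition each model is built fresh via its factory, fitted on
    the training split (each model balances its own training data if and only
    if ``balanced``), and evaluated on the untouched test split.  A factory
    or fit failure is recorded for that cell and the run continues.
    """
    if repetitions < 1:
        raise ConfigurationError("repetitions must be >= 1")
    if models is None:
        models = default_model_factories()
    y = dataset.binary_label()
    rep_seeds = np.random.default_rng(seed).integers(0, _SEED_CAP, size=repetitions)
    reports: dict[str, list[MetricsReport]] = {m: [] for m in models}
    errors: dict[str, list[str]] = {m: [] for m in models}
    for r, rep_seed in enumerate(map(int, rep_seeds)):
        train_idx, test_idx = stratified_split(y, test_fraction, rep_seed)
        train_tbl = dataset.select_rows(train_idx)
        test_tbl = dataset.select_rows(test_idx)
        test_y = y[test_idx]
        for name, factory in models.items():
            try:
                clf = factory(balanced, rep_seed)
                clf.fit(train_tbl)
                pred = clf.predict(test_tbl)
                reports[name].append(evaluate(test_y, pred))
            except Exception as exc:
                errors[name].append(f"repetition {r}: {exc}")
    summary = {m: aggregate_reports(rs) for m, rs in reports.items() if rs}
    return BenchmarkResult(
        reports=reports, summary=summary, errors=errors,
        repetitions=repetitions, balanced=balanced, seed=seed,
    )
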