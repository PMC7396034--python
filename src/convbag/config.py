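"""Run configuration: documented defaults, YAML/JSON loading, strict keys."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .convnet import TrainConfig
from .errors import ConfigurationError
from .pipeline import CnnPlusConfig
from .preprocess import CleaningPolicy

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Top-level options for the command-line surface.

    Every field has a default; unknown keys in a config file are rejected
    with the list of valid keys.
    """

    input_csv: str = ""
    output_dir: str = "convbag_run"
    label_column: str = "label"

    max_missing_fraction: float = 0.5
    balance_method: str = "random_oversample"
    select_k: int = 36
    keep_features: list[str] = field(default_factory=list)
    contamination: float = 0.05
    iforest_trees: int = 100
    iforest_subsample: int = 256

    learning_rate: float = 1e-4
    max_iterations: int = 1000
    tolerance: float = 1e-6
    batch_size: int = 256

    ensemble_size: int = 21
    tree_max_depth: int = 8
    tree_min_leaf: int = 5

    benchmark_repetitions: int = 5
    benchmark_balanced: bool = True
    benchmark_models: list[str] = field(default_factory=lambda: [
        "cnn_bagging", "cnn", "decision_tree", "random_forest", "naive_bayes",
    ])
    test_fraction: float = 0.2

    seed: int = 0

    def to_pipeline_config(self) -> CnnPlusConfig:
        return CnnPlusConfig(
            cleaning=CleaningPolicy(self.max_missing_fraction),
            balance_method=self.balance_method,
            select_k=self.select_k,
            keep_features=tuple(self.keep_features),
            iforest_trees=self.iforest_trees,
            iforest_subsample=self.iforest_subsample,
            contamination=self.contamination,
            train=TrainConfig(
                learning_rate=self.learning_rate,
                max_iterations=self.max_iterations,
                tolerance=self.tolerance,
                batch_size=self.batch_size,
                seed=self.seed,
            ),
            ensemble_size=self.ensemble_size,
            tree_max_depth=self.tree_max_depth,
            tree_min_leaf=self.tree_min_leaf,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML/JSON file plus overrides.

    Defaults fill every omitted field; an unknown key raises an error that
    lists the valid keys.  The fully resolved config should be echoed to the
    run manifest for reproducibility.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = (json.loads(text) if str(path).endswith(".json")
                  else yaml.safe_load(text))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    valid = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ConfigurationError(
            f"unknown config keys {unknown}; valid keys: {sorted(valid)}"
        )
    return RunConfig(**data)
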