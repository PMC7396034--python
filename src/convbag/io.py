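"""CSV readers/writers, model serialisation, and run manifests.

CSV dialect: comma-separated, UTF-8, mandatory header row; ``"NA"`` and the
empty string are the missing-value tokens.  Labels are coerced to {0, 1}
(missing allowed until cleaning); any other value is an error naming the row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError
from .tables import FeatureTable

__all__ = ["read_feature_table", "write_feature_table", "write_manifest",
           "save_model", "load_model", "MISSING_TOKENS"]

MISSING_TOKENS = ("NA", "")


def read_feature_table(
    path,
    label_column: str = "label",
    missing_tokens: tuple[str, ...] = MISSING_TOKENS,
) -> FeatureTable:
    """Parse a delimited table into a :class:`FeatureTable`.

    Errors carry row/column coordinates: duplicate header names, unparseable
    numeric cells and non-binary label values are all reported explicitly.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise SchemaError(f"duplicate columns in {path.name}: {dupes}")
    if label_column not in header:
        raise SchemaError(f"label column {label_column!r} not found in {path.name}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                      na_values=list(missing_tokens))
    frame = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        values = np.empty(len(raw), dtype=np.float64)
        for i, cell in enumerate(raw[col].to_numpy()):
            if cell is np.nan or (isinstance(cell, float) and np.isnan(cell)):
                values[i] = np.nan
                continue
            try:
                # python float() is correctly rounded; pandas' fast parser
                # can be one ulp off, which would break bit-exact round-trips
                values[i] = float(cell)
            except ValueError:
                raise SchemaError(
                    f"unparseable cell at row {i + 1}, column {col!r}: {cell!r}"
                ) from None
        frame[col] = values
    label = frame.pop(label_column).to_numpy()
    finite = ~np.isnan(label)
    bad_label = finite & ~np.isin(label, (0.0, 1.0))
    if bad_label.any():
        row = int(np.where(bad_label)[0][0])
        raise SchemaError(
            f"non-binary label {label[row]!r} at row {row + 1}"
        )
    return FeatureTable(frame, label)


def write_feature_table(table: FeatureTable, path,
                        label_column: str = "label") -> None:
    """Write features + label as CSV; missing cells become empty fields."""
    table.to_frame(label_column).to_csv(path, index=False)


def write_manifest(path, config_dict: dict, seed: int,
                   extra: dict | None = None) -> None:
    """Record everything needed to reproduce a run bit-for-bit."""
    manifest = {
        "package": "convbag",
        "version": __version__,
        "seed": seed,
        "config": config_dict,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))


# ---------------------------------------------------------------------------
# model persistence: npz archive for the network, JSON for everything else
# ---------------------------------------------------------------------------

def save_model(model, directory) -> None:
    """Serialise a fitted end-to-end model into a directory."""
    from .pipeline import CnnPlusModel  # local import avoids a cycle

    assert isinstance(model, CnnPlusModel)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model.network.save(directory / "network.npz", directory / "network_spec.json")
    state = {
        "imputation_medians": model.imputation_medians,
        "selected_features": model.selected_features,
        "encoder": model.encoder.state_dict(),
        "ranking": {"scores": model.ranking.scores,
                    "ordering": model.ranking.ordering},
        "cleaning_log": model.cleaning_log.to_dict(),
        "outlier_report": vars(model.outlier_report),
        "ensemble_seeds": model.ensemble.bootstrap_seeds,
        "ensemble_n_features": model.ensemble.n_features,
    }
    (directory / "preprocess.json").write_text(json.dumps(state, indent=1))
    ens_dir = directory / "ensemble"
    ens_dir.mkdir(exist_ok=True)
    (ens_dir / "manifest.json").write_text(json.dumps({
        "T": model.ensemble.T,
        "bootstrap_seeds": model.ensemble.bootstrap_seeds,
        "learner_type": type(model.ensemble.learners[0]).__name__,
        "n_features": model.ensemble.n_features,
    }, indent=1))
    for i, learner in enumerate(model.ensemble.learners):
        (ens_dir / f"learner_{i:03d}.json").write_text(
            json.dumps(learner.to_dict())
        )
    model.history.to_csv(directory / "history.csv")


def load_model(directory):
    """Load a model saved by :func:`save_model` (CART ensembles only)."""
    from .bagging import CartTree, EnsembleModel
    from .convnet import Network, TrainingHistory, default_network_spec
    from .pipeline import CnnPlusConfig, CnnPlusModel
    from .preprocess import CleaningLog, GridEncoder, ImportanceRanking, OutlierReport

    directory = Path(directory)
    state = json.loads((directory / "preprocess.json").read_text())
    network = Network.load(default_network_spec(), directory / "network.npz")
    learners = []
    for f in sorted((directory / "ensemble").glob("learner_*.json")):
        learners.append(CartTree.from_dict(json.loads(f.read_text())))
    ensemble = EnsembleModel(
        learners=learners,
        bootstrap_seeds=state["ensemble_seeds"],
        n_features=state["ensemble_n_features"],
    )
    return CnnPlusModel(
        imputation_medians=state["imputation_medians"],
        selected_features=state["selected_features"],
        encoder=GridEncoder.from_state(state["encoder"]),
        network=network,
        ensemble=ensemble,
        ranking=ImportanceRanking(**state["ranking"]),
        cleaning_log=CleaningLog(**state["cleaning_log"]),
        outlier_report=OutlierReport(**state["outlier_report"]),
        history=TrainingHistory(),
        config=CnnPlusConfig(),
    )
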