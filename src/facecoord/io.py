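"""Delimited-text readers/writers shared by the CLI and tests.

Everything is plain CSV: per-participant series files (one row per frame),
per-Tw feature tables (one row per participant), labels, and fold-weight
tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .coordination_features import CoordinationFeatureVector
from .diagnosis_classifier import CohortFeatures

__all__ = [
    "write_labels",
    "read_labels",
    "write_feature_table",
    "read_feature_table",
    "cohort_features_from_tables",
    "write_fold_weights",
    "read_fold_weights",
]


def write_labels(path, participant_ids, labels) -> None:
    pd.DataFrame({"participant": list(participant_ids), "label": list(labels)}).to_csv(
        path, index=False
    )


def read_labels(path) -> tuple[tuple[str, ...], tuple[str, ...]]:
    df = pd.read_csv(path)
    return tuple(df["participant"].astype(str)), tuple(df["label"].astype(str))


def write_feature_table(
    path, participant_ids, vectors: list[CoordinationFeatureVector]
) -> None:
    """One row per participant; header carries the feature names."""
    if len(participant_ids) != len(vectors):
        raise ValueError("one feature vector per participant required")
    names = vectors[0].names
    for v in vectors:
        if v.names != names:
            raise ValueError("feature vectors have inconsistent name order")
    df = pd.DataFrame(
        np.vstack([v.values for v in vectors]),
        columns=list(names),
        index=pd.Index(list(participant_ids), name="participant"),
    )
    df.to_csv(path)


def read_feature_table(path) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Returns (participant_ids, feature_names, values)."""
    df = pd.read_csv(path, index_col="participant")
    return tuple(df.index.astype(str)), tuple(df.columns), df.to_numpy(dtype=float)


def cohort_features_from_tables(
    table_paths: dict[float, Path | str], labels_path
) -> CohortFeatures:
    """Assemble :class:`CohortFeatures` from per-Tw table files + labels."""
    ids, labels = read_labels(labels_path)
    tables = {}
    names: tuple[str, ...] = ()
    for tw, path in table_paths.items():
        t_ids, names, values = read_feature_table(path)
        if t_ids != ids:
            raise ValueError(
                f"participants in {path} do not match the labels file"
            )
        tables[float(tw)] = values
    return CohortFeatures(tables, ids, labels, names)


def write_fold_weights(path, feature_names, mean_abs, stderr) -> None:
    pd.DataFrame(
        {
            "feature": list(feature_names),
            "mean_abs_weight": np.asarray(mean_abs, dtype=float),
            "stderr": np.asarray(stderr, dtype=float),
        }
    ).to_csv(path, index=False)


def read_fold_weights(path) -> pd.DataFrame:
    return pd.read_csv(path)
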