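"""Labeled feature tables and their CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LabeledDataset:
    """Feature matrix (samples x features) with class labels and names."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"{self.features.shape[0]} feature rows vs {self.labels.shape[0]} labels")
        if np.isnan(self.features).any():
            raise ValueError("features must not contain missing values")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.features.shape[1])]
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must match the feature count")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def to_csv(self, path: str | Path, label_column: str = "class") -> None:
        frame = pd.DataFrame(self.features, columns=self.feature_names)
        frame[label_column] = self.labels
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label_column: str = "class") -> "LabeledDataset":
        frame = pd.read_csv(path)
        if label_column not in frame.columns:
            raise ValueError(f"label column {label_column!r} not found in {path}")
        labels = frame[label_column].to_numpy()
        features = frame.drop(columns=[label_column])
        non_numeric = [c for c in features.columns
                       if not np.issubdtype(features[c].dtype, np.number)]
        if non_numeric:
            raise ValueError(f"non-numeric feature columns: {non_numeric}")
        return cls(features.to_numpy(dtype=float), labels, list(features.columns))
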