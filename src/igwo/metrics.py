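"""Classification metrics and the desk-scale wrapper evaluator.

Accuracy, sensitivity and specificity are computed from one-vs-rest
confusion tallies and reported as percentages; degenerate denominators
yield an explicit ``None`` marker rather than a silent zero. The built-in
wrapper evaluator is leave-one-out nearest-neighbour voting on
z-standardized feature columns — parameter-free, deterministic and fast
enough to sit inside an optimization loop. Repeated stratified k-fold
cross-validation (defaults 10 x 10) provides the reported accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from igwo.datasets import LabeledDataset


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN tallies for a single positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(y_true, y_pred, positive_class) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.shape[0] < 1:
        raise ValueError("at least one sample is required")
    true_pos = y_true == positive_class
    pred_pos = y_pred == positive_class
    return ConfusionCounts(
        TP=int(np.sum(true_pos & pred_pos)),
        TN=int(np.sum(~true_pos & ~pred_pos)),
        FP=int(np.sum(~true_pos & pred_pos)),
        FN=int(np.sum(true_pos & ~pred_pos)),
    )


def accuracy(c: ConfusionCounts) -> float | None:
    """``100 (TP+TN) / (TP+TN+FP+FN)``, or None if no samples."""
    if c.total == 0:
        return None
    return 100.0 * (c.TP + c.TN) / c.total


def sensitivity(c: ConfusionCounts) -> float | None:
    """``100 TP / (TP+FN)``, or None when the positive class is empty."""
    if c.TP + c.FN == 0:
        return None
    return 100.0 * c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float | None:
    """``100 TN / (TN+FP)``, or None when the negative class is empty."""
    if c.TN + c.FP == 0:
        return None
    return 100.0 * c.TN / (c.TN + c.FP)


def metrics_report(y_true, y_pred) -> pd.DataFrame:
    """Per-class one-vs-rest metrics plus their macro average.

    The macro row averages only the defined per-class values; undefined
    entries stay missing.
    """
    rows = []
    for cls in np.unique(np.asarray(y_true)):
        c = confusion_counts(y_true, y_pred, cls)
        rows.append({
            "class": cls, "TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN,
            "accuracy": accuracy(c),
            "sensitivity": sensitivity(c),
            "specificity": specificity(c),
        })
    frame = pd.DataFrame(rows)
    macro = {"class": "macro", "TP": "", "TN": "", "FP": "", "FN": ""}
    for col in ("accuracy", "sensitivity", "specificity"):
        defined = frame[col].dropna()
        macro[col] = float(defined.mean()) if len(defined) else None
    return pd.concat([frame, pd.DataFrame([macro])], ignore_index=True)


def _standardize(features: np.ndarray) -> np.ndarray:
    mean = features.mean(axis=0)
    std = features.std(axis=0)
    std[std == 0] = 1.0  # constant columns carry no distance information
    return (features - mean) / std


def _flags_to_columns(flags, n_features: int) -> np.ndarray:
    flags = np.asarray(getattr(flags, "flags", flags)).astype(int)
    if flags.shape[0] != n_features:
        raise ValueError(f"flag vector length {flags.shape[0]} != {n_features} features")
    columns = np.flatnonzero(flags)
    if columns.size == 0:
        raise ValueError("at least one feature must be selected")
    return columns


def _knn_predict(train_x, train_y, test_x, k_neighbors: int) -> np.ndarray:
    distances = cdist(test_x, train_x)
    if k_neighbors == 1:
        return train_y[np.argmin(distances, axis=1)]
    order = np.argsort(distances, axis=1, kind="stable")[:, :k_neighbors]
    predictions = np.empty(test_x.shape[0], dtype=train_y.dtype)
    for i, neighbors in enumerate(order):
        votes = train_y[neighbors]
        classes, counts = np.unique(votes, return_counts=True)
        winners = classes[counts == counts.max()]
        if len(winners) == 1:
            predictions[i] = winners[0]
        else:  # tie: side with the single nearest neighbour among tied classes
            for j in neighbors:
                if train_y[j] in winners:
                    predictions[i] = train_y[j]
                    break
    return predictions


def knn_evaluate(dataset: LabeledDataset, flags, k_neighbors: int = 1) -> float:
    """Leave-one-out k-NN accuracy on the selected, z-standardized columns."""
    if k_neighbors < 1:
        raise ValueError(f"k_neighbors must be >= 1, got {k_neighbors}")
    if dataset.n_samples < k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors+1 = {k_neighbors + 1} samples, "
            f"got {dataset.n_samples}")
    columns = _flags_to_columns(flags, dataset.n_features)
    x = _standardize(dataset.features)[:, columns]
    distances = cdist(x, x)
    np.fill_diagonal(distances, np.inf)
    labels = dataset.labels
    if k_neighbors == 1:
        predictions = labels[np.argmin(distances, axis=1)]
    else:
        order = np.argsort(distances, axis=1, kind="stable")[:, :k_neighbors]
        predictions = np.empty(dataset.n_samples, dtype=labels.dtype)
        for i, neighbors in enumerate(order):
            votes = labels[neighbors]
            classes, counts = np.unique(votes, return_counts=True)
            winners = classes[counts == counts.max()]
            if len(winners) == 1:
                predictions[i] = winners[0]
            else:
                for j in neighbors:
                    if labels[j] in winners:
                        predictions[i] = labels[j]
                        break
    return float(np.mean(predictions == labels))


def make_knn_evaluator(dataset: LabeledDataset, k_neighbors: int = 1):
    """Bind a dataset into a ``flags -> accuracy`` wrapper evaluator.

    Standardization is precomputed once; each call only slices columns and
    recomputes distances, which keeps the wrapper loop fast.
    """
    standardized = _standardize(dataset.features)
    labels = dataset.labels
    n_features = dataset.n_features

    def evaluate(flags) -> float:
        columns = _flags_to_columns(flags, n_features)
        x = standardized[:, columns]
        distances = cdist(x, x)
        np.fill_diagonal(distances, np.inf)
        if k_neighbors == 1:
            predictions = labels[np.argmin(distances, axis=1)]
        else:
            predictions = _loo_vote(distances, labels, k_neighbors)
        return float(np.mean(predictions == labels))

    return evaluate


def _loo_vote(distances: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    order = np.argsort(distances, axis=1, kind="stable")[:, :k]
    predictions = np.empty(labels.shape[0], dtype=labels.dtype)
    for i, neighbors in enumerate(order):
        votes = labels[neighbors]
        classes, counts = np.unique(votes, return_counts=True)
        winners = classes[counts == counts.max()]
        predictions[i] = winners[0] if len(winners) == 1 else next(
            labels[j] for j in neighbors if labels[j] in winners)
    return predictions


def repeated_kfold_accuracy(
    dataset: LabeledDataset,
    flags,
    k_folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    k_neighbors: int = 1,
) -> tuple[float, np.ndarray]:
    """Mean accuracy over repeated stratified k-fold cross-validation.

    Each repeat reshuffles the stratified folds with a seed derived from
    the repeat index, so extending ``repeats`` leaves earlier repeats
    untouched. Returns ``(overall mean, per-repeat means)``.
    """
    classes, counts = np.unique(dataset.labels, return_counts=True)
    too_small = classes[counts < k_folds]
    if too_small.size:
        raise ValueError(
            f"classes {too_small.tolist()} have fewer than k_folds={k_folds} members")
    columns = _flags_to_columns(flags, dataset.n_features)
    x = _standardize(dataset.features)[:, columns]
    y = dataset.labels

    repeat_seeds = np.random.SeedSequence(seed).generate_state(repeats)
    per_repeat = np.empty(repeats)
    for r in range(repeats):
        splitter = StratifiedKFold(
            n_splits=k_folds, shuffle=True, random_state=int(repeat_seeds[r] % 2**31))
        fold_accuracies = []
        for train_idx, test_idx in splitter.split(x, y):
            predictions = _knn_predict(x[train_idx], y[train_idx], x[test_idx], k_neighbors)
            fold_accuracies.append(float(np.mean(predictions == y[test_idx])))
        per_repeat[r] = np.mean(fold_accuracies)
    return float(per_repeat.mean()), per_repeat
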