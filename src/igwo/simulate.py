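"""Seeded synthetic generators: labeled feature tables and disk phantoms.

The feature generator plants a handful of informative Gaussian columns
whose class means are equally spaced by a configurable effect size, mixed
with class-independent standard-normal noise columns — a desk-scale
stand-in for a three-class (normal/benign/malignant) radiomics table. The
phantom generator renders hard-edged bright disks on a flat background
with the matching ground-truth label mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from igwo.datasets import LabeledDataset

DEFAULT_CLASS_NAMES = ("normal", "benign", "malignant")

#: Three disjoint disks (row, col, radius, intensity) for a 128-px phantom.
DEFAULT_NODULES = ((32, 32, 12, 200), (64, 96, 10, 220), (96, 44, 14, 180))


@dataclass
class FeatureGenSpec:
    n_per_class: tuple[int, ...] = (50, 50, 50)
    n_features: int = 30
    n_informative: int = 5
    class_separation: float = 2.0
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != len(self.class_names):
            raise ValueError("n_per_class and class_names lengths differ")
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("all class sizes must be positive")
        if not 0 < self.n_informative <= self.n_features:
            raise ValueError("need 0 < n_informative <= n_features")


@dataclass
class PhantomSpec:
    side: int = 128
    background: int = 30
    nodules: tuple[tuple[int, int, int, int], ...] = DEFAULT_NODULES
    overlap_allowed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side < 8:
            raise ValueError("phantom side must be >= 8 pixels")
        if not 0 <= self.background <= 255:
            raise ValueError("background intensity must lie in [0, 255]")


def make_feature_dataset(spec: FeatureGenSpec) -> tuple[LabeledDataset, np.ndarray]:
    """Generate the dataset plus the planted informative column indices.

    Informative columns get class-dependent means at
    ``(c - (n_classes-1)/2) * class_separation`` with unit variance; all
    other columns are standard normal regardless of class. Informative
    columns are placed at seeded-random positions so recovery scoring is
    non-trivial.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = sum(spec.n_per_class)
    features = rng.standard_normal((n_total, spec.n_features))
    informative = np.sort(rng.choice(spec.n_features, spec.n_informative, replace=False))

    labels = np.repeat(list(spec.class_names), spec.n_per_class)
    n_classes = len(spec.class_names)
    offsets = (np.arange(n_classes) - (n_classes - 1) / 2) * spec.class_separation
    row = 0
    for class_index, n in enumerate(spec.n_per_class):
        features[row:row + n, informative] += offsets[class_index]
        row += n

    dataset = LabeledDataset(
        features, labels, [f"f{i}" for i in range(spec.n_features)])
    return dataset, informative


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the phantom image (uint8) and its ground-truth label mask.

    Disks are labeled 1..k in list order; later disks overwrite earlier
    ones in overlap zones (only reachable when ``overlap_allowed``).
    """
    image = np.full((spec.side, spec.side), spec.background, dtype=np.uint8)
    mask = np.zeros((spec.side, spec.side), dtype=np.int32)
    rows, cols = np.ogrid[: spec.side, : spec.side]
    for label, (r, c, radius, intensity) in enumerate(spec.nodules, start=1):
        if radius < 1:
            raise ValueError(f"nodule {label}: radius must be >= 1")
        if not 0 <= intensity <= 255:
            raise ValueError(f"nodule {label}: intensity must lie in [0, 255]")
        if (r - radius < 0 or c - radius < 0
                or r + radius >= spec.side or c + radius >= spec.side):
            raise ValueError(
                f"nodule {label} at ({r},{c}) radius {radius} exceeds the "
                f"{spec.side}-px image")
        disk = (rows - r) ** 2 + (cols - c) ** 2 <= radius**2
        if not spec.overlap_allowed and (mask[disk] != 0).any():
            raise ValueError(f"nodule {label} overlaps an earlier nodule")
        image[disk] = intensity
        mask[disk] = label
    return image, mask
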