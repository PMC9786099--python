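"""Denoising-filter optimization and nodule segmentation.

The denoising stage searches a small two-family filter space — sliding
median and center-weighted local mean — with the grey wolf optimizer,
scoring candidates by PSNR against a clean reference (a calibration
setting: the reference exists because noise is injected synthetically).
The segmentation stage thresholds, dilates, splits touching blobs by
marker-based watershed on the distance transform, and traces each
region's rim as a closed 8-connected clockwise path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import relabel_sequential, watershed

from igwo.config import OptimizerConfig
from igwo.gwo import run_gwo

#: Sentinel returned by :func:`psnr` for identical images (zero MSE).
INFINITE_PSNR = math.inf

MIN_WINDOW_RADIUS = 1
MAX_WINDOW_RADIUS = 5
MAX_CENTER_WEIGHT_EXPONENT = 3.0  # weight in [1, 10^3]


@dataclass
class FilterSpec:
    """One denoising filter: family, window radius, family-specific weight.

    ``weight_parameter`` is the center weight of the normalized local-mean
    kernel (ignored by the median family); at large weights the filter
    approaches the identity.
    """

    family: str
    window_radius: int = 1
    weight_parameter: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("median", "weighted-mean"):
            raise ValueError(f"unknown filter family {self.family!r}")
        if self.window_radius < MIN_WINDOW_RADIUS:
            raise ValueError(f"window_radius must be >= 1, got {self.window_radius}")
        if self.weight_parameter <= 0:
            raise ValueError(f"weight_parameter must be positive, got {self.weight_parameter}")

    @property
    def window_side(self) -> int:
        return 2 * self.window_radius + 1


@dataclass
class SegmentationResult:
    labeled_mask: np.ndarray
    boundaries: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def region_count(self) -> int:
        return int(self.labeled_mask.max())


def _declared_max(image: np.ndarray) -> float:
    return 255.0 if image.dtype == np.uint8 else 1.0


def psnr(reference: np.ndarray, test: np.ndarray, max_value: float | None = None) -> float:
    """``10 log10(MAX^2 / MSE)`` in dB; identical images give ``inf``.

    MAX defaults to 255 for uint8 inputs and 1.0 for float inputs.
    """
    reference = np.asarray(reference)
    test = np.asarray(test)
    if reference.shape != test.shape:
        raise ValueError(f"image shapes differ: {reference.shape} vs {test.shape}")
    if max_value is None:
        if (reference.dtype == np.uint8) != (test.dtype == np.uint8):
            raise ValueError("images declare different ranges; pass max_value explicitly")
        max_value = _declared_max(reference)
    mse = float(np.mean((reference.astype(float) - test.astype(float)) ** 2))
    if mse == 0.0:
        return INFINITE_PSNR
    return 10.0 * math.log10(max_value**2 / mse)


def add_noise(
    image: np.ndarray,
    model: str,
    level: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inject gaussian (sigma = level, clipped) or salt-pepper noise.

    Salt-pepper replaces each pixel independently with the range minimum
    or maximum, each with probability ``level / 2``. The output keeps the
    input's dtype and declared range.
    """
    if level < 0:
        raise ValueError(f"noise level must be >= 0, got {level}")
    image = np.asarray(image)
    max_value = _declared_max(image)
    if model == "gaussian":
        noisy = image.astype(float) + rng.normal(0.0, level, image.shape)
        noisy = np.clip(noisy, 0.0, max_value)
        return np.rint(noisy).astype(np.uint8) if image.dtype == np.uint8 else noisy
    if model == "salt-pepper":
        u = rng.random(image.shape)
        noisy = image.copy()
        noisy[u < level / 2] = 0
        noisy[u > 1 - level / 2] = max_value
        return noisy
    raise ValueError(f"unknown noise model {model!r}")


def apply_filter(image: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Run one filter over the image with edge replication.

    median: sliding-window median. weighted-mean: local mean whose kernel
    is all ones except a ``weight_parameter`` center, normalized to unit
    sum, so outputs stay inside the input range.
    """
    image = np.asarray(image)
    if spec.window_side > min(image.shape):
        raise ValueError(
            f"window side {spec.window_side} exceeds image extent {image.shape}")
    if spec.family == "median":
        return ndi.median_filter(image, size=spec.window_side, mode="nearest")
    kernel = np.ones((spec.window_side, spec.window_side))
    kernel[spec.window_radius, spec.window_radius] = spec.weight_parameter
    kernel /= kernel.sum()
    filtered = ndi.convolve(image.astype(float), kernel, mode="nearest")
    filtered = np.clip(filtered, 0.0, _declared_max(image))
    return np.rint(filtered).astype(np.uint8) if image.dtype == np.uint8 else filtered


def decode_filter_position(position: np.ndarray) -> FilterSpec:
    """Map a point of [0,1]^3 onto (family, window radius, center weight)."""
    family = "median" if position[0] < 0.5 else "weighted-mean"
    radius_span = MAX_WINDOW_RADIUS - MIN_WINDOW_RADIUS
    radius = MIN_WINDOW_RADIUS + int(round(float(position[1]) * radius_span))
    weight = 10.0 ** (MAX_CENTER_WEIGHT_EXPONENT * float(position[2]))
    return FilterSpec(family, radius, weight)


def optimize_filter(
    noisy: np.ndarray,
    reference: np.ndarray,
    config: OptimizerConfig | None = None,
) -> tuple[FilterSpec, float]:
    """Search the filter space for the spec maximizing PSNR to the reference.

    A near-identity filter (radius 1, extreme center weight) is inside
    the space, so the achieved PSNR is effectively bounded below by the
    unfiltered image's PSNR. Identical inputs short-circuit with the
    infinite-PSNR marker.
    """
    if config is None:
        config = OptimizerConfig()
    if np.array_equal(np.asarray(noisy), np.asarray(reference)):
        return FilterSpec("weighted-mean", MIN_WINDOW_RADIUS,
                          10.0**MAX_CENTER_WEIGHT_EXPONENT), INFINITE_PSNR
    config = config.with_(dimensionality=3, domain_low=0.0, domain_high=1.0,
                          orientation="maximize")
    cache: dict[tuple, float] = {}

    def objective(position: np.ndarray) -> float:
        spec = decode_filter_position(position)
        key = (spec.family, spec.window_radius, round(spec.weight_parameter, 6))
        if key not in cache:
            value = psnr(reference, apply_filter(noisy, spec))
            # clamp the zero-MSE sentinel so the optimizer sees finite values
            cache[key] = min(value, 10.0 * math.log10(_declared_max(noisy) ** 2 * 1e16))
        return cache[key]

    result = run_gwo(objective, config)
    best_spec = decode_filter_position(result.best_position)
    achieved = psnr(reference, apply_filter(noisy, best_spec))
    return best_spec, achieved


def segment_nodules(
    image: np.ndarray,
    threshold_method: str | float = "otsu",
    dilation_radius: int = 2,
) -> SegmentationResult:
    """Threshold, dilate, watershed-split and trace nodule regions.

    The binary foreground (global threshold: Otsu by default, or a fixed
    value) is dilated with a disk, then split by marker-based watershed
    on the euclidean distance transform; markers are distance-transform
    local maxima separated by at least ``dilation_radius``. The labeled
    regions are then restricted to the morphological closing of the
    foreground, so the dilation fills holes and bridges fragments without
    inflating region size. Labels are relabeled consecutively from 1 and
    each region's rim is traced as a closed clockwise 8-connected path
    starting at its topmost-leftmost pixel. An all-background image
    yields ``region_count == 0``.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("segmentation expects a 2-D grayscale image")
    if dilation_radius < 0:
        raise ValueError(f"dilation_radius must be >= 0, got {dilation_radius}")
    if isinstance(threshold_method, str):
        if threshold_method != "otsu":
            raise ValueError(f"unknown threshold method {threshold_method!r}")
        if np.all(image == image.flat[0]):  # constant image: nothing to segment
            return SegmentationResult(np.zeros(image.shape, dtype=np.int32))
        threshold = threshold_otsu(image)
    else:
        threshold = float(threshold_method)
    binary = image > threshold
    if not binary.any():
        return SegmentationResult(np.zeros(image.shape, dtype=np.int32))
    if dilation_radius > 0:
        structure = disk(dilation_radius)
        dilated = ndi.binary_dilation(binary, structure=structure)
        closed = ndi.binary_erosion(dilated, structure=structure)
    else:
        dilated = closed = binary

    distance = ndi.distance_transform_edt(dilated)
    peak_coords = peak_local_max(
        distance, min_distance=max(1, dilation_radius), labels=dilated,
        exclude_border=False)
    markers = np.zeros(image.shape, dtype=np.int32)
    markers[tuple(peak_coords.T)] = 1
    markers, _ = ndi.label(markers)
    labels = watershed(-distance, markers, mask=dilated)
    labels[~closed] = 0
    labels, _, _ = relabel_sequential(labels)
    labels = labels.astype(np.int32)

    boundaries = {
        int(lab): trace_boundary(labels == lab) for lab in range(1, labels.max() + 1)
    }
    return SegmentationResult(labels, boundaries)


_CLOCKWISE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def trace_boundary(region: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbour rim trace: closed, clockwise, 8-connected.

    Starts at the topmost-leftmost pixel of the region and walks the rim
    clockwise; a single-pixel region traces to just that pixel.
    """
    region = np.asarray(region, dtype=bool)
    pixels = np.argwhere(region)
    if pixels.shape[0] == 0:
        return []
    start = tuple(pixels[np.lexsort((pixels[:, 1], pixels[:, 0]))][0])
    if pixels.shape[0] == 1:
        return [start]

    def inside(p: tuple[int, int]) -> bool:
        return (0 <= p[0] < region.shape[0] and 0 <= p[1] < region.shape[1]
                and region[p])

    trace = [start]
    # entered the start from above (outside, since start is topmost-leftmost)
    backtrack_dir = 0  # index into _CLOCKWISE pointing at the previous (outside) pixel
    current = start
    while True:
        found = False
        for step in range(1, 9):
            d = (backtrack_dir + step) % 8
            candidate = (current[0] + _CLOCKWISE[d][0], current[1] + _CLOCKWISE[d][1])
            if inside(candidate):
                # next backtrack: direction from candidate toward the last
                # outside pixel checked (one step counter-clockwise)
                backtrack_dir = (d + 4 + 1) % 8
                current = candidate
                found = True
                break
        if not found:  # isolated pixel surrounded by background
            break
        if current == start and len(trace) > 1:
            break
        trace.append(current)
    return trace


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image from PNG/TIFF, or DICOM when pydicom exists."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        try:
            import pydicom
        except ImportError as exc:
            raise RuntimeError(
                "DICOM input requires the optional pydicom package") from exc
        pixels = pydicom.dcmread(path).pixel_array
        return np.asarray(pixels)
    image = iio.imread(path)
    if image.ndim == 3:  # collapse RGB(A) to luminance
        image = np.rint(image[..., :3].mean(axis=-1)).astype(image.dtype)
    return image


def write_image(path: str | Path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        image = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), image)
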