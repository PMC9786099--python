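import math

import numpy as np
import pytest
from matplotlib.path import Path as MplPath

from igwo.config import OptimizerConfig
from igwo.imaging import (
    INFINITE_PSNR,
    FilterSpec,
    add_noise,
    apply_filter,
    decode_filter_position,
    optimize_filter,
    psnr,
    segment_nodules,
    trace_boundary,
)
from igwo.simulate import PhantomSpec, make_phantom


def disk_image(centers_radii, side=128, background=30, intensity=200):
    rows, cols = np.ogrid[:side, :side]
    image = np.full((side, side), background, dtype=np.uint8)
    for r, c, radius in centers_radii:
        image[(rows - r) ** 2 + (cols - c) ** 2 <= radius**2] = intensity
    return image


class TestPsnr:
    def test_identical_images(self, phantom):
        image, _ = phantom
        assert psnr(image, image.copy()) == INFINITE_PSNR

    def test_constant_offset_closed_form(self):
        a = np.full((32, 32), 100, dtype=np.uint8)
        b = np.full((32, 32), 116, dtype=np.uint8)
        assert psnr(a, b) == pytest.approx(20 * math.log10(255 / 16), abs=1e-9)

    def test_noise_ladder_monotone(self, phantom):
        image, _ = phantom
        rng = np.random.default_rng(0)
        small = add_noise(image, "gaussian", 5.0, rng)
        rng = np.random.default_rng(0)
        large = add_noise(image, "gaussian", 20.0, rng)
        assert psnr(image, large) < psnr(image, small)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_float_range(self):
        a = np.zeros((8, 8))
        b = np.full((8, 8), 0.1)
        assert psnr(a, b) == pytest.approx(10 * math.log10(1.0 / 0.01))


class TestAddNoise:
    def test_zero_level_identity(self, phantom, rng):
        image, _ = phantom
        assert np.array_equal(add_noise(image, "gaussian", 0.0, rng), image)

    def test_salt_pepper_saturation(self, phantom, rng):
        image, _ = phantom
        noisy = add_noise(image, "salt-pepper", 1.0, rng)
        assert np.isin(noisy, (0, 255)).all()

    def test_gaussian_moment(self, phantom):
        image, _ = phantom
        # measure away from clip boundaries
        base = np.full((100, 100), 128, dtype=np.uint8)
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = add_noise(base, "gaussian", 10.0, rng)
            diffs.append((noisy.astype(float) - 128.0).std())
        assert abs(np.mean(diffs) - 10.0) < 1.0

    def test_unknown_model(self, phantom, rng):
        image, _ = phantom
        with pytest.raises(ValueError):
            add_noise(image, "speckle", 0.1, rng)


class TestApplyFilter:
    def test_constant_image_unchanged(self):
        image = np.full((16, 16), 42, dtype=np.uint8)
        for spec in (FilterSpec("median", 2), FilterSpec("weighted-mean", 2, 3.0)):
            assert np.array_equal(apply_filter(image, spec), image)

    def test_median_restores_salt_pixel(self):
        image = np.full((9, 9), 50, dtype=np.uint8)
        image[4, 4] = 255
        out = apply_filter(image, FilterSpec("median", 1))
        assert out[4, 4] == 50

    def test_large_center_weight_approaches_identity(self, phantom):
        image, _ = phantom
        rng = np.random.default_rng(0)
        noisy = add_noise(image, "gaussian", 10.0, rng)
        # float path avoids uint8 quantization ties at exactly 1.0
        noisy_float = noisy.astype(float) / 255.0
        out = apply_filter(noisy_float, FilterSpec("weighted-mean", 1, 1e3))
        assert np.max(np.abs(out - noisy_float)) * 255.0 < 1.0

    def test_output_stays_in_range(self, phantom, rng):
        image, _ = phantom
        noisy = add_noise(image, "salt-pepper", 0.2, rng)
        for spec in (FilterSpec("median", 3), FilterSpec("weighted-mean", 2, 0.5)):
            out = apply_filter(noisy, spec)
            assert out.min() >= 0 and out.max() <= 255

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            apply_filter(np.zeros((5, 5), dtype=np.uint8), FilterSpec("median", 4))

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            FilterSpec("bilateral", 1)


class TestOptimizeFilter:
    def test_degenerate_input_short_circuits(self, phantom):
        image, _ = phantom
        spec, achieved = optimize_filter(image, image)
        assert achieved == INFINITE_PSNR

    def test_improvement_over_noisy(self, phantom):
        image, _ = phantom
        rng = np.random.default_rng(0)
        noisy = add_noise(image, "salt-pepper", 0.05, rng)
        config = OptimizerConfig(iterations=20, seed=0)
        _, achieved = optimize_filter(noisy, image, config)
        assert achieved >= psnr(image, noisy)

    def test_two_noise_conditions(self, phantom):
        image, _ = phantom
        config = OptimizerConfig(iterations=15, seed=0)
        for model, level in (("gaussian", 10.0), ("salt-pepper", 0.05)):
            rng = np.random.default_rng(1)
            noisy = add_noise(image, model, level, rng)
            _, achieved = optimize_filter(noisy, image, config)
            assert achieved >= psnr(image, noisy)

    def test_decode_covers_space(self):
        low = decode_filter_position(np.array([0.0, 0.0, 0.0]))
        high = decode_filter_position(np.array([1.0, 1.0, 1.0]))
        assert low.family == "median" and low.window_radius == 1
        assert high.family == "weighted-mean" and high.window_radius == 5
        assert high.weight_parameter == pytest.approx(1000.0)


class TestSegmentNodules:
    def test_all_background(self):
        result = segment_nodules(np.zeros((32, 32), dtype=np.uint8))
        assert result.region_count == 0

    def test_three_disjoint_disks(self, phantom):
        image, gt = phantom
        result = segment_nodules(image)
        assert result.region_count == 3
        for lab in range(1, 4):
            gt_mask = gt == lab
            iou = max(
                (np.logical_and(result.labeled_mask == k, gt_mask).sum()
                 / np.logical_or(result.labeled_mask == k, gt_mask).sum())
                for k in range(1, 4))
            assert iou >= 0.9

    def test_touching_disks_split_by_watershed(self):
        from scipy import ndimage as ndi
        image = disk_image([(64, 50, 14), (64, 70, 14)])
        assert ndi.label(image > 100)[0].max() == 1  # plain threshold merges
        assert segment_nodules(image).region_count == 2

    def test_intensity_rescale_invariance(self, phantom):
        image, _ = phantom
        rescaled = (image // 2).astype(np.uint8)
        a = segment_nodules(image)
        b = segment_nodules(rescaled)
        assert a.region_count == b.region_count
        assert np.array_equal(a.labeled_mask, b.labeled_mask)

    def test_boundaries_closed_and_on_rim(self, phantom):
        image, _ = phantom
        result = segment_nodules(image)
        for lab, trace in result.boundaries.items():
            region = result.labeled_mask == lab
            trace_arr = np.array(trace)
            # every trace pixel belongs to the region and touches background
            for r, c in trace:
                assert region[r, c]
            # closed 8-connected path
            loop = np.vstack([trace_arr, trace_arr[:1]])
            steps = np.abs(np.diff(loop, axis=0)).max(axis=1)
            assert (steps <= 1).all()
            # starts at topmost-leftmost region pixel
            pixels = np.argwhere(region)
            start = pixels[np.lexsort((pixels[:, 1], pixels[:, 0]))][0]
            assert tuple(trace[0]) == tuple(start)

    def test_boundary_encloses_disk_center(self, phantom):
        image, gt = phantom
        result = segment_nodules(image)
        centers = [tuple(np.argwhere(gt == lab).mean(axis=0)) for lab in range(1, 4)]
        for trace in result.boundaries.values():
            path = MplPath(np.array(trace))
            assert any(path.contains_point(center) for center in centers)

    def test_fixed_threshold(self, phantom):
        image, _ = phantom
        result = segment_nodules(image, threshold_method=100.0)
        assert result.region_count == 3

    def test_single_pixel_region_traces_itself(self):
        region = np.zeros((5, 5), dtype=bool)
        region[2, 3] = True
        assert trace_boundary(region) == [(2, 3)]

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            segment_nodules(np.zeros((4, 4, 3), dtype=np.uint8))
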