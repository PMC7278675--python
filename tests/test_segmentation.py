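"""Thresholding, morphology, wand selection and three-phase classification."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from crumbscope.segmentation import (
    ComponentMasks,
    DegenerateHistogramError,
    SegmentationConfig,
    classify_pixels,
    morph_clean,
    otsu_threshold,
    triangle_threshold,
    wand_select,
)

# ---------------------------------------------------------------- oracles


def otsu_brute_force(image):
    """Exhaustive scan of all 255 cut points for max between-class variance."""
    hist = np.bincount(image.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_v = 0, -1.0
    for t in range(255):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        v = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def triangle_brute_force(image):
    """Literal per-bin geometric distance scan (peak to far tail line)."""
    hist = np.bincount(image.ravel(), minlength=256).astype(float)
    occ = np.flatnonzero(hist)
    peak = int(np.argmax(hist))
    lo, hi = int(occ[0]), int(occ[-1])
    tail = hi if (hi - peak) >= (peak - lo) else lo
    a, b = min(peak, tail), max(peak, tail)
    best_bin, best_d = a, -1.0
    dx, dy = tail - peak, hist[tail] - hist[peak]
    norm = np.hypot(dx, dy)
    for bin_ in range(a + 1, b):
        d = abs(dy * (bin_ - peak) - dx * (hist[bin_] - hist[peak])) / norm
        if d > best_d + 1e-12:
            best_d, best_bin = d, bin_
    return best_bin


def flood_fill_bfs(image, seed, tolerance, connectivity):
    """Breadth-first tolerance flood fill."""
    h, w = image.shape
    ref = int(image[seed])
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    mask = np.zeros((h, w), dtype=bool)
    mask[seed] = True
    queue = deque([seed])
    while queue:
        r, c = queue.popleft()
        for dr, dc in steps:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and not mask[nr, nc]:
                if abs(int(image[nr, nc]) - ref) <= tolerance:
                    mask[nr, nc] = True
                    queue.append((nr, nc))
    return mask


# ------------------------------------------------------------- thresholds


class TestOtsu:
    def test_perfect_two_class_separation(self):
        img = np.concatenate(
            [np.full(60, 10, np.uint8), np.full(40, 200, np.uint8)]
        ).reshape(10, 10)
        t = otsu_threshold(img)
        assert 10 <= t < 200
        assert ((img > t) == (img == 200)).all()

    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        for _ in range(30):
            img = rng.integers(0, 256, size=(24, 24), dtype=np.uint8)
            assert otsu_threshold(img) == otsu_brute_force(img)

    def test_symmetric_histogram_inversion_relation(self):
        # dense symmetric bimodal histogram: inverting intensities
        # reflects the optimal cut about the midpoint, t' = 255 - t - 1
        # (dense so the variance maximizer is a single bin, not a
        # plateau between occupied bins)
        counts = np.ones(256, int)
        counts[40:80] += 10
        counts[176:216] += 10  # mirror of [40, 80) about 127.5
        img = np.repeat(np.arange(256, dtype=np.uint8), counts)
        t = otsu_threshold(img)
        t_inv = otsu_threshold(255 - img)
        assert t_inv == 255 - t - 1

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full((8, 8), 7, np.uint8))


class TestTriangle:
    def test_decay_histogram_threshold_between_peak_and_tail(self, rng):
        # exponential-decay histogram peaked at 0
        vals = np.clip(rng.exponential(20, size=4096), 0, 255).astype(np.uint8)
        t = triangle_threshold(vals.reshape(64, 64))
        assert 0 < t < int(vals.max())

    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        for _ in range(30):
            img = rng.integers(0, 256, size=(24, 24), dtype=np.uint8)
            assert triangle_threshold(img) == triangle_brute_force(img)

    def test_tie_break_takes_lowest_bin(self):
        # flat valley between peak and tail: several bins at equal
        # distance; the lowest must win
        img = np.repeat(
            np.array([0] * 100 + [50] * 10 + [100] * 10 + [150] * 10 + [200] * 10),
            2,
        ).astype(np.uint8)
        t = triangle_threshold(img.reshape(-1, 10))
        assert t == triangle_brute_force(img.reshape(-1, 10))

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateHistogramError):
            triangle_threshold(np.zeros((8, 8), np.uint8))


# ------------------------------------------------------------- morphology


class TestMorphClean:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = True
        assert not morph_clean(mask).any()

    def test_large_square_restored_by_opening(self):
        mask = np.zeros((120, 120), bool)
        mask[10:110, 10:110] = True
        out = morph_clean(mask)
        # square element: erosion then dilation restores the square exactly
        np.testing.assert_array_equal(out, mask)

    def test_zero_iterations_is_identity(self, rng):
        mask = rng.random((30, 30)) > 0.5
        np.testing.assert_array_equal(morph_clean(mask, 0, 0), mask)

    def test_opening_never_escapes_dilation_closure(self, rng):
        # the opened mask is always contained in the dilation of the input
        st3 = np.ones((3, 3), bool)
        for _ in range(10):
            mask = rng.random((40, 40)) > 0.6
            opened = morph_clean(mask)
            closure = ndi.binary_dilation(mask, st3, iterations=2)
            assert not (opened & ~closure).any()


# ------------------------------------------------------------------ wand


class TestWandSelect:
    def test_uniform_image_selects_full_frame(self):
        img = np.full((16, 16), 80, np.uint8)
        assert wand_select(img, (3, 3), tolerance=0).all()

    def test_zero_tolerance_selects_equal_valued_region(self):
        img = np.zeros((10, 10), np.uint8)
        img[2:5, 2:5] = 100
        mask = wand_select(img, (3, 3), tolerance=0)
        np.testing.assert_array_equal(mask, img == 100)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_bfs_oracle_on_random_images(self, rng, connectivity):
        for _ in range(10):
            img = rng.integers(0, 6, size=(20, 20), dtype=np.uint8) * 40
            seed = tuple(rng.integers(0, 20, size=2))
            got = wand_select(img, seed, tolerance=4, connectivity=connectivity)
            want = flood_fill_bfs(img, seed, 4, connectivity)
            np.testing.assert_array_equal(got, want)

    def test_idempotent_under_reseeding_inside_selection(self, rng):
        img = rng.integers(0, 4, size=(24, 24), dtype=np.uint8) * 60
        seed = (5, 5)
        mask = wand_select(img, seed, tolerance=2)
        rows, cols = np.nonzero(mask)
        for i in range(0, len(rows), max(1, len(rows) // 7)):
            again = wand_select(img, (rows[i], cols[i]), tolerance=2)
            np.testing.assert_array_equal(again, mask)

    def test_out_of_bounds_seed_raises(self):
        with pytest.raises(IndexError):
            wand_select(np.zeros((5, 5), np.uint8), (9, 0))


# --------------------------------------------------------- classification


class TestClassifyPixels:
    def test_dark_oil_bright_matrix_is_all_solid(self):
        masks = classify_pixels(
            np.full((32, 32), 255, np.uint8), np.zeros((32, 32), np.uint8)
        )
        assert masks.solid.all()
        assert not masks.oil.any() and not masks.empty.any()

    def test_saturated_oil_channel_gives_full_oil_fraction(self):
        masks = classify_pixels(
            np.zeros((32, 32), np.uint8), np.full((32, 32), 255, np.uint8)
        )
        assert masks.oil.all()

    def test_both_channels_constant_raises(self):
        flat = np.full((16, 16), 9, np.uint8)
        with pytest.raises(DegenerateHistogramError):
            classify_pixels(flat, flat)

    def test_oil_priority_where_channels_overlap(self):
        matrix = np.zeros((40, 40), np.uint8)
        matrix[:, :30] = 200
        oil = np.zeros((40, 40), np.uint8)
        oil[:, 20:] = 200
        masks = classify_pixels(matrix, oil)
        # the overlap column band must be oil, not solid
        assert masks.oil[:, 22:28].all()
        assert not masks.solid[:, 22:28].any()

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_property_on_random_inputs(self, seed):
        r = np.random.default_rng(seed)
        matrix = r.integers(0, 256, (24, 24), dtype=np.uint8)
        oil = r.integers(0, 256, (24, 24), dtype=np.uint8)
        masks = classify_pixels(matrix, oil)
        total = (
            masks.solid.astype(int) + masks.oil.astype(int) + masks.empty.astype(int)
        )
        assert (total == 1).all()

    def test_component_masks_reject_overlap(self):
        ones = np.ones((4, 4), bool)
        with pytest.raises(ValueError, match="partition"):
            ComponentMasks(solid=ones, oil=ones, empty=~ones)

    def test_explicit_thresholds_from_config(self):
        matrix = np.tile(np.arange(0, 240, 10, np.uint8), (24, 1))
        oil = np.zeros_like(matrix)
        cfg = SegmentationConfig(
            matrix_threshold=100, oil_threshold=0, n_erode=0, n_dilate=0
        )
        masks = classify_pixels(matrix, oil, cfg)
        np.testing.assert_array_equal(masks.solid, matrix > 100)

    def test_config_loadable_from_yaml(self, tmp_path):
        p = tmp_path / "seg.yaml"
        p.write_text("matrix_threshold: 80\nn_erode: 1\nwand_tolerance: 3\n")
        cfg = SegmentationConfig.from_yaml(p)
        assert cfg.matrix_threshold == 80
        assert cfg.n_erode == 1 and cfg.n_dilate == 2
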