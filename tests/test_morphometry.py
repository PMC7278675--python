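"""Particle labelling, shape descriptors, histograms and crumb metrics."""

import math
from collections import deque

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk, ellipse, polygon

from crumbscope.morphometry import (
    compute_crumb_metrics,
    label_particles,
    particle_features,
    pore_size_histogram,
    summarize_particles,
)
from crumbscope.segmentation import ComponentMasks


def count_components_bfs(mask, connectivity):
    """Flood-fill component count oracle."""
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    n = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                n += 1
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    rr, cc = queue.popleft()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if (
                            0 <= nr < h
                            and 0 <= nc < w
                            and mask[nr, nc]
                            and not seen[nr, nc]
                        ):
                            seen[nr, nc] = True
                            queue.append((nr, nc))
    return n


def shape_mask(draw_fn, shape=(220, 220)):
    m = np.zeros(shape, bool)
    rr, cc = draw_fn()
    m[rr, cc] = True
    return m


class TestLabelParticles:
    def test_diagonal_pixels_connectivity(self):
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_particles(mask, connectivity=4).max() == 2
        assert label_particles(mask, connectivity=8).max() == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_label_count_matches_bfs_oracle(self, rng, connectivity):
        for _ in range(8):
            mask = rng.random((30, 30)) > 0.65
            got = label_particles(mask, connectivity).max()
            assert got == count_components_bfs(mask, connectivity)


class TestParticleFeatures:
    def test_disk_circularity_near_one(self):
        mask = shape_mask(lambda: disk((110, 110), 50))
        t = particle_features(label_particles(mask), pixel_size_um=1.0)
        assert 0.95 <= t.loc[0, "circularity"] <= 1.0

    def test_square_circularity_matches_polygonal_value(self):
        mask = np.zeros((200, 200), bool)
        mask[50:150, 50:150] = True
        t = particle_features(label_particles(mask), pixel_size_um=1.0)
        assert t.loc[0, "circularity"] == pytest.approx(math.pi / 4, abs=0.02)

    def test_convex_shapes_have_high_solidity(self):
        for fn in (lambda: disk((110, 110), 50), lambda: ellipse(110, 110, 40, 80)):
            t = particle_features(
                label_particles(shape_mask(fn)), pixel_size_um=1.0
            )
            assert t.loc[0, "solidity"] >= 0.98

    def test_star_solidity_below_convex_hull_oracle_bound(self):
        # 5-pointed star: hull is the outer pentagon, area ratio well < 0.8
        ang = np.linspace(-np.pi / 2, 1.5 * np.pi, 11)[:-1]
        radius = np.where(np.arange(10) % 2 == 0, 80, 30)
        pr = 110 + radius * np.sin(ang)
        pc = 110 + radius * np.cos(ang)
        mask = shape_mask(lambda: polygon(pr, pc))
        t = particle_features(label_particles(mask), pixel_size_um=1.0)
        assert t.loc[0, "solidity"] < 0.8

    def test_circularity_scale_invariance(self):
        cs = []
        for scale in (1, 2):
            mask = shape_mask(
                lambda: ellipse(110 * scale, 110 * scale, 30 * scale, 60 * scale),
                shape=(240 * scale, 240 * scale),
            )
            t = particle_features(label_particles(mask), pixel_size_um=1.0)
            cs.append(t.loc[0, "circularity"])
        assert abs(cs[0] - cs[1]) < 0.05

    def test_physical_units_scale_with_pixel_size(self):
        mask = np.zeros((60, 60), bool)
        mask[10:40, 10:40] = True
        labels = label_particles(mask)
        t1 = particle_features(labels, pixel_size_um=1.0)
        t2 = particle_features(labels, pixel_size_um=2.768)
        assert t2.loc[0, "area_um2"] == pytest.approx(
            t1.loc[0, "area_um2"] * 2.768**2
        )
        assert t2.loc[0, "perimeter_um"] == pytest.approx(
            t1.loc[0, "perimeter_um"] * 2.768
        )
        # circularity is dimensionless
        assert t2.loc[0, "circularity"] == pytest.approx(t1.loc[0, "circularity"])

    def test_min_area_filter_and_border_flag(self):
        mask = np.zeros((30, 30), bool)
        mask[0:5, 0:5] = True  # touches border
        mask[20, 20] = True  # single pixel, dropped
        t = particle_features(label_particles(mask), pixel_size_um=1.0)
        assert len(t) == 1
        assert bool(t.loc[0, "touches_border"])

    def test_empty_labeling_gives_empty_table(self):
        t = particle_features(np.zeros((10, 10), int), pixel_size_um=1.0)
        assert len(t) == 0


class TestSummary:
    def test_three_equal_particles(self):
        t = pd.DataFrame(
            {
                "area_um2": [100.0, 100.0, 100.0],
                "perimeter_um": [40.0, 40.0, 40.0],
                "circularity": [0.9, 0.8, 0.7],
                "solidity": [1.0, 1.0, 1.0],
            }
        )
        s = summarize_particles(t)
        assert s.count == 3
        assert s.total_area_um2 == pytest.approx(300.0)
        assert s.average_size_um2 == pytest.approx(100.0)

    def test_empty_table_has_nan_means(self):
        s = summarize_particles(pd.DataFrame(columns=["area_um2"]))
        assert s.count == 0 and s.total_area_um2 == 0.0
        assert math.isnan(s.average_size_um2)

    def test_mean_size_times_count_equals_total(self, small_crumb):
        _, truth = small_crumb
        s = summarize_particles(truth.true_particle_table)
        assert s.average_size_um2 * s.count == pytest.approx(
            s.total_area_um2, rel=1e-9
        )


class TestPoreSizeHistogram:
    def test_small_diameters_land_in_first_bin(self):
        t = pd.DataFrame({"equiv_diameter_um": [10.0, 12.0, 3.0]})
        d = pore_size_histogram(t)
        assert d.frequency_pct[0] == pytest.approx(100.0)
        assert d.bin_edges_um[1] == pytest.approx(25.0)

    def test_uniform_diameters_spread_evenly(self, rng):
        t = pd.DataFrame({"equiv_diameter_um": rng.uniform(0, 100, 40_000)})
        d = pore_size_histogram(t, bin_width_um=25)
        np.testing.assert_allclose(d.frequency_pct[:4], 25.0, atol=1.5)
        assert d.frequency_pct.sum() == pytest.approx(100.0)

    def test_empty_table_all_zero(self):
        d = pore_size_histogram(pd.DataFrame(columns=["equiv_diameter_um"]))
        assert not d.frequency_pct.any()
        assert d.bin_edges_um[-1] == pytest.approx(500.0)


class TestCrumbMetrics:
    @staticmethod
    def masks_from_fractions(empty_frac, oil_frac, size=100):
        n = size * size
        flat = np.zeros(n, np.uint8)
        flat[: int(n * empty_frac)] = 1
        flat[int(n * empty_frac) : int(n * (empty_frac + oil_frac))] = 2
        grid = flat.reshape(size, size)
        return ComponentMasks(solid=grid == 0, empty=grid == 1, oil=grid == 2)

    def test_direct_substitution(self):
        m = compute_crumb_metrics(self.masks_from_fractions(0.30, 0.20))
        assert m.porosity_pct == pytest.approx(50.0)
        assert m.poia_pct == pytest.approx(20.0)

    def test_all_solid_frame(self):
        m = compute_crumb_metrics(self.masks_from_fractions(0.0, 0.0))
        assert m.porosity_pct == 0.0 and m.poia_pct == 0.0

    def test_porosity_and_solid_fraction_are_complementary(self, rng):
        for _ in range(10):
            e, o = rng.uniform(0, 0.5, 2)
            masks = self.masks_from_fractions(e, o)
            m = compute_crumb_metrics(masks)
            solid_pct = masks.solid.mean() * 100
            assert m.porosity_pct + solid_pct == pytest.approx(100.0)
            assert m.poia_pct <= m.porosity_pct
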