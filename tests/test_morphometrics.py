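"""Circularity, extents, front class, colocalization, clusters, gap closure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import draw

from axmorph.morphometrics import (
    ClusterStats,
    LabelImage,
    circularity,
    circularity_from_measures,
    cluster_size_distribution,
    front_curvature_class,
    gap_closure_speed,
    mask_perimeter,
    pearson_colocalization,
    tissue_extents,
)
from axmorph.cpm import CellType


def disk_mask(radius, pad=5):
    n = 2 * radius + 2 * pad
    m = np.zeros((n, n), bool)
    rr, cc = draw.disk((n // 2, n // 2), radius)
    m[rr, cc] = True
    return m


class TestCircularity:
    def test_analytic_disk_is_exactly_one(self):
        r = 10.0
        assert circularity_from_measures(math.pi * r**2, 2 * math.pi * r) == pytest.approx(1.0)

    @pytest.mark.parametrize("radius", [15, 50])
    def test_rasterized_disk_close_to_one(self, radius):
        assert circularity(disk_mask(radius)) == pytest.approx(1.0, abs=0.05)

    def test_rectangle_polygonal_perimeter_and_formula(self):
        """A 2x20 rectangle has pixel-edge boundary polygon length 44, hence
        circularity 4*pi*40/44^2 ~ 0.260."""
        m = np.zeros((10, 30), bool)
        m[4:6, 5:25] = True
        assert mask_perimeter(m, method="pixel_edge") == pytest.approx(44.0)
        c = circularity(m, method="pixel_edge")
        assert c == pytest.approx(4 * math.pi * 40 / 44**2, rel=1e-12)
        assert c == pytest.approx(0.260, abs=0.001)

    def test_invariant_under_translation_and_rotation(self):
        m = np.zeros((40, 40), bool)
        m[10:14, 8:28] = True
        c0 = circularity(m)
        shifted = np.roll(m, (7, 5), axis=(0, 1))
        assert circularity(shifted) == pytest.approx(c0, rel=1e-12)
        assert circularity(np.rot90(m)) == pytest.approx(c0, rel=1e-12)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            circularity(np.zeros((5, 5), bool))

    def test_decreasing_along_eccentric_ellipse_family(self):
        """Fixed-area ellipses of growing eccentricity have decreasing
        circularity; none exceeds 1 + discretization tolerance."""
        area = 60 * 60 * math.pi
        values = []
        for ratio in (1.0, 1.5, 2.5, 4.0, 6.0):
            a = math.sqrt(area / math.pi * ratio)
            b = area / math.pi / a
            m = np.zeros((400, 400), bool)
            rr, cc = draw.ellipse(200, 200, a, b)
            m[rr, cc] = True
            values.append(circularity(m))
        assert all(v <= 1.05 for v in values)
        assert all(x > y for x, y in zip(values, values[1:]))


class TestTissueExtents:
    def test_block_extents_and_aspect(self):
        img = LabelImage(np.zeros((100, 100), np.int32), pixel_size=2.0)
        img.labels[20:80, 10:30] = 3  # 60 AP x 20 ML sites
        ap, ml, ar = tissue_extents(img, 3)
        assert (ap, ml, ar) == (120.0, 40.0, 3.0)

    def test_single_site(self):
        img = LabelImage(np.zeros((10, 10), np.int32), pixel_size=2.0)
        img.labels[4, 7] = 1
        assert tissue_extents(img, 1) == (2.0, 2.0, 1.0)

    def test_rotation_swaps_axes(self):
        labs = np.zeros((50, 50), np.int32)
        labs[5:25, 10:14] = 2
        ap, ml, _ = tissue_extents(LabelImage(labs), 2)
        ap2, ml2, _ = tissue_extents(LabelImage(np.rot90(labs)), 2)
        assert (ap2, ml2) == (ml, ap)

    def test_absent_target_raises(self):
        with pytest.raises(ValueError):
            tissue_extents(LabelImage(np.zeros((5, 5), np.int32)), 9)


class TestFrontCurvature:
    def _img(self, front_rows):
        labs = np.zeros((60, len(front_rows)), np.int32)
        for c, r in enumerate(front_rows):
            labs[int(r) : int(r) + 3, c] = int(CellType.LEADING_EDGE)
        return LabelImage(labs)

    def test_straight_front_is_flat(self):
        img = self._img([30] * 40)
        assert front_curvature_class(img) == "flat"

    def test_circular_anterior_bulge_is_convex(self):
        cols = np.arange(40, dtype=float)
        bulge = 30 - np.sqrt(np.clip(25**2 - (cols - 20) ** 2, 0, None)) / 3
        assert front_curvature_class(self._img(bulge)) == "convex"

    def test_central_notch_is_concave(self):
        cols = np.arange(40, dtype=float)
        notch = 30 + 8 * np.exp(-((cols - 20) ** 2) / 80.0)
        assert front_curvature_class(self._img(notch)) == "concave"

    def test_narrow_front_raises(self):
        img = self._img([30] * 4)
        with pytest.raises(ValueError, match="5 ML"):
            front_curvature_class(img)


class TestPearson:
    def test_identity_and_inversion(self, rng):
        a = rng.normal(size=(20, 20, 20))
        assert pearson_colocalization(a, a) == pytest.approx(1.0)
        assert pearson_colocalization(a, -a + 3.0) == pytest.approx(-1.0)

    def test_target_correlation_recovered(self):
        from axmorph.synthetic import synth_coloc_pair

        a, b, _ = synth_coloc_pair(0.8, n=100_000, seed=1)
        assert pearson_colocalization(a, b) == pytest.approx(0.8, abs=0.01)

    def test_constant_channel_raises(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_colocalization(np.ones(100), np.arange(100.0))

    def test_mask_restricts_voxels(self, rng):
        a = rng.normal(size=1000)
        b = a.copy()
        b[500:] = rng.normal(size=500)  # decorrelate the unmasked half
        mask = np.zeros(1000, bool)
        mask[:500] = True
        assert pearson_colocalization(a, b, mask) == pytest.approx(1.0)

    def test_zero_correlation_estimator_unbiased(self):
        """Mean Pearson estimate over 100 independent rho=0 pairs is ~0."""
        from axmorph.synthetic import synth_coloc_pair

        vals = []
        for seed in range(100):
            a, b, _ = synth_coloc_pair(0.0, n=2000, seed=seed)
            vals.append(pearson_colocalization(a, b))
        assert abs(np.mean(vals)) < 0.02


class TestClusters:
    def test_blank_image_gives_zero_clusters(self):
        stats = cluster_size_distribution(np.zeros((50, 50)), threshold=0.5)
        assert stats.count == 0 and math.isnan(stats.mean)

    def test_three_disjoint_disks(self):
        img = np.zeros((120, 120))
        areas = []
        for centre, r in [((20, 20), 6), ((60, 80), 9), ((100, 30), 4)]:
            rr, cc = draw.disk(centre, r)
            img[rr, cc] = 1.0
            areas.append(len(rr))
        stats = cluster_size_distribution(img, threshold=0.5)
        assert stats.count == 3
        assert sorted(stats.sizes.tolist()) == sorted(float(a) for a in areas)

    def test_corner_touching_disks_merge_under_full_connectivity(self):
        img = np.zeros((30, 30))
        img[10:15, 10:15] = 1.0
        img[15:20, 15:20] = 1.0  # diagonal touch only
        assert cluster_size_distribution(img, 0.5, connectivity=2).count == 1
        assert cluster_size_distribution(img, 0.5, connectivity=1).count == 2

    def test_sizes_sum_equals_thresholded_pixels_when_unfiltered(self, rng):
        img = rng.random((64, 64))
        stats = cluster_size_distribution(img, threshold=0.7, min_size=0.0)
        assert stats.sizes.sum() == pytest.approx((img > 0.7).sum())

    def test_min_size_filter(self):
        img = np.zeros((40, 40))
        img[5:7, 5:7] = 1.0  # 4 px
        img[20:30, 20:30] = 1.0  # 100 px
        stats = cluster_size_distribution(img, 0.5, min_size=10.0)
        assert stats.count == 1 and stats.sizes[0] == 100.0


class TestGapClosure:
    def _series(self, widths, n_cols=100, n_rows=80):
        frames = []
        for w in widths:
            f = np.zeros((n_rows, n_cols), bool)
            top = (n_rows - int(round(w))) // 2
            f[:top] = True
            f[top + int(round(w)) :] = True
            frames.append(f)
        return np.array(frames)

    def test_constant_gap_has_zero_speed(self):
        masks = self._series([30, 30, 30, 30])
        gaps, speed = gap_closure_speed(masks, np.arange(4.0))
        assert speed == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(gaps, 30.0)

    def test_linear_closure_speed_recovered(self):
        """Gap shrinking 10 um/h (1 um/px) gives closure speed ~10 um/h."""
        times = np.arange(6.0)  # hours
        masks = self._series([60 - 10 * t for t in times])
        gaps, speed = gap_closure_speed(masks, times)
        assert speed == pytest.approx(10.0, abs=0.2)

    def test_closed_gap_records_zero_width(self):
        masks = self._series([20, 10, 0])
        gaps, _ = gap_closure_speed(masks, np.arange(3.0))
        assert gaps[-1] == 0.0

    def test_default_uses_ten_positions(self):
        import inspect

        assert inspect.signature(gap_closure_speed).parameters["n_positions"].default == 10


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(5, 30), st.integers(5, 30))
def test_rectangle_circularity_below_square(h, w):
    """Any h x w rectangle's formula circularity never exceeds the square's
    (pi/4) and equals it exactly when h == w."""
    c = circularity_from_measures(h * w, 2.0 * (h + w))
    assert c <= math.pi / 4 + 1e-12
    if h == w:
        assert c == pytest.approx(math.pi / 4)
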