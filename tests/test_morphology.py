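"""Segmentation, region measurement and size-distribution behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as disk_coords

import pelletmetrics as pm
from pelletmetrics.image import PelletImage
from pelletmetrics.morphology import fill_holes, measurements_frame

REL = 1e-9


def disk_mask(shape, center, radius):
    m = np.zeros(shape, bool)
    rr, cc = disk_coords(center, radius, shape=shape)
    m[rr, cc] = True
    return m


class TestBinarizeLocalMean:
    def test_constant_image_gives_empty_mask(self):
        img = PelletImage(np.full((128, 128), 120.0), 4.5)
        assert not pm.binarize_local_mean(img).any()

    def test_dark_disk_matches_global_threshold_oracle(self):
        # noise-free dark disk: oracle = threshold at midpoint intensity
        px = np.full((128, 128), 200.0)
        px[disk_mask(px.shape, (64, 64), 20)] = 60.0
        mask = pm.binarize_local_mean(PelletImage(px, 4.5))
        oracle = px < 130.0
        inter = (mask & oracle).sum()
        union = (mask | oracle).sum()
        assert inter / union >= 0.95

    def test_bright_polarity_on_inverted_image_matches_dark(self):
        rng = np.random.default_rng(0)
        px = np.full((96, 96), 200.0) + rng.normal(0, 3, (96, 96))
        px[disk_mask(px.shape, (40, 50), 15)] = 70.0
        dark = pm.binarize_local_mean(PelletImage(px, 4.5), polarity="dark")
        inverted = (px.min() + px.max()) - px
        bright = pm.binarize_local_mean(PelletImage(inverted, 4.5),
                                        polarity="bright")
        assert np.array_equal(dark, bright)

    def test_window_larger_than_image_raises(self):
        with pytest.raises(ValueError, match="window"):
            pm.binarize_local_mean(PelletImage(np.zeros((32, 32)), 4.5),
                                   window_px=65)


class TestWatershed:
    def test_disjoint_disks_keep_their_components(self):
        m = disk_mask((128, 128), (30, 30), 15) | disk_mask((128, 128), (90, 90), 18)
        labels = pm.segment_watershed(m)
        assert labels.max() == 2
        assert (labels > 0).sum() == m.sum()

    def test_single_disk_single_label(self):
        labels = pm.segment_watershed(disk_mask((80, 80), (40, 40), 22))
        assert labels.max() == 1

    def test_empty_mask_gives_zero_objects(self):
        assert pm.segment_watershed(np.zeros((16, 16), bool)).max() == 0

    def test_fused_equal_disks_split_near_neck_bisector(self):
        # centers 1.5 r apart: the analytic split line is the perpendicular
        # bisector at the neck, x = midpoint column
        r = 20
        m = disk_mask((100, 140), (50, 50), r) | disk_mask((100, 140), (50, 80), r)
        labels = pm.segment_watershed(m)
        assert labels.max() == 2
        mid = 65.0
        left = labels == labels[50, 50]
        right = labels == labels[50, 80]
        assert left.sum() + right.sum() == m.sum()
        cols_left = np.nonzero(left)[1]
        cols_right = np.nonzero(right)[1]
        assert cols_left.max() <= mid + 2
        assert cols_right.min() >= mid - 2

    def test_label_conservation(self):
        rng = np.random.default_rng(3)
        m = np.zeros((150, 150), bool)
        for _ in range(6):
            m |= disk_mask(m.shape, tuple(rng.integers(20, 130, 2)),
                           rng.integers(8, 20))
        labels = pm.segment_watershed(m)
        assert (labels > 0).sum() == m.sum()


class TestMeasureRegions:
    def test_single_pixel_arithmetic(self):
        labels = np.zeros((9, 9), np.int32)
        labels[4, 4] = 1
        (m,) = pm.measure_regions(labels, 4.5)
        assert m.area_um2 == pytest.approx(20.25, rel=REL)
        assert m.equivalent_diameter_um == pytest.approx(
            math.sqrt(4 * 20.25 / math.pi), rel=REL)

    def test_rasterized_disk_equivalent_diameter(self):
        labels = disk_mask((100, 100), (50, 50), 20).astype(np.int32)
        (m,) = pm.measure_regions(labels, 4.5)
        assert m.equivalent_diameter_um == pytest.approx(180.0, rel=0.02)
        assert m.circularity >= 0.9

    def test_square_feret_geometry(self):
        a = 12
        labels = np.zeros((40, 40), np.int32)
        labels[10:10 + a, 15:15 + a] = 1
        (m,) = pm.measure_regions(labels, 1.0)
        assert m.feret_min_um == pytest.approx(a, rel=REL)
        assert m.feret_max_um == pytest.approx(a * math.sqrt(2), rel=REL)
        assert m.feret_ratio == pytest.approx(1 / math.sqrt(2), rel=REL)

    def test_touches_edge_flag(self):
        labels = np.zeros((30, 30), np.int32)
        labels[0:5, 10:15] = 1
        labels[20:24, 10:14] = 2
        m = pm.measure_regions(labels, 4.5)
        assert m[0].touches_edge and not m[1].touches_edge

    def test_scale_equivariance(self):
        labels = disk_mask((80, 80), (40, 40), 17).astype(np.int32)
        (m1,) = pm.measure_regions(labels, 4.5)
        (m2,) = pm.measure_regions(labels, 9.0)
        assert m2.equivalent_diameter_um == pytest.approx(
            2 * m1.equivalent_diameter_um, rel=REL)
        assert m2.feret_max_um == pytest.approx(2 * m1.feret_max_um, rel=REL)
        assert m2.area_um2 == pytest.approx(4 * m1.area_um2, rel=REL)
        assert m2.circularity == pytest.approx(m1.circularity, rel=REL)
        assert m2.feret_ratio == pytest.approx(m1.feret_ratio, rel=REL)


class TestCircularity:
    def test_analytic_circle_is_one(self):
        r = 7.3
        assert pm.circularity(math.pi * r * r, 2 * math.pi * r) == \
            pytest.approx(1.0, rel=REL)

    def test_square_is_pi_over_4(self):
        assert pm.circularity(25.0, 20.0) == pytest.approx(math.pi / 4, rel=REL)

    def test_two_to_one_ellipse_by_quadrature(self):
        a, b = 2.0, 1.0
        theta = np.linspace(0, 2 * np.pi, 200001)
        arc = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
        perimeter = np.trapezoid(arc, theta)
        c = pm.circularity(math.pi * a * b, perimeter)
        assert c == pytest.approx(0.8412, abs=5e-4)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            pm.circularity(0.0, 10.0)
        with pytest.raises(ValueError):
            pm.circularity(10.0, -1.0)


class TestFilterRegions:
    def _labels_and_measurements(self):
        labels = np.zeros((60, 60), np.int32)
        labels[5:8, 5:8] = 1          # 9 px = 182.25 um2 -> removed
        labels[20:22, 20:25] = 2      # 10 px = 202.5 um2 -> kept
        labels[0, 30:50] = 3          # touches edge -> removed
        labels[40:50, 40:50] = 4      # large interior -> kept
        return pm.measure_regions(labels, 4.5), labels

    def test_small_and_edge_objects_removed(self):
        meas, labels = self._labels_and_measurements()
        kept, new_labels = pm.filter_regions(meas, labels)
        assert [m.area_um2 for m in kept] == [202.5, 100 * 20.25]
        assert [m.label for m in kept] == [1, 2]
        assert set(np.unique(new_labels)) == {0, 1, 2}

    def test_idempotent(self):
        meas, labels = self._labels_and_measurements()
        once_m, once_l = pm.filter_regions(meas, labels)
        twice_m, twice_l = pm.filter_regions(once_m, once_l)
        assert [m.__dict__ for m in twice_m] == [m.__dict__ for m in once_m]
        assert np.array_equal(once_l, twice_l)


class TestSizeDistributions:
    def test_single_value_occupies_one_bin(self):
        d = pm.size_distributions([150.0] * 7, bin_width_um=20.0)
        occupied = d.q0 > 0
        assert occupied.sum() == 1
        assert (d.q0 * np.diff(d.bin_edges_um))[occupied][0] == pytest.approx(1.0, rel=REL)

    def test_q3_volume_weighting_ratio(self):
        d = pm.size_distributions([100.0] * 5 + [200.0] * 5, bin_width_um=20.0)
        mass = d.q3 * np.diff(d.bin_edges_um)
        occupied = mass[mass > 0]
        assert len(occupied) == 2
        assert occupied[1] / occupied[0] == pytest.approx(8.0, rel=1e-12)

    def test_matches_independent_histogram_oracle(self):
        rng = np.random.default_rng(42)
        d = np.exp(rng.normal(math.log(150), 0.3, 10_000))
        dist = pm.size_distributions(d, bin_width_um=20.0)
        # second implementation: manual bin counting
        idx = np.minimum((d // 20.0).astype(int), len(dist.q0) - 1)
        counts = np.bincount(idx, minlength=len(dist.q0))
        widths = np.diff(dist.bin_edges_um)
        np.testing.assert_allclose(dist.q0, counts / (counts.sum() * widths),
                                   rtol=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            pm.size_distributions([])


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(1.0, 800.0), min_size=1, max_size=60),
       st.floats(5.0, 50.0))
def test_distribution_normalization_property(diameters, bin_width):
    dist = pm.size_distributions(diameters, bin_width)
    widths = np.diff(dist.bin_edges_um)
    assert np.sum(dist.q0 * widths) == pytest.approx(1.0, abs=1e-9)
    assert np.sum(dist.q3 * widths) == pytest.approx(1.0, abs=1e-9)
    assert (dist.q0 >= 0).all() and (dist.q3 >= 0).all()


class TestPipelineRecovery:
    def test_noise_free_recovery_on_synthetic_image(self):
        params = pm.ImageGenParams(n_pellets=20, noise_sd=0.0, seed=21)
        image, truth = pm.generate_pellet_image(params)
        meas, _ = pm.analyze_image(image)
        frame = measurements_frame(meas)
        centroids = frame[["centroid_px"]].to_numpy()
        matched = 0
        for _, t in truth.iterrows():
            dists = [math.hypot(c[0] - t.center_row_px, c[1] - t.center_col_px)
                     for (c,) in centroids]
            j = int(np.argmin(dists))
            tol = max(2 * 4.5, 0.03 * t.true_equivalent_diameter_um)
            if dists[j] < t.true_equivalent_diameter_um / 9:
                assert abs(frame.equivalent_diameter_um[j]
                           - t.true_equivalent_diameter_um) <= tol
                matched += 1
        assert matched == len(truth)

    def test_rendered_circles_are_round(self):
        params = pm.ImageGenParams(n_pellets=10, eccentricity_max=0.0,
                                   noise_sd=0.0, seed=5)
        image, _ = pm.generate_pellet_image(params)
        meas, _ = pm.analyze_image(image)
        assert meas and all(m.circularity >= 0.9 for m in meas)

    def test_hole_filling_superset(self):
        m = disk_mask((60, 60), (30, 30), 20)
        holey = m & ~disk_mask((60, 60), (30, 30), 8)
        assert np.array_equal(fill_holes(holey), m)
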