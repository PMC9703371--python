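import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelspot.registration import CropRect
from gelspot.segmentation import (
    LabelMap,
    SegmentationParams,
    filter_regions,
    orient_spots_bright,
    segment_mean_image,
    suppress_shallow_maxima,
    tophat_filter,
    watershed_segment,
)
from gelspot.synthetic import PlantedSpot, SyntheticGroundTruth, render_gel
from gelspot.registration import SimilarityTransform

from conftest import gel
from oracles import (
    regional_maxima_count,
    reconstruct_dilation_oracle,
    tophat_oracle,
)


def gaussian_peak(shape, cx, cy, sigma, amp):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


class TestOrientation:
    def test_dark_spots_complements(self):
        out = orient_spots_bright(gel(np.full((3, 3), 0.2)), "dark_spots")
        np.testing.assert_allclose(out.pixels, 0.8)

    def test_bright_spots_identity(self, rng):
        img = gel(rng.random((4, 4)))
        out = orient_spots_bright(img, "bright_spots")
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_complement_is_involution(self, rng):
        img = gel(rng.random((4, 4)))
        twice = orient_spots_bright(orient_spots_bright(img, "dark_spots"), "dark_spots")
        np.testing.assert_allclose(twice.pixels, img.pixels, atol=1e-15)


class TestTophat:
    def test_constant_image_maps_to_zero(self):
        out = tophat_filter(gel(np.full((10, 10), 0.7)), 4)
        np.testing.assert_allclose(out.pixels, 0.0, atol=1e-15)

    def test_impulse_survives_whole(self):
        img = np.zeros((11, 11))
        img[5, 5] = 1.0
        out = tophat_filter(gel(img), 3)
        np.testing.assert_allclose(out.pixels, img, atol=1e-15)

    def test_peak_on_ramp_matches_neighborhood_oracle(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        ramp = 0.1 + 0.4 * xx / 63.0
        img = np.clip(ramp + gaussian_peak((64, 64), 32, 30, 2.0, 0.5), 0, 1)
        out = tophat_filter(gel(img), 8)
        expected = tophat_oracle(img, 8)
        np.testing.assert_allclose(out.pixels, expected, atol=1e-12)
        # far from the peak only the (removed) ramp remains; the opening
        # under-reaches within one disk radius of the border, so check there
        interior = (xx >= 8) & (xx < 56) & (yy >= 8) & (yy < 56)
        dist = np.hypot(xx - 32, yy - 30)
        assert out.pixels[(dist >= 20) & interior].max() < 0.01

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 5))
    def test_anti_extensive_and_offset_invariant(self, seed, radius):
        arr = np.random.default_rng(seed).random((16, 16)) * 0.5
        base = tophat_filter(gel(arr), radius).pixels
        assert base.min() >= 0
        assert np.all(base <= arr + 1e-12)
        shifted = tophat_filter(gel(arr + 0.3), radius).pixels
        np.testing.assert_allclose(shifted, base, atol=1e-12)


class TestHMaximaSuppression:
    def test_h_zero_is_identity(self, rng):
        img = gel(rng.random((8, 8)))
        out = suppress_shallow_maxima(img, 0.0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_shallow_peak_suppressed(self):
        img = np.zeros((30, 30))
        img += gaussian_peak((30, 30), 8, 15, 2.0, 0.5)
        img += gaussian_peak((30, 30), 22, 15, 2.0, 0.15)
        out = suppress_shallow_maxima(gel(np.clip(img, 0, 1)), 0.3)
        assert regional_maxima_count(out.pixels) == 1

    def test_matches_fixpoint_reconstruction_oracle(self, rng):
        img = np.round(rng.random((16, 16)) * 255) / 255
        h = 0.1
        out = suppress_shallow_maxima(gel(img), h, connectivity=8)
        expected = reconstruct_dilation_oracle(img - h, img, connectivity=8)
        np.testing.assert_allclose(out.pixels, np.clip(expected, 0, 1), atol=1e-12)
        assert regional_maxima_count(out.pixels) == regional_maxima_count(expected)


def params(**kw):
    defaults = dict(disk_radius=10, h_suppress=0.02, min_area=4)
    defaults.update(kw)
    return SegmentationParams(**defaults)


class TestWatershed:
    def test_single_spot_yields_one_region_containing_center(self):
        img = gaussian_peak((60, 60), 30, 28, 4.0, 0.5)
        labels = watershed_segment(gel(np.clip(img, 0, 1)), params())
        assert labels.n_spots == 1
        assert labels.labels[28, 30] == 1

    def test_tiny_background_roi_finds_nothing(self):
        img = gaussian_peak((60, 60), 30, 30, 4.0, 0.5)
        p = params(roi=CropRect(2, 2, 1, 1), foreground_threshold=0.1)
        labels = watershed_segment(gel(np.clip(img, 0, 1)), p)
        assert labels.n_spots == 0
        assert not labels.labels.any()

    def test_equal_twin_spots_split_at_bisector(self):
        c1, c2 = np.array([30.0, 40.0]), np.array([70.0, 40.0])  # 40 px apart
        img = gaussian_peak((80, 100), *c1, 4.0, 0.5) + gaussian_peak(
            (80, 100), *c2, 4.0, 0.5
        )
        labels = watershed_segment(gel(np.clip(img, 0, 1)), params())
        assert labels.n_spots == 2
        l1 = labels.labels[int(c1[1]), int(c1[0])]
        l2 = labels.labels[int(c2[1]), int(c2[0])]
        assert {l1, l2} == {1, 2}
        yy, xx = np.nonzero(labels.labels)
        axis = (c2 - c1) / np.linalg.norm(c2 - c1)
        mid = (c1 + c2) / 2
        proj = (np.column_stack([xx, yy]) - mid) @ axis  # signed dist to bisector
        vals = labels.labels[yy, xx]
        assert proj[vals == l1].max() <= 1.0
        assert proj[vals == l2].min() >= -1.0

    def test_foreground_partition_and_connectivity(self, rng):
        from skimage.measure import label as cc_label

        img = np.zeros((64, 64))
        for _ in range(4):
            img += gaussian_peak(
                (64, 64), rng.uniform(12, 52), rng.uniform(12, 52), 3.0, 0.4
            )
        img = np.clip(img + rng.normal(0, 0.01, img.shape), 0, 1)
        p = params(connectivity=8)
        labels = watershed_segment(gel(img), p)
        fg = labels.labels > 0
        for k in range(1, labels.n_spots + 1):
            region = labels.labels == k
            assert region.any()
            assert cc_label(region, connectivity=2).max() == 1
        # no foreground pixel outside a label: partition by construction
        assert (labels.labels[fg] >= 1).all()

    def test_increasing_h_never_adds_regions(self):
        rng = np.random.default_rng(3)
        img = np.zeros((64, 64))
        for _ in range(5):
            img += gaussian_peak(
                (64, 64), rng.uniform(10, 54), rng.uniform(10, 54), 3.0, 0.35
            )
        img = np.clip(img + rng.normal(0, 0.02, img.shape), 0, 1)
        counts = [
            watershed_segment(gel(img), params(h_suppress=h)).n_spots
            for h in (0.0, 0.02, 0.05, 0.1, 0.2)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFilterRegions:
    def test_no_op_filter_preserves_labeling(self):
        arr = np.array([[0, 1, 1], [2, 2, 0], [0, 3, 0]])
        out = filter_regions(LabelMap(arr, 3), min_area=1)
        np.testing.assert_array_equal(out.labels, arr)
        assert out.n_spots == 3

    def test_small_region_dropped_and_relabeled(self):
        arr = np.zeros((10, 10), dtype=int)
        arr[0, 0] = 1  # area 1
        arr[5:9, 5:9] = 2  # area 16
        out = filter_regions(LabelMap(arr, 2), min_area=10)
        assert out.n_spots == 1
        assert set(np.unique(out.labels)) == {0, 1}
        assert (out.labels[5:9, 5:9] == 1).all()

    def test_survivor_count_matches_histogram_oracle(self, rng):
        from skimage.measure import label as cc_label

        mask = rng.random((40, 40)) > 0.6
        arr = cc_label(mask, connectivity=1)
        k = arr.max()
        min_area = 5
        out = filter_regions(LabelMap(arr, k), min_area=min_area)
        # oracle: count areas by python loop
        areas = {}
        for y in range(40):
            for x in range(40):
                if arr[y, x]:
                    areas[arr[y, x]] = areas.get(arr[y, x], 0) + 1
        expected = sum(1 for a in areas.values() if a >= min_area)
        assert out.n_spots == expected


class TestPlantedRecovery:
    def test_well_separated_spots_recovered_with_centroids(self):
        rng = np.random.default_rng(11)
        sigma = 4.0
        centers = [(40, 40), (130, 45), (210, 60), (60, 140), (150, 160), (210, 210)]
        spots = [
            PlantedSpot(cx, cy, sigma, sigma, float(rng.uniform(0.3, 0.5)))
            for cx, cy in centers
        ]
        truth = SyntheticGroundTruth(
            spots=spots,
            transforms=[SimilarityTransform.identity()],
            intensity_scales=[1.0],
            background=(0.88, 0.04, 0.03),
            noise_sigma=0.004,
            seed=11,
        )
        mean = render_gel(truth, 0, (256, 256))
        _, labels = segment_mean_image(mean, SegmentationParams(disk_radius=15))
        assert labels.n_spots == len(spots)
        yy, xx = np.nonzero(labels.labels)
        for cx, cy in centers:
            k = labels.labels[cy, cx]
            assert k >= 1
            sel = labels.labels[yy, xx] == k
            centroid = (xx[sel].mean(), yy[sel].mean())
            assert np.hypot(centroid[0] - cx, centroid[1] - cy) < 2.0
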