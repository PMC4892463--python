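import numpy as np
import pytest
from scipy.spatial.distance import cdist

import pptrack as pt
from pptrack.detect import (
    DetectionParams,
    HaarFeatureImage,
    adapt_params,
    classify_pixels,
    compute_haar_features,
    compute_ppi,
    detect_frame,
    enhancement_factor,
    extract_pers,
    find_markers,
    localize,
    segment_watershed,
)


class TestHaarFeatures:
    def test_constant_image_gives_zero_contrast(self):
        out = compute_haar_features(np.full((32, 32), 17.0), S=12, s=4)
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_single_pixel_hand_convolution(self):
        # 1-px inner window (s = S = 1): hand-computed kernel responses.
        # At the bright pixel every inner window holds v alone or dominates:
        # square gives v - 0 = v (the maximum).  At the left neighbour the
        # square kernel gives 0 - v/8, the vertical bar -(v/6), but the
        # horizontal 1x3 bar window contains v, giving v/3 - 0 = v/3,
        # which wins the per-pixel maximum.
        v = 40.0
        img = np.zeros((9, 9))
        img[4, 4] = v
        out = compute_haar_features(img, S=1, s=1)
        assert out.values[4, 4] == pytest.approx(v)
        assert out.values[4, 3] == pytest.approx(v / 3)

    def test_dc_offset_invariance(self, rng):
        img = rng.normal(50, 10, (48, 48))
        a = compute_haar_features(img, S=12, s=4).values
        b = compute_haar_features(img + 123.4, S=12, s=4).values
        assert np.allclose(a, b, atol=1e-8)

    def test_oversized_scale_skipped(self):
        out = compute_haar_features(np.zeros((12, 12)), S=12, s=4)
        assert all(w + 2 * ((w - 1) // 2) <= 12 for w in out.scales)


class TestEnhancementFactor:
    @pytest.mark.parametrize(
        "snr,density,expected",
        [(7.0, "low", 1.0), (1.0, "high", 2.625), (1e9, "medium", 1.25)],
    )
    def test_values(self, snr, density, expected):
        assert enhancement_factor(snr, density) == pytest.approx(expected)

    def test_monotone_in_snr_and_density(self):
        snrs = [0.5, 1, 2, 4, 7]
        f = [enhancement_factor(s, "medium") for s in snrs]
        assert all(a >= b for a, b in zip(f, f[1:]))
        assert (enhancement_factor(2, "low") <= enhancement_factor(2, "medium")
                <= enhancement_factor(2, "high"))


class TestClassifyPixels:
    def test_selects_exactly_k_pixels(self, rng):
        haar = HaarFeatureImage(rng.normal(size=(100, 100)), [3])
        params = DetectionParams(S=9, s=1, N=1, density="low", snr=7.0)
        assert classify_pixels(haar, params).sum() == 9

    def test_doubling_f_doubles_k(self, rng):
        haar = HaarFeatureImage(rng.normal(size=(100, 100)), [3])
        p1 = DetectionParams(S=9, s=1, N=10, density="low", snr=7.0, F=1.0)
        p2 = DetectionParams(S=9, s=1, N=10, density="low", snr=7.0, F=2.0)
        assert classify_pixels(haar, p2).sum() == 2 * classify_pixels(haar, p1).sum()

    def test_ties_broken_in_raster_order(self):
        haar = HaarFeatureImage(np.zeros((10, 10)), [3])
        params = DetectionParams(S=5, s=1, N=1, density="low", snr=7.0)
        mask = classify_pixels(haar, params)
        assert mask.ravel()[:5].all() and not mask.ravel()[5:].any()

    def test_k_covering_image_raises(self):
        haar = HaarFeatureImage(np.zeros((10, 10)), [3])
        params = DetectionParams(S=100, s=1, N=10, density="low", snr=7.0)
        with pytest.raises(ValueError, match="parameters inconsistent"):
            classify_pixels(haar, params)


class TestComputePpi:
    def test_all_particle_map_is_one(self):
        assert np.allclose(compute_ppi(np.ones((20, 20), bool), S=9), 1.0)

    def test_all_background_map_is_zero(self):
        assert np.allclose(compute_ppi(np.zeros((20, 20), bool), S=9), 0.0)

    def test_ratio_definition(self):
        binary = np.zeros((9, 9), bool)
        binary[4, 4] = binary[4, 5] = binary[3, 4] = True
        ppi = compute_ppi(binary, S=9)  # 3x3 window
        assert ppi[4, 4] == pytest.approx(3 / 9)

    def test_values_in_unit_interval(self, rng):
        binary = rng.random((40, 40)) > 0.6
        ppi = compute_ppi(binary, S=12)
        assert ppi.min() >= 0.0 and ppi.max() <= 1.0


class TestExtractPers:
    def test_uniform_above_threshold_single_region(self):
        pers = extract_pers(np.full((16, 16), 0.5), s=1)
        assert pers.n_regions == 1
        assert np.all(pers.labels == 1)

    def test_uniform_below_threshold_empty(self):
        pers = extract_pers(np.full((16, 16), 0.3), s=1)
        assert pers.n_regions == 0

    def test_soft_threshold_splits_weakly_joined_blobs(self):
        # two PPI blobs (peaks 1.0 and 0.5) joined by a 0.42 bridge: the
        # bridge survives the base 1/e threshold, but the region-local
        # re-threshold at 0.5 * regional max = 0.5 cuts it in two
        ppi = np.zeros((12, 30))
        ppi[4:9, 4:9] = 1.0
        ppi[6, 9:16] = 0.42  # bridge, above 1/e ~ 0.368
        ppi[4:9, 16:21] = 0.5
        pers = extract_pers(ppi, s=1)
        assert pers.n_regions == 2

    def test_small_regions_discarded(self):
        ppi = np.zeros((16, 16))
        ppi[2, 2] = 0.9  # single-pixel region
        ppi[8:11, 8:11] = 0.9
        pers = extract_pers(ppi, s=4)
        assert pers.n_regions == 1


class TestFindMarkers:
    def _gaussian_frame(self, cx=15.0, cy=11.0, shape=(24, 32)):
        yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
        return 100 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 2.0**2))

    def test_single_spot_marker_at_peak(self):
        frame = self._gaussian_frame()
        ppi = np.clip(frame / frame.max(), 0, 1)
        pers = extract_pers(ppi, s=4)
        markers = find_markers(frame, pers, ppi, s=4)
        assert len(markers) == 1
        assert abs(markers.cols[0] - 15) <= 1 and abs(markers.rows[0] - 11) <= 1

    def test_constant_per_collapses_to_centroid(self):
        frame = np.zeros((20, 20))
        frame[5:10, 5:10] = 50.0  # flat plateau
        ppi = np.zeros((20, 20))
        ppi[5:10, 5:10] = 0.8
        pers = extract_pers(ppi, s=4)
        markers = find_markers(frame, pers, ppi, s=4)
        assert len(markers) == 1
        assert markers.rows[0] == 7 and markers.cols[0] == 7

    def test_maxima_outside_pers_are_not_markers(self):
        frame = self._gaussian_frame() + self._gaussian_frame(cx=28.0, cy=5.0)
        ppi = np.zeros_like(frame)
        yy, xx = np.mgrid[0:24, 0:32]
        ppi[((xx - 15) ** 2 + (yy - 11) ** 2) < 25] = 0.9  # PER on first spot only
        pers = extract_pers(ppi, s=4)
        markers = find_markers(frame, pers, ppi, s=4)
        assert np.all(pers.labels[markers.rows, markers.cols] > 0)
        assert len(markers) == 1


class TestSegmentWatershed:
    def test_single_marker_segment_fills_per(self):
        yy, xx = np.mgrid[0:24, 0:24]
        frame = 100 * np.exp(-((xx - 12) ** 2 + (yy - 12) ** 2) / (2 * 3.0**2))
        ppi = np.clip(frame / frame.max(), 0, 1)
        pers = extract_pers(ppi, s=4)
        markers = find_markers(frame, pers, ppi, s=4)
        segs = segment_watershed(frame, markers, pers, s=4)
        assert np.array_equal(segs > 0, pers.labels > 0)

    def test_two_markers_partition_dumbbell_per(self):
        yy, xx = np.mgrid[0:24, 0:44]
        f1 = 100 * np.exp(-((xx - 20) ** 2 + (yy - 12) ** 2) / (2 * 1.5**2))
        f2 = 100 * np.exp(-((xx - 24) ** 2 + (yy - 12) ** 2) / (2 * 1.5**2))
        frame = f1 + f2
        ppi = np.clip(frame / 100, 0, 1)
        pers = extract_pers(ppi, s=4)
        assert pers.n_regions == 1  # blobs joined into one dumbbell PER
        markers = find_markers(frame, pers, ppi, s=4)
        assert len(markers) == 2
        segs = segment_watershed(frame, markers, pers, s=4)
        assert np.array_equal(segs > 0, pers.labels > 0)  # union equals the PER
        assert len(np.unique(segs[segs > 0])) == 2
        # the watershed line separates the two peaks
        assert segs[12, 20] != segs[12, 24]

    def test_no_pixel_outside_pers_labelled(self, rng):
        frame = rng.normal(50, 10, (32, 32))
        ppi = np.zeros((32, 32))
        ppi[10:20, 10:20] = 0.9
        pers = extract_pers(ppi, s=4)
        markers = find_markers(frame, pers, ppi, s=4)
        segs = segment_watershed(frame, markers, pers, s=4)
        assert np.all(segs[pers.labels == 0] == 0)


class TestLocalize:
    def test_two_pixel_weighted_mean(self):
        frame = np.zeros((5, 5))
        frame[2, 1], frame[2, 2] = 10.0, 30.0
        segs = np.zeros((5, 5), dtype=np.int32)
        segs[2, 1] = segs[2, 2] = 1
        det = localize(frame, segs, S=12)[0]
        assert det.x == pytest.approx(1.75)
        assert det.y == pytest.approx(2.0)

    def test_symmetric_spot_subpixel_accuracy(self):
        cx, cy = 12.37, 11.62
        yy, xx = np.mgrid[0:24, 0:24]
        frame = 5.0 + 120 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 1.5**2))
        dd = (xx - cx) ** 2 + (yy - cy) ** 2
        segs = (dd < 4.5**2).astype(np.int32)
        det = localize(frame, segs, S=12)[0]
        assert np.hypot(det.x - cx, det.y - cy) <= 0.05

    def test_disc_circularity_near_one(self):
        yy, xx = np.mgrid[0:32, 0:32]
        segs = (((xx - 16) ** 2 + (yy - 16) ** 2) < 8**2).astype(np.int32)
        det = localize(np.ones((32, 32)), segs, S=200)[0]
        assert det.circularity == pytest.approx(1.0, abs=0.15)

    def test_small_particle_gaussian_fit_branch(self):
        cx, cy = 10.3, 9.7
        yy, xx = np.mgrid[0:20, 0:20]
        frame = 3.0 + 90 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 1.0**2))
        dd = (xx - cx) ** 2 + (yy - cy) ** 2
        segs = (dd < 2.0**2).astype(np.int32)
        det = localize(frame, segs, S=7)[0]  # S < 9 -> fit branch
        assert np.hypot(det.x - cx, det.y - cy) <= 0.05
        assert not det.fit_fallback


class TestDetectFrame:
    def test_counts_well_separated_clean_spots(self, clean_scene, clean_params):
        stack, truth = clean_scene
        dets = detect_frame(stack.data[0], clean_params)
        assert len(dets) == 20
        gt = truth.positions_in_frame(0)[:, :2]
        est = np.array([[d.x, d.y] for d in dets])
        assert cdist(est, gt).min(axis=1).max() < 0.5

    def test_pure_noise_frame_yields_few_detections(self):
        spec = pt.NoiseSpec()
        stack = pt.add_noise(
            pt.FrameStack(np.full((3, 128, 128), 20.0)), spec, seed=123
        )
        params = DetectionParams(S=12, s=4, N=5, density="low", snr=7.0)
        for t in range(3):
            dets = detect_frame(stack.data[t], params, t)
            assert len(dets) <= 5


class TestAdaptParams:
    def test_within_tolerance_returns_immediately(self, clean_scene, clean_params):
        stack, _ = clean_scene
        p, dets = adapt_params(clean_params, stack.data[0])
        assert p.snr == clean_params.snr and p.density == clean_params.density
        assert len(dets) == 20

    @pytest.mark.parametrize("n0", [10, 30])
    def test_misspecified_n_converges_to_true_count(self, clean_scene, n0):
        stack, _ = clean_scene
        params = DetectionParams(S=12, s=4, N=n0, density="low", snr=7.0)
        _, dets = adapt_params(params, stack.data[0])
        assert abs(len(dets) - 20) <= 0.2 * 20

    def test_lower_snr_estimate_never_decreases_count(self, clean_scene):
        stack, _ = clean_scene
        counts = []
        for snr in (7.0, 4.0, 2.0, 1.0):
            params = DetectionParams(S=12, s=4, N=20, density="low", snr=snr)
            counts.append(len(detect_frame(stack.data[0], params)))
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestPipelineInvariants:
    def test_ppi_bounds_and_marker_segment_soundness(self, rng):
        # random frames: PPI in [0, 1], markers inside PERs, segments inside PERs
        from pptrack.detect import compute_haar_features as chf

        for _ in range(10):
            frame = rng.normal(40, 15, (64, 64)).clip(0, 255)
            params = DetectionParams(S=12, s=4, N=10, density="medium", snr=2.0)
            haar = chf(frame, params.S, params.s)
            binary = classify_pixels(haar, params)
            ppi = compute_ppi(binary, params.S)
            assert ppi.min() >= 0 and ppi.max() <= 1
            pers = extract_pers(ppi, params.s)
            markers = find_markers(frame, pers, ppi, params.s)
            assert np.all(pers.labels[markers.rows, markers.cols] > 0)
            segs = segment_watershed(frame, markers, pers, params.s)
            assert np.all(pers.labels[segs > 0] > 0)
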