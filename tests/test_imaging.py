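"""Alignment, ROI detection, ΔF/F₀, metrics, thresholding, aggregation."""

import numpy as np
import pandas as pd
import pytest

from chromamotion import imaging as im
from chromamotion import synthetic as sy
from chromamotion.behavior import TuningCurve


def _blob_movie(jitter=None, n_trials=3, size=128, noise_sd=0.0, seed=0):
    """Small movie with one bright blob; optional per-frame planted shifts."""
    rng = np.random.default_rng(seed)
    blob = sy._gaussian_blob((size, size), (40, 60), 20.0)
    n_frames = 20
    frames = np.tile(50.0 + 100.0 * blob, (n_trials * n_frames, 1, 1))
    if noise_sd:
        frames += rng.normal(0, noise_sd, frames.shape)
    if jitter is not None:
        for i in range(frames.shape[0]):
            frames[i] = np.roll(frames[i], tuple(jitter[i]), axis=(0, 1))
    trials = pd.DataFrame({
        "trial": np.arange(n_trials),
        "uv_level": [0] * n_trials,
        "start": np.arange(n_trials) * n_frames,
        "length": n_frames,
    })
    return im.Movie(frames, 6.83, trials, stim_onset=1.6, expansion_end=1.8, hold_end=2.0)


class TestAlign:
    def test_zero_jitter_gives_zero_shifts(self):
        movie = _blob_movie()
        _, shifts, rejected = im.align(movie, 0)
        assert not rejected
        assert (shifts == 0).all()

    def test_constant_planted_shift_recovered(self):
        n = 60
        jitter = np.tile([3, -2], (n, 1))
        movie = _blob_movie(jitter=jitter)
        aligned, shifts, rejected = im.align(movie, 0)
        assert not rejected
        # The template itself is built from shifted frames; relative
        # shifts are what matter and here they are uniform.
        assert (shifts == shifts[0]).all()
        ref = _blob_movie()
        np.testing.assert_allclose(aligned.frames[0], np.roll(ref.frames[0],
                                   tuple(jitter[0] - shifts[0]), axis=(0, 1)))

    def test_varying_planted_shifts_recovered(self, rng):
        jitter = rng.integers(-4, 5, size=(60, 2))
        movie = _blob_movie(jitter=jitter, noise_sd=1.0)
        _, shifts, rejected = im.align(movie, 0)
        assert not rejected
        np.testing.assert_array_equal(shifts, jitter)

    def test_large_excursion_rejected(self):
        jitter = np.zeros((60, 2), dtype=int)
        jitter[30] = (30, 0)     # beyond the 25 px tolerance
        movie = _blob_movie(jitter=jitter)
        _, shifts, rejected = im.align(movie, 0)
        assert rejected
        assert shifts[30, 0] == 30

    def test_idempotent(self):
        jitter = np.tile([2, 1], (60, 1))
        movie = _blob_movie(jitter=jitter)
        aligned, _, _ = im.align(movie, 0)
        _, shifts2, _ = im.align(aligned, 0)
        assert (shifts2 == 0).all()

    def test_empty_movie_errors(self):
        movie = _blob_movie()
        movie.frames = movie.frames[:0]
        with pytest.raises(ValueError):
            im.align(movie, 0)


class TestDetectRois:
    def test_single_blob(self):
        img = 10.0 + 200.0 * sy._gaussian_blob((128, 128), (50, 70), 20.0)
        rois = im.detect_rois(img, min_separation=30)
        assert len(rois) == 1
        assert rois[0].mask[50, 70]
        assert rois[0].peak == (50, 70)

    def test_k_blobs_recovered_with_centers(self):
        centers = [(30, 30), (30, 100), (100, 64)]
        img = 10.0 + sum(200.0 * sy._gaussian_blob((128, 128), c, 20.0) for c in centers)
        rois = im.detect_rois(img, min_separation=30)
        assert len(rois) == 3
        found = sorted(r.peak for r in rois)
        for (fy, fx), (cy, cx) in zip(found, sorted(centers)):
            assert abs(fy - cy) <= 2 and abs(fx - cx) <= 2

    def test_close_blobs_merge(self):
        centers = [(60, 54), (60, 74)]    # 20 px apart, below min_separation
        img = 10.0 + sum(200.0 * sy._gaussian_blob((128, 128), c, 20.0) for c in centers)
        rois = im.detect_rois(img, min_separation=30)
        assert len(rois) == 1

    def test_masks_disjoint_and_connected(self):
        centers = [(30, 30), (30, 100), (100, 64)]
        img = 10.0 + sum(200.0 * sy._gaussian_blob((128, 128), c, 20.0) for c in centers)
        rois = im.detect_rois(img, min_separation=30)
        total = np.zeros((128, 128), dtype=int)
        for r in rois:
            total += r.mask
            from skimage.measure import label as cc_label
            assert cc_label(r.mask).max() == 1
        assert total.max() == 1

    def test_flat_image_yields_no_rois(self):
        assert im.detect_rois(np.zeros((64, 64))) == []


class TestDffAndMetric:
    def test_constant_fluorescence_gives_zero_trace(self):
        movie = _blob_movie()
        roi = im.Roi(mask=sy._gaussian_blob((128, 128), (40, 60), 20.0) > 0.5, peak=(40, 60))
        traces = im.dff(movie, roi)
        np.testing.assert_allclose(traces, 0.0, atol=1e-12)

    def test_doubling_gives_unity(self):
        movie = _blob_movie(n_trials=1)
        t = movie.trial_times
        movie.frames[t >= 2.0] *= 2.0
        roi = im.Roi(mask=np.ones((128, 128), bool), peak=(0, 0))
        trace = im.dff(movie, roi)[0]
        np.testing.assert_allclose(trace[t >= 2.0], 1.0, atol=1e-12)
        np.testing.assert_allclose(trace[t < 1.6], 0.0, atol=1e-12)

    def test_closed_form_kinetics(self):
        movie = _blob_movie(n_trials=1)
        n = movie.trial_length
        t = movie.trial_times
        f0 = 120.0
        f = f0 * (1.0 + 0.5 * np.exp(-np.clip(t - 2.0, 0, None)) * (t >= 2.0))
        movie.frames = np.repeat(f[:, None, None], 128 * 128, axis=1).reshape(n, 128, 128)
        roi = im.Roi(mask=np.ones((128, 128), bool), peak=(0, 0))
        trace = im.dff(movie, roi)[0]
        np.testing.assert_allclose(trace, (f - f0) / f0, atol=1e-10)

    def test_nonpositive_baseline_flags_invalid(self):
        movie = _blob_movie(n_trials=1)
        movie.frames[:] = 0.0
        roi = im.Roi(mask=np.ones((128, 128), bool), peak=(0, 0))
        traces = im.dff(movie, roi)
        assert not roi.valid
        assert np.isnan(traces).all()

    def test_metric_two_frames_mean(self):
        movie = _blob_movie(n_trials=1)
        trace = np.zeros(movie.trial_length)
        i0 = int(np.searchsorted(movie.trial_times, movie.expansion_end))
        trace[i0] = 0.4
        trace[i0 + 1] = 0.8
        assert im.roi_metric(trace, movie) == pytest.approx(0.6)

    def test_metric_constant(self):
        movie = _blob_movie(n_trials=1)
        assert im.roi_metric(np.full(movie.trial_length, 0.3), movie) == pytest.approx(0.3)

    def test_blank_subtraction(self):
        movie = _blob_movie(n_trials=1)
        trace = np.full(movie.trial_length, 0.5)
        assert im.roi_metric(trace, movie, blank_response=0.2) == pytest.approx(0.3)


class TestRoiIsoluminance:
    def test_off_scans_upward(self):
        curve = TuningCurve.from_means([6, 7, 8, 9], [0.5, 0.1, -0.1, -0.4])
        est = im.roi_isoluminance(curve, "OFF")
        assert est.value == pytest.approx(7.5)
        assert est.crossing_found

    def test_on_scans_downward(self):
        curve = TuningCurve.from_means([4, 5, 6, 7], [-0.4, -0.2, 0.2, 0.5])
        est = im.roi_isoluminance(curve, "ON")
        assert est.value == pytest.approx(5.5)
        assert est.crossing_found

    def test_no_crossing_takes_minimum(self):
        curve = TuningCurve.from_means([0, 3, 6, 9, 12], [0.9, 0.5, 0.3, 0.1, 0.2])
        est = im.roi_isoluminance(curve, "OFF")
        assert est.value == 9.0
        assert not est.crossing_found

    def test_negative_at_scan_start_capped(self):
        curve = TuningCurve.from_means([0, 5, 10, 15], [0.5, 0.2, -0.1, -0.3])
        est = im.roi_isoluminance(curve, "ON")   # already negative at UV=15
        assert est.value == 15.0 and est.capped

    def test_first_crossing_in_scan_order(self):
        # ON scan from the top: crossing between 12 and 10 wins over lower ones.
        curve = TuningCurve.from_means([0, 4, 8, 10, 12], [1.0, -1.0, 1.0, -0.5, 0.5])
        est = im.roi_isoluminance(curve, "ON")
        assert 10 < est.value < 12


class TestThresholdAndAggregate:
    @staticmethod
    def _roi(levels, means):
        roi = im.Roi(mask=np.ones((4, 4), bool), peak=(0, 0))
        roi.tuning = TuningCurve.from_means(levels, means)
        return roi

    def test_zero_threshold_keeps_all(self):
        levels = [0, 3, 12, 15]
        rois = [self._roi(levels, [0.5, 0.3, 0.2, 0.4]),
                self._roi(levels, [0.0, 0.0, 0.0, 0.0])]
        assert len(im.threshold_responsive(rois, "OFF", 0.0)) == 2

    def test_flat_roi_removed_at_positive_threshold(self):
        levels = [0, 3, 12, 15]
        rois = [self._roi(levels, [0.5, 0.3, -0.2, -0.4]),
                self._roi(levels, [0.0, 0.0, 0.0, 0.0])]
        kept = im.threshold_responsive(rois, "OFF", 0.05)
        assert len(kept) == 1

    def test_missing_reference_levels_error(self):
        rois = [self._roi([5, 6, 7], [0.1, 0.2, 0.3])]
        with pytest.raises(ValueError, match="reference"):
            im.threshold_responsive(rois, "OFF", 0.0)

    def test_dm9_reference_range(self):
        levels = [0, 1, 5, 15]
        rois = [self._roi(levels, [0.5, 0.5, -1.0, -1.0])]
        assert len(im.threshold_responsive(rois, "Dm9", 0.3,
                                           im.REFERENCE_LEVELS["Dm9"])) == 1

    def test_aggregate_equal_fly_weighting(self):
        # Fly A has ROIs {4, 6}, fly B has {8}: grand mean is 6.5, not 6.
        agg = im.aggregate([("A", 4.0), ("A", 6.0), ("B", 8.0)])
        assert agg.per_fly == {"A": 5.0, "B": 8.0}
        assert agg.grand_mean == pytest.approx(6.5)

    def test_single_roi_single_fly(self):
        agg = im.aggregate([("A", 7.25)])
        assert agg.grand_mean == pytest.approx(7.25)

    def test_excluded_fly_warns(self):
        with pytest.warns(UserWarning, match="no surviving"):
            im.aggregate([("A", 5.0)], expected_flies=["A", "B"])

    def test_population_from_fly_curves(self):
        levels = np.arange(16)
        curves = [TuningCurve.from_means(levels, 1.0 * (levels - 4.0)),
                  TuningCurve.from_means(levels, 1.0 * (levels - 6.0))]
        agg = im.aggregate([("A", 4.0), ("B", 6.0)], per_fly_curves=curves,
                           polarity="OFF")
        # OFF scan: mean curve is negative below 5... positive above; the
        # OFF rule looks for +->- which does not occur, so minimum rule.
        assert agg.population is not None

    def test_threshold_sweep_stability_on_linear_tuning(self):
        levels = np.arange(0, 16)
        rois, flies = [], []
        rng = np.random.default_rng(7)
        for fly in range(4):
            for _ in range(3):
                amp = rng.uniform(0.5, 1.5)
                rois.append(self._roi(levels, amp * (8.0 - levels) / 15.0))
                flies.append(fly)
        sweep = im.threshold_sweep(rois, flies, "OFF", np.linspace(0, 0.04, 5))
        kept_half = sweep[sweep["n_rois"] >= 6]
        assert kept_half["mean_isoluminance"].max() - kept_half["mean_isoluminance"].min() < 0.2


class TestEndToEnd:
    def test_noiseless_pipeline_recovers_planted_isoluminance(self):
        syn = sy.simulate_movie(
            [((64, 64), "ON", 5.0), ((64, 192), "ON", 5.0)],
            uv_levels=[0, 2, 4, 6, 8, 15], n_trials_per_level=1,
            jitter_sd=0.0, noise_sd=0.0, seed=11,
        )
        res = im.run_pipeline(syn.movie, "ON")
        assert not res.rejected
        assert len(res.estimates) == 2
        for _, est in res.estimates:
            assert est.value == pytest.approx(5.0, abs=0.1)

    def test_planted_jitter_recovered(self):
        syn = sy.simulate_movie([((64, 64), "ON", 5.0)], uv_levels=[0, 5, 15],
                                n_trials_per_level=1, jitter_sd=3.0,
                                noise_sd=2.0, seed=4)
        _, shifts, rejected = im.align(syn.movie, 15)
        assert not rejected
        rms = np.sqrt(np.mean((shifts - syn.jitter) ** 2))
        assert rms <= 1.0
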