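import numpy as np
import pytest

from respyre import (DataError, DetectionFailure, PeakDetectConfig,
                     SynthConfig, bandpass, detect_peaks, enhance_peaks,
                     generate, heart_rate_bpm, reject_false_peaks,
                     repair_clipping, rr_series)


class TestRepairClipping:
    def test_clipped_triangle_apex_restored(self):
        t = np.linspace(0, 2, 200)
        x = 1.0 - np.abs(t - 1.0)          # triangle, apex 1.0
        clipped = np.minimum(x, 0.8)
        y, spans = repair_clipping(clipped, clip_run_min=3)
        assert len(spans) == 1
        s, e = spans[0]
        assert y[s:e].max() > 0.8          # spline rises above the ceiling

    def test_single_sample_maximum_not_repaired(self):
        x = np.sin(np.linspace(0, 6 * np.pi, 300))
        y, spans = repair_clipping(x, clip_run_min=3)
        assert spans == []
        np.testing.assert_array_equal(y, x)

    def test_untouched_outside_spans(self):
        t = np.linspace(0, 2, 200)
        clipped = np.minimum(1.0 - np.abs(t - 1.0), 0.8)
        y, spans = repair_clipping(clipped, clip_run_min=3)
        mask = np.ones(y.size, bool)
        for s, e in spans:
            mask[s:e] = False
        np.testing.assert_array_equal(y[mask], clipped[mask])

    def test_matches_independent_spline(self):
        from scipy.interpolate import CubicSpline
        t = np.linspace(0, 2, 200)
        clipped = np.minimum(1.0 - np.abs(t - 1.0), 0.8)
        y, spans = repair_clipping(clipped, clip_run_min=3)
        (s, e), = spans
        anchors = np.r_[np.arange(s - 3, s), np.arange(e, e + 3)]
        expected = CubicSpline(anchors, clipped[anchors])(np.arange(s, e))
        np.testing.assert_allclose(y[s:e], expected)


def _enhanced_cardiac(rec):
    card = bandpass(rec.samples, rec.fs, 0.5, 3.5)
    return enhance_peaks(card)


class TestDetectPeaks:
    def test_clean_60bpm_minute_yields_60_peaks(self):
        cfg = SynthConfig(duration_s=60, hr_bpm=60, fm_depth=0.0,
                          am_depth=0.0, noise_sd=0.01, wander_amp=0.0,
                          seed=11)
        rec, _ = generate(cfg)
        peaks = detect_peaks(_enhanced_cardiac(rec), rec.fs)
        assert abs(peaks.size - 60) <= 1

    def test_flat_signal_fails(self):
        with pytest.raises(DetectionFailure):
            detect_peaks(np.zeros(2000), 125.0)

    def test_plateau_tie_takes_earliest_index(self):
        fs = 10.0
        x = np.zeros(400)
        for start in (50, 150, 250, 350):
            x[start:start + 5] = 1.0     # flat-topped plateaus
        peaks = detect_peaks(x, fs, PeakDetectConfig(ma_window_s=1.0,
                                                     bpm_min=1, bpm_max=600))
        assert set(peaks) <= {50, 150, 250, 350}

    @pytest.mark.parametrize("hr", range(50, 111, 10))
    def test_beat_recovery_on_clean_records(self, hr):
        """>=95% of true beats recovered within +-40 ms."""
        cfg = SynthConfig(duration_s=120, hr_bpm=hr, resp_hz=0.25,
                          noise_sd=0.02, wander_amp=0.1, seed=100 + hr)
        rec, truth = generate(cfg)
        peaks = reject_false_peaks(
            detect_peaks(_enhanced_cardiac(rec), rec.fs), rec.fs)
        peak_t = peaks / rec.fs
        # band-limiting smooths the fast systolic rise, delaying every apex
        # by the same few tens of ms; RR intervals are invariant to this
        # uniform delay, so it is removed before matching beat times
        offsets = [peak_t[np.argmin(np.abs(peak_t - bt))] - bt
                   for bt in truth.beat_times
                   if 1.0 < bt < cfg.duration_s - 1.0]
        delay = np.median(offsets)
        matched = sum(np.min(np.abs(peak_t - delay - bt)) <= 0.040
                      for bt in truth.beat_times
                      if 1.0 < bt < cfg.duration_s - 1.0)
        n_true = sum(1 for bt in truth.beat_times
                     if 1.0 < bt < cfg.duration_s - 1.0)
        assert matched / n_true >= 0.95


def brute_force_reject(peaks, fs, fraction=0.30):
    """Iterative restatement of the 30% rule with explicit recomputation."""
    peaks = list(peaks)
    while len(peaks) >= 2:
        rr = np.diff(peaks) / fs
        mean_rr = rr.mean()
        bad = [k for k, v in enumerate(rr) if v < fraction * mean_rr]
        if not bad:
            break
        del peaks[bad[0] + 1]
    return np.asarray(peaks)


class TestRejectFalsePeaks:
    fs = 125.0

    def test_extra_peak_removed(self):
        true = np.arange(0, 10 * 125, 125)
        with_false = np.sort(np.append(true, 3 * 125 + 12))  # 0.1 s after
        out = reject_false_peaks(with_false, self.fs)
        np.testing.assert_array_equal(out, true)

    def test_regular_train_unchanged(self):
        peaks = np.arange(0, 2000, 100)
        np.testing.assert_array_equal(reject_false_peaks(peaks, self.fs),
                                      peaks)

    def test_matches_brute_force_on_random_insertions(self, rng):
        for _ in range(50):
            n = rng.integers(5, 40)
            true = np.cumsum(rng.integers(80, 140, n))
            n_false = rng.integers(0, 4)
            false = true[rng.integers(0, n, n_false)] + rng.integers(
                5, 25, n_false)
            peaks = np.unique(np.concatenate([true, false]))
            out = reject_false_peaks(peaks, self.fs)
            np.testing.assert_array_equal(out,
                                          brute_force_reject(peaks, self.fs))

    def test_idempotent(self, rng):
        peaks = np.unique(rng.integers(0, 5000, 40))
        try:
            once = reject_false_peaks(peaks, self.fs)
        except DetectionFailure:
            return
        np.testing.assert_array_equal(reject_false_peaks(once, self.fs), once)

    def test_too_few_peaks(self):
        with pytest.raises(DetectionFailure):
            reject_false_peaks([5], self.fs)


class TestRRSeries:
    def test_one_second_intervals(self):
        rr = rr_series([0, 125, 250], fs=125)
        np.testing.assert_allclose(rr.rr_ms, [1000.0, 1000.0])

    def test_sub_second_interval(self):
        rr = rr_series([0, 100], fs=125)
        np.testing.assert_allclose(rr.rr_ms, [800.0])

    def test_non_increasing_rejected(self):
        with pytest.raises(DataError):
            rr_series([10, 10, 20], fs=125)


@pytest.mark.parametrize("rr_ms,expected", [
    ([1000, 1000], 60.0),
    ([500], 120.0),
    ([750, 850], 75.0),   # 60000 / 800
])
def test_heart_rate_bpm(rr_ms, expected):
    from respyre import RRSeries
    rr = RRSeries(peak_indices=np.arange(len(rr_ms) + 1),
                  rr_ms=np.asarray(rr_ms, float), fs=125.0)
    assert heart_rate_bpm(rr) == pytest.approx(expected)
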