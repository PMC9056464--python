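import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respyre import (ConfigError, DataError, bandpass, enhance_peaks,
                     hampel_filter, interpolate_missing)
from respyre.preprocess import MAD_TO_SIGMA

nan = np.nan


class TestInterpolateMissing:
    @pytest.mark.parametrize("x,expected", [
        ([1, nan, 3], [1, 2, 3]),              # mean of the two neighbours
        ([nan, 5, 5], [5, 5, 5]),              # leading edge fill
        ([1, nan, nan, 4], [1, 2, 3, 4]),      # linear fill over a run
        ([2, 4, nan], [2, 4, 4]),              # trailing edge fill
    ])
    def test_examples(self, x, expected):
        np.testing.assert_allclose(interpolate_missing(x), expected)

    def test_identity_and_idempotence(self, rng):
        x = rng.normal(size=200)
        x[rng.integers(0, 200, 20)] = nan
        once = interpolate_missing(x)
        assert not np.isnan(once).any()
        np.testing.assert_array_equal(interpolate_missing(once), once)
        clean = rng.normal(size=50)
        np.testing.assert_array_equal(interpolate_missing(clean), clean)

    def test_all_missing_error(self):
        with pytest.raises(DataError):
            interpolate_missing([nan, nan])


class TestBandpass:
    fs = 125.0

    def _rms(self, x):
        return np.sqrt(np.mean(x ** 2))

    def test_in_band_sinusoid_preserved(self):
        t = np.arange(0, 120, 1 / self.fs)
        x = np.sin(2 * np.pi * 0.25 * t)
        y = bandpass(x, self.fs, 0.1, 0.4)
        # analytic magnitude of the squared order-2 Butterworth at 0.25 Hz
        # is ~0.999; allow edge transients
        assert self._rms(y) >= 0.9 * self._rms(x)

    def test_out_of_band_sinusoid_suppressed(self):
        t = np.arange(0, 120, 1 / self.fs)
        x = np.sin(2 * np.pi * 2.0 * t)
        y = bandpass(x, self.fs, 0.1, 0.4)
        assert self._rms(y) <= 0.1 * self._rms(x)

    def test_zero_in_zero_out(self):
        y = bandpass(np.zeros(1000), self.fs, 0.1, 0.4)
        np.testing.assert_allclose(y, 0.0)

    def test_linearity(self, rng):
        a = rng.normal(size=4000)
        b = rng.normal(size=4000)
        lhs = bandpass(a + b, self.fs, 0.5, 3.5)
        rhs = bandpass(a, self.fs, 0.5, 3.5) + bandpass(b, self.fs, 0.5, 3.5)
        np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-9 * np.max(
            np.abs(lhs)))

    def test_invalid_band(self):
        with pytest.raises(ConfigError):
            bandpass(np.ones(100), 10.0, 0.1, 6.0)

    def test_rejects_missing_values(self):
        x = np.ones(100)
        x[3] = nan
        with pytest.raises(DataError):
            bandpass(x, self.fs, 0.1, 0.4)


class TestEnhancePeaks:
    def test_default_range_mapping(self):
        np.testing.assert_allclose(
            enhance_peaks([0, 0.5, 1], rb=1024, l_lt=0), [0, 512, 1024])

    def test_endpoints_map_to_limits(self):
        np.testing.assert_allclose(
            enhance_peaks([-3, 7], rb=10, l_lt=5), [5, 15])

    def test_constant_signal_error(self):
        with pytest.raises(DataError):
            enhance_peaks([2.0, 2.0, 2.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50)
           .filter(lambda v: max(v) > min(v)))
    def test_preserves_ranking(self, vals):
        x = np.asarray(vals)
        y = enhance_peaks(x)
        order = np.argsort(x, kind="stable")
        assert np.all(np.diff(y[order]) >= 0)   # order-preserving map
        assert y[np.argmax(x)] == y.max()


def brute_force_hampel(x, half_window, n_sigma):
    """Literal re-statement of the sliding median/MAD rule with end padding."""
    x = np.asarray(x, float)
    n = x.size
    padded = np.concatenate([x, np.full(half_window, x.mean())])
    out = x.copy()
    flagged = []
    for i in range(n):
        win = padded[max(0, i - half_window): i + half_window + 1]
        med = np.median(win)
        sigma = MAD_TO_SIGMA * np.median(np.abs(win - med))
        if abs(x[i] - med) > n_sigma * sigma:
            out[i] = med
            flagged.append(i)
    return out, np.array(flagged, dtype=np.int64)


class TestHampel:
    def test_single_spike_replaced_by_median(self):
        x = np.array([1, 1, 1, 50, 1, 1, 1, 1], float)
        y, idx = hampel_filter(x, half_window=3, n_sigma=3)
        assert idx.tolist() == [3]
        assert y[3] == 1.0

    def test_clean_sinusoid_untouched(self):
        t = np.linspace(0, 4, 400)
        x = np.sin(2 * np.pi * 0.5 * t)
        y, idx = hampel_filter(x, 3, 3)
        assert idx.size == 0
        np.testing.assert_array_equal(y, x)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            x = rng.normal(size=rng.integers(20, 200))
            spikes = rng.integers(0, x.size, 3)
            x[spikes] += rng.choice([-1, 1], 3) * 10.0
            y, idx = hampel_filter(x, 3, 3)
            y_ref, idx_ref = brute_force_hampel(x, 3, 3)
            np.testing.assert_array_equal(y, y_ref)
            np.testing.assert_array_equal(idx, idx_ref)

    def test_non_flagged_samples_bit_identical(self, rng):
        x = rng.normal(size=300)
        y, idx = hampel_filter(x, 3, 3)
        mask = np.ones(x.size, bool)
        mask[idx] = False
        np.testing.assert_array_equal(y[mask], x[mask])

    def test_too_short_signal(self):
        with pytest.raises(DataError):
            hampel_filter(np.ones(5), half_window=3)
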