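"""F/F0 normalization, smoothing, noise estimation, peak detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endoca.datatypes import FF0Trace
from endoca.synthetic import transient_kernel
from endoca.traces import (detect_peaks, estimate_noise_sd, moving_average,
                           normalize_f_f0, savgol_smooth)


class TestNormalize:
    def test_constant_trace_maps_to_one(self):
        ff0 = normalize_f_f0(np.full(300, 7.3))
        assert np.allclose(ff0.values, 1.0)
        assert abs(ff0.values[:100].mean() - 1.0) < 1e-9

    def test_simple_ratio(self):
        raw = np.full(150, 2.0)
        raw[120] = 3.0
        assert normalize_f_f0(raw).values[120] == pytest.approx(1.5)

    def test_matches_elementwise_division(self, rng):
        raw = rng.random(300) + 0.5
        ff0 = normalize_f_f0(raw)
        np.testing.assert_allclose(ff0.values, raw / raw[:100].mean())

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=1e4))
    def test_scale_invariance(self, c):
        raw = np.linspace(1.0, 2.0, 200)
        a = normalize_f_f0(raw).values
        b = normalize_f_f0(c * raw).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            normalize_f_f0(np.ones(100))

    def test_nonpositive_baseline_rejected(self):
        raw = np.zeros(200)
        raw[150:] = 5.0
        with pytest.raises(ValueError, match="positive"):
            normalize_f_f0(raw)


class TestSavgol:
    def test_reproduces_cubic_at_interior(self, rng):
        coeffs = rng.normal(size=4)
        x = np.arange(200, dtype=float)
        y = np.polyval(coeffs, x / 100)
        out = savgol_smooth(y, 21, 3)
        np.testing.assert_allclose(out[10:-10], y[10:-10], atol=1e-8)

    def test_preserves_constant(self):
        assert np.allclose(savgol_smooth(np.full(50, 3.3), 21, 3), 3.3)

    def test_matches_windowed_least_squares_oracle(self, rng):
        y = rng.random(101)
        out = savgol_smooth(y, 21, 3)
        # explicit cubic least squares on the window centred at index 50
        idx = np.arange(40, 61)
        X = np.vander(idx - 50.0, 4, increasing=True)
        beta, *_ = np.linalg.lstsq(X, y[idx], rcond=None)
        assert out[50] == pytest.approx(beta[0], abs=1e-10)

    @pytest.mark.parametrize("window,poly", [(20, 3), (21, 21), (5, 7)])
    def test_invalid_window_rejected(self, window, poly):
        with pytest.raises(ValueError):
            savgol_smooth(np.ones(100), window, poly)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            savgol_smooth(np.ones(10), 21, 3)

    def test_moving_average_patch_config(self):
        y = np.ones(100)
        y[50] = 21.0
        out = moving_average(y, 20)
        assert out.max() == pytest.approx(2.0)  # spread over the boxcar


class TestNoiseEstimate:
    def test_noise_free_is_zero(self):
        t = np.arange(300) / 10.0
        clean = 1.0 + transient_kernel(t, 20.0, 0.5)
        ff0 = FF0Trace(values=clean)
        assert estimate_noise_sd(ff0) == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_gaussian_sd(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = 1.0 + rng.normal(0, 0.02, 500)
            errs.append(estimate_noise_sd(FF0Trace(values=vals)))
        assert np.mean(errs) == pytest.approx(0.02, rel=0.2)

    def test_scales_linearly_with_noise(self):
        rng = np.random.default_rng(4)
        noise = rng.normal(0, 0.01, 400)
        a = estimate_noise_sd(FF0Trace(values=1 + noise))
        b = estimate_noise_sd(FF0Trace(values=1 + 2 * noise))
        assert b == pytest.approx(2 * a, rel=1e-9)


def _brute_force_peaks(s, threshold):
    """Exhaustive local-maximum scan: s[i-1] < s[i] >= s[i+1], amplitude
    above threshold."""
    out = []
    for i in range(1, len(s) - 1):
        if s[i - 1] < s[i] >= s[i + 1] and s[i] - 1.0 >= threshold:
            out.append(i)
    return out


class TestDetectPeaks:
    def test_monotone_trace_has_no_peaks(self):
        assert detect_peaks(np.linspace(1, 3, 100)) == []

    def test_single_transient(self):
        t = np.arange(500) / 10.0
        s = 1.0 + transient_kernel(t, 20.0, 0.5)
        peaks = detect_peaks(s, frame_rate_hz=10.0)
        assert len(peaks) == 1
        assert peaks[0].frame == int(np.argmax(s))
        assert peaks[0].amplitude == pytest.approx(0.5, abs=1e-3)

    def test_plateau_reports_first_frame(self):
        # rising ramp reaches 2.0 at index 9; the flat top spans 9..14
        s = np.concatenate([np.linspace(1, 2, 10), np.full(5, 2.0),
                            np.linspace(2, 1, 10)])
        peaks = detect_peaks(s)
        assert [p.frame for p in peaks] == [9]

    def test_matches_local_maximum_oracle(self, rng):
        for _ in range(50):
            s = 1.0 + savgol_smooth(rng.normal(0, 0.2, 300), 21, 3)
            peaks = detect_peaks(s, noise_sd=0.0, min_amplitude=0.05)
            assert [p.frame for p in peaks] == _brute_force_peaks(s, 0.05)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.2),
           st.floats(min_value=1.0, max_value=6.0))
    def test_count_non_increasing_in_thresholds(self, min_amp, k_sigma):
        rng = np.random.default_rng(77)
        s = 1.0 + savgol_smooth(rng.normal(0, 0.2, 300), 21, 3)
        base = len(detect_peaks(s, noise_sd=0.02, k_sigma=1.0,
                                min_amplitude=0.0))
        tightened = len(detect_peaks(s, noise_sd=0.02, k_sigma=k_sigma,
                                     min_amplitude=min_amp))
        assert tightened <= base

    def test_peaks_in_time_order(self, rng):
        s = 1.0 + savgol_smooth(np.abs(rng.normal(0, 0.3, 400)), 21, 3)
        frames = [p.frame for p in detect_peaks(s)]
        assert frames == sorted(frames)
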