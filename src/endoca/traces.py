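"""F/F0 normalization, smoothing, and Ca2+ event peak detection.

The processing chain per cell is: divide the raw trace by the mean of its
first ``baseline_frames`` frames (F/F0), smooth with a 21-point third-order
Savitzky-Golay filter, and find event apexes as positive-to-negative zero
crossings of the smoothed trace's derivative, keeping peaks whose amplitude
(smoothed F/F0 - 1) clears max(k_sigma * noise SD, min_amplitude).

The derivative used for the zero-crossing detector is the first difference
of the smoothed trace: its sign change is exactly the local-maximum
condition (with plateaus resolved to their first frame), so the detector
provably returns every retained local maximum and nothing else.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter, peak_prominences
from scipy.ndimage import uniform_filter1d

from .datatypes import FF0Trace, Peak

__all__ = [
    "normalize_f_f0",
    "savgol_smooth",
    "moving_average",
    "estimate_noise_sd",
    "detect_peaks",
    "detection_threshold",
]

DEFAULT_BASELINE_FRAMES = 100
DEFAULT_SG_WINDOW = 21
DEFAULT_SG_POLYORDER = 3
DEFAULT_K_SIGMA = 3.0
DEFAULT_MIN_AMPLITUDE = 0.05


def normalize_f_f0(raw, baseline_frames: int = DEFAULT_BASELINE_FRAMES,
                   frame_rate_hz: float = 10.0) -> FF0Trace:
    """Divide a raw intensity trace by its mean over the opening baseline
    window (the first ``baseline_frames`` frames).

    Raises
    ------
    ValueError
        If the trace is no longer than the baseline window, or the baseline
        mean is not strictly positive (an unusable trace).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("raw trace must be 1-D")
    if raw.size <= baseline_frames:
        raise ValueError("trace must be longer than the baseline window")
    f0 = raw[:baseline_frames].mean()
    if not np.isfinite(f0) or f0 <= 0:
        raise ValueError("baseline mean must be positive; trace unusable")
    return FF0Trace(values=raw / f0, baseline_frames=baseline_frames,
                    frame_rate_hz=frame_rate_hz)


def savgol_smooth(values, window: int = DEFAULT_SG_WINDOW,
                  polyorder: int = DEFAULT_SG_POLYORDER) -> np.ndarray:
    """Savitzky-Golay smoothing (local least-squares polynomial fit
    evaluated at the window centre), mirror-padded at the edges."""
    values = np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if values.size < window:
        raise ValueError("trace shorter than the smoothing window")
    return savgol_filter(values, window, polyorder, mode="mirror")


def moving_average(values, window: int = 20) -> np.ndarray:
    """Boxcar smoothing, the alternate configuration used for the isolated
    patch recordings (20-point window)."""
    values = np.asarray(values, dtype=float)
    if not 1 <= window <= values.size:
        raise ValueError("window must be in [1, len(trace)]")
    return uniform_filter1d(values, size=window, mode="reflect")


def estimate_noise_sd(ff0: FF0Trace, window: int = DEFAULT_SG_WINDOW,
                      polyorder: int = DEFAULT_SG_POLYORDER) -> float:
    """Robust per-trace noise SD: 1.4826 x the median absolute deviation of
    (raw F/F0 minus its smoothed version) over the baseline window."""
    if ff0.baseline_frames < 1:
        raise ValueError("baseline window is empty")
    smoothed = savgol_smooth(ff0.values, window, polyorder)
    resid = (ff0.values - smoothed)[: ff0.baseline_frames]
    return 1.4826 * float(np.median(np.abs(resid - np.median(resid))))


def detection_threshold(noise_sd: float, k_sigma: float = DEFAULT_K_SIGMA,
                        min_amplitude: float = DEFAULT_MIN_AMPLITUDE) -> float:
    """Amplitude floor for retaining a peak: max(k_sigma * sigma, floor)."""
    return max(k_sigma * noise_sd, min_amplitude)


def detect_peaks(smoothed, frame_rate_hz: float = 10.0,
                 noise_sd: float = 0.0,
                 k_sigma: float = DEFAULT_K_SIGMA,
                 min_amplitude: float = DEFAULT_MIN_AMPLITUDE) -> list[Peak]:
    """Find Ca2+ event apexes on a smoothed F/F0 trace.

    Candidates are positive-to-negative zero crossings of the trace
    derivative (plateau tops resolve to their first frame); a candidate is
    retained when its amplitude, the smoothed value minus 1, reaches
    ``max(k_sigma * noise_sd, min_amplitude)``. Peaks are returned in time
    order; an empty list is a valid result.
    """
    s = np.asarray(smoothed, dtype=float)
    if s.ndim != 1:
        raise ValueError("smoothed trace must be 1-D")
    threshold = detection_threshold(noise_sd, k_sigma, min_amplitude)

    # A retained apex is the sample after the last strictly rising step that
    # is followed (across any flat run) by a falling step: exactly the local
    # maxima with plateau tops resolved to their first frame.
    d = np.diff(s)
    nz = np.flatnonzero(d)
    if nz.size >= 2:
        rising = d[nz] > 0
        crossing = rising[:-1] & ~rising[1:]
        candidates = nz[:-1][crossing] + 1
    else:
        candidates = np.empty(0, dtype=int)

    frames_arr = candidates[s[candidates] - 1.0 >= threshold]
    if frames_arr.size == 0:
        return []
    prom = peak_prominences(s, frames_arr)[0]
    return [
        Peak(frame=int(f), time_s=f / frame_rate_hz,
             amplitude=float(s[f] - 1.0), prominence=float(p))
        for f, p in zip(frames_arr, prom)
    ]
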