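"""Per-cell event metrics and activity classification.

A cell's response to a stimulus is summarized over a response window
[stim_frame, stim_frame + window): peak amplitude (max smoothed F/F0 - 1),
number of oscillation peaks, mean F/F0, and response duration (first to
last crossing of the detection threshold). Any detected activity in the
window makes the cell a responder; any retained peak in the first 150
frames marks it spontaneously active at baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CellEventSummary, FF0Trace, Peak
from .traces import (DEFAULT_K_SIGMA, DEFAULT_MIN_AMPLITUDE,
                     detection_threshold, savgol_smooth)

__all__ = [
    "summarize_cell",
    "classify_responder",
    "spontaneous_activity",
    "percent_active",
    "summaries_to_frame",
    "SPONTANEOUS_WINDOW",
]

#: Baseline window for spontaneous-activity counting: the first 150 frames
#: (15 s at 10 frames/s), half-open.
SPONTANEOUS_WINDOW = (0, 150)


def summarize_cell(ff0: FF0Trace, peaks: list[Peak], stim_frame: int,
                   window_frames: int | None = None,
                   smoothed: np.ndarray | None = None,
                   noise_sd: float = 0.0,
                   k_sigma: float = DEFAULT_K_SIGMA,
                   min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
                   cell_id: int = 0) -> CellEventSummary:
    """Reduce one cell's trace and peaks to its response-window metrics.

    The window is [stim_frame, min(stim_frame + window_frames, T)); when
    ``window_frames`` is None it extends to the end of the record (the
    full post-stimulus record is analysed). ``peak_amp`` is the maximum
    smoothed F/F0 in the window minus 1 when at least one retained peak
    falls there, else 0. Duration runs from the first upward crossing of
    the detection threshold after the stimulus to the last frame still at
    or above it within the window.
    """
    T = ff0.values.size
    if not 0 <= stim_frame < T:
        raise ValueError("stim_frame must lie within the trace")
    end = T if window_frames is None else min(stim_frame + window_frames, T)
    if end <= stim_frame:
        raise ValueError("empty response window")

    if smoothed is None:
        smoothed = savgol_smooth(ff0.values)
    smoothed = np.asarray(smoothed, dtype=float)

    in_window = [p for p in peaks if stim_frame <= p.frame < end]
    n_peaks = len(in_window)
    window_vals = smoothed[stim_frame:end]
    peak_amp = float(max(window_vals.max() - 1.0, 0.0)) if n_peaks else 0.0
    mean_ff0 = float(ff0.values[stim_frame:end].mean())

    duration_s = 0.0
    if n_peaks:
        thr = 1.0 + detection_threshold(noise_sd, k_sigma, min_amplitude)
        above = np.nonzero(window_vals >= thr)[0]
        if above.size:
            duration_s = (above[-1] - above[0]) / ff0.frame_rate_hz

    return CellEventSummary(cell_id=cell_id, peak_amp=peak_amp,
                            n_peaks=n_peaks, mean_ff0=mean_ff0,
                            duration_s=duration_s, responder=n_peaks >= 1)


def classify_responder(summary: CellEventSummary) -> bool:
    """Any detected activity in the stimulus window counts as responding."""
    return summary.n_peaks >= 1


def spontaneous_activity(ff0: FF0Trace, peaks: list[Peak],
                         window: tuple[int, int] = SPONTANEOUS_WINDOW) -> bool:
    """True iff at least one retained peak falls in the baseline window
    (default: the first 150 frames, half-open)."""
    lo, hi = window
    if ff0.values.size < hi:
        raise ValueError(
            f"trace shorter than the spontaneous-activity window [{lo}, {hi})")
    return any(lo <= p.frame < hi for p in peaks)


def percent_active(flags) -> float:
    """Percentage of True flags; permutation-invariant by construction."""
    flags = list(flags)
    if not flags:
        raise ValueError("no cells to classify")
    return 100.0 * sum(bool(f) for f in flags) / len(flags)


def summaries_to_frame(summaries: list[CellEventSummary],
                       **constants) -> pd.DataFrame:
    """Stack per-cell summaries into a tidy table; ``constants`` adds
    recording-level columns (animal, condition, tech_rep, ...)."""
    df = pd.DataFrame([{
        "cell_id": s.cell_id,
        "peak_amp": s.peak_amp,
        "n_peaks": s.n_peaks,
        "mean_ff0": s.mean_ff0,
        "duration_s": s.duration_s,
        "responder": s.responder,
        "spont_active": s.spont_active,
    } for s in summaries])
    for key, val in constants.items():
        df[key] = val
    return df
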