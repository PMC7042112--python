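"""Core containers shared across the pipeline.

The pipeline reduces a fluorescence movie to per-cell time series and then to
per-cell event metrics:

* :class:`Movie` — a T x H x W stack of non-negative intensities with its
  acquisition geometry (frame rate, pixel size).
* :class:`CellMap` — an integer label image assigning pixels to cells
  (0 = background), standing in for manually placed regions of interest.
* :class:`RawTraceSet` — per-cell mean-intensity traces extracted from a movie.
* :class:`FF0Trace` — a baseline-normalized trace (F/F0), dimensionless, with
  resting level 1 over its baseline window by construction.
* :class:`Peak` — a detected Ca2+ event apex; ``amplitude`` is the smoothed
  F/F0 value at the apex minus 1 (i.e. dF/F0).
* :class:`CellEventSummary` — the per-cell metrics reported downstream
  (peak amplitude, oscillation count, response duration, mean F/F0, and the
  responder / spontaneously-active flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Movie",
    "CellMap",
    "RawTraceSet",
    "FF0Trace",
    "Peak",
    "CellEventSummary",
]


@dataclass(frozen=True)
class Movie:
    """A fluorescence movie: frames (T, H, W), all finite and >= 0."""

    frames: np.ndarray
    frame_rate_hz: float = 10.0
    pixel_size_um: float = 0.4

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W stack with T >= 1")
        if not np.all(np.isfinite(frames)):
            raise ValueError("movie contains non-finite values")
        if frames.min() < 0:
            raise ValueError("movie contains negative intensities")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass(frozen=True)
class CellMap:
    """Integer label image: 0 background, consecutive cell IDs 1..N."""

    labels: np.ndarray
    pixel_size_um: float = 0.4

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be an integer image")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "labels", labels)

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def pixel_counts(self) -> np.ndarray:
        """Pixels per cell, indexed so entry i corresponds to cell ID i+1."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_cells + 1)
        return counts[1:]


@dataclass
class RawTraceSet:
    """Per-cell raw traces: ``traces[i]`` is the mean intensity of cell
    ``cell_ids[i]`` in each frame."""

    traces: np.ndarray  # (n_cells, T)
    cell_ids: np.ndarray  # (n_cells,)
    frame_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        self.cell_ids = np.asarray(self.cell_ids, dtype=int)
        if self.traces.shape[0] != self.cell_ids.shape[0]:
            raise ValueError("one trace per cell ID required")

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


@dataclass
class FF0Trace:
    """Baseline-normalized trace; mean over the baseline window is 1."""

    values: np.ndarray
    baseline_frames: int = 100
    frame_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("F/F0 trace contains non-finite values")
        if not 0 < self.baseline_frames <= self.values.size:
            raise ValueError("baseline window must lie within the trace")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate_hz


@dataclass(frozen=True)
class Peak:
    frame: int
    time_s: float
    amplitude: float  # smoothed F/F0 at the apex minus 1
    prominence: float


@dataclass
class CellEventSummary:
    cell_id: int
    peak_amp: float
    n_peaks: int
    mean_ff0: float
    duration_s: float
    responder: bool
    spont_active: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        if self.peak_amp < 0:
            raise ValueError("peak_amp must be >= 0")
        if self.responder != (self.n_peaks >= 1):
            raise ValueError("responder flag must equal (n_peaks >= 1)")
        if self.n_peaks == 0 and self.duration_s != 0:
            raise ValueError("duration must be 0 for a cell without peaks")
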