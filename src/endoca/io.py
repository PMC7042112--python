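"""Reading and writing the pipeline's on-disk formats.

Movies are multi-page unsigned 16-bit TIFF stacks; cell maps are
single-page integer TIFFs. Acquisition metadata (frame rate, pixel size,
seed, preset) travels in a JSON sidecar next to each TIFF. Traces, peaks,
ground-truth events and per-cell summaries are plain CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import CellMap, FF0Trace, Movie, Peak, RawTraceSet

__all__ = [
    "write_movie", "read_movie",
    "write_cell_map", "read_cell_map",
    "write_traces_csv", "read_traces_csv",
    "write_peaks_csv", "read_peaks_csv",
    "write_ground_truth", "sidecar_path",
]


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path, meta: dict) -> None:
    with open(sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def _read_sidecar(path) -> dict:
    p = sidecar_path(path)
    if p.exists():
        with open(p) as fh:
            return json.load(fh)
    return {}


def write_movie(path, movie: Movie, extra_meta: dict | None = None) -> None:
    """Write a movie as multi-page uint16 TIFF plus a JSON sidecar."""
    frames = np.clip(np.round(movie.frames), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, frames.astype(np.uint16))
    meta = {"frame_rate_hz": movie.frame_rate_hz,
            "pixel_size_um": movie.pixel_size_um}
    meta.update(extra_meta or {})
    _write_sidecar(path, meta)


def read_movie(path, frame_rate_hz: float | None = None,
               pixel_size_um: float | None = None) -> Movie:
    """Read a TIFF stack; metadata comes from the sidecar unless given."""
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = _read_sidecar(path)
    return Movie(
        frames=frames.astype(np.float32),
        frame_rate_hz=frame_rate_hz or meta.get("frame_rate_hz", 10.0),
        pixel_size_um=pixel_size_um or meta.get("pixel_size_um", 0.4),
    )


def write_cell_map(path, cell_map: CellMap) -> None:
    tifffile.imwrite(path, cell_map.labels.astype(np.uint16))
    _write_sidecar(path, {"pixel_size_um": cell_map.pixel_size_um})


def read_cell_map(path, pixel_size_um: float | None = None) -> CellMap:
    labels = tifffile.imread(path).astype(np.int32)
    meta = _read_sidecar(path)
    return CellMap(labels=labels,
                   pixel_size_um=pixel_size_um or meta.get("pixel_size_um", 0.4))


def write_traces_csv(path, traces: RawTraceSet,
                     value_column: str = "intensity") -> None:
    """Long-format trace table: cell_id, frame, time_s, <value>."""
    n_cells, T = traces.traces.shape
    frames = np.tile(np.arange(T), n_cells)
    df = pd.DataFrame({
        "cell_id": np.repeat(traces.cell_ids, T),
        "frame": frames,
        "time_s": frames / traces.frame_rate_hz,
        value_column: traces.traces.ravel(),
    })
    df.to_csv(path, index=False)


def read_traces_csv(path, value_column: str = "intensity",
                    frame_rate_hz: float | None = None) -> RawTraceSet:
    df = pd.read_csv(path)
    ids = np.sort(df["cell_id"].unique())
    wide = (df.pivot(index="cell_id", columns="frame", values=value_column)
              .loc[ids].to_numpy())
    if frame_rate_hz is None:
        with_time = df[df["frame"] == 1]
        frame_rate_hz = (1.0 / with_time["time_s"].iloc[0]
                         if len(with_time) and with_time["time_s"].iloc[0] > 0
                         else 10.0)
    return RawTraceSet(traces=wide, cell_ids=ids, frame_rate_hz=frame_rate_hz)


def write_peaks_csv(path, peaks_by_cell: dict[int, list[Peak]]) -> None:
    rows = [
        (cid, p.frame, p.time_s, p.amplitude, p.prominence)
        for cid, peaks in peaks_by_cell.items() for p in peaks
    ]
    pd.DataFrame(rows, columns=["cell_id", "frame", "time_s", "amplitude",
                                "prominence"]).to_csv(path, index=False)


def read_peaks_csv(path) -> dict[int, list[Peak]]:
    df = pd.read_csv(path)
    out: dict[int, list[Peak]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(int(row.cell_id), []).append(
            Peak(frame=int(row.frame), time_s=float(row.time_s),
                 amplitude=float(row.amplitude),
                 prominence=float(row.prominence)))
    return out


def write_ground_truth(path, events: pd.DataFrame, meta: dict) -> None:
    """One row per true event (animal, tech_rep, cell_id, frame, amplitude,
    ...) plus a JSON sidecar recording preset, seed, frame rate and pixel
    size exactly as used."""
    events.to_csv(path, index=False)
    _write_sidecar(path, meta)
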