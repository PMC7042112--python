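"""End-to-end pipeline orchestration with reproducible configuration.

A :class:`RunConfig` names a preset, a workspace directory, a master seed
and every stage parameter; :func:`run` executes the requested stages in
canonical order (simulate -> extract -> process -> summarize -> stats, or
recover), writing TIFF/CSV/JSON artifacts into the workspace. Identical
config + seed produces identical outputs: all randomness flows from the
single master seed and there is no hidden global state.

Workspace layout (per preset arm)::

    <workspace>/<arm>/cellmap.tif(.json)
    <workspace>/<arm>/a<animal>_r<rep>_movie.tif(.json)
    <workspace>/<arm>/a<animal>_r<rep>_raw.csv / _ff0.csv / _peaks.csv
    <workspace>/ground_truth_<arm>.csv(.json)
    <workspace>/summary.csv
    <workspace>/stats.json
    <workspace>/recovery.json
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .datatypes import CellMap, RawTraceSet
from .presets import preset as get_preset
from .recovery import (ProcessingConfig, patch_fractions, process_recording,
                       recover_preset)
from .roi import extract_traces, uncaging_mask
from .stats import aggregate, paired_t_log
from .synthetic import NoiseModel, generate_cell_map, render_movie, \
    simulate_traces

__all__ = ["RunConfig", "run", "STAGES"]

log = logging.getLogger("endoca")

STAGES = ("simulate", "extract", "process", "summarize", "stats", "recover")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips losslessly via YAML.

    Defaults mirror the acquisition and analysis settings of the study the
    presets encode: 100-frame F0 baseline, 21-point third-order smoothing,
    10 frames/s, a 70-um uncaging disc, triplicate technical replicates and
    alpha = 0.05.
    """

    stages: list[str] = field(default_factory=lambda: list(STAGES[:5]))
    preset: str = "ip3_fk506"
    arms: list[str] | None = None
    workspace: str = "endoca_run"
    seed: int = 0

    # synthetic field geometry
    height: int = 192
    width: int = 192
    pixel_size_um: float = 0.4

    # imaging noise model
    baseline_counts: float = 200.0
    read_noise_sd: float = 3.0
    bleach_rate_per_frame: float = 0.0
    shot_noise: bool = True

    # trace processing
    baseline_frames: int = 100
    sg_window: int = 21
    sg_polyorder: int = 3
    k_sigma: float = 3.0
    min_amplitude: float = 0.05
    response_window_frames: int | None = None

    # uncaging mask (x, y in pixels); None disables masking
    uncage_center: tuple[float, float] | None = None
    uncage_diameter_um: float = 70.0
    overlap_threshold: float = 0.5
    remap_csv: str | None = None  # optional old_id,new_id table

    # statistics
    alpha: float = 0.05
    recover_n_seeds: int = 20

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}; "
                             f"valid: {list(STAGES)}")
        get_preset(self.preset)  # raises on unknown preset
        if self.sg_window % 2 == 0 or self.sg_polyorder >= self.sg_window:
            raise ValueError("smoothing window must be odd and > polyorder")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.baseline_frames < 1 or self.recover_n_seeds < 1:
            raise ValueError("counts must be >= 1")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if d["uncage_center"] is not None:
            d["uncage_center"] = list(d["uncage_center"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        extra = set(d) - {f.name for f in dataclasses.fields(cls)}
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        if d.get("uncage_center") is not None:
            d["uncage_center"] = tuple(d["uncage_center"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def processing(self) -> ProcessingConfig:
        return ProcessingConfig(
            baseline_frames=self.baseline_frames, sg_window=self.sg_window,
            sg_polyorder=self.sg_polyorder, k_sigma=self.k_sigma,
            min_amplitude=self.min_amplitude,
            response_window_frames=self.response_window_frames)

    def noise(self) -> NoiseModel:
        return NoiseModel(self.baseline_counts, self.read_noise_sd,
                          self.bleach_rate_per_frame, self.shot_noise)


def _arm_specs(cfg: RunConfig):
    cp = get_preset(cfg.preset)
    if not cp.arms:
        raise ValueError(
            f"preset {cfg.preset!r} is a phase protocol; use the recover "
            "stage (patch fractions) instead of simulate/extract")
    return [cp.arm(a) for a in cfg.arms] if cfg.arms else list(cp.arms)


def _rec_tag(animal: int, rep: int) -> str:
    return f"a{animal}_r{rep}"


def _stage_simulate(cfg: RunConfig, ws: Path) -> None:
    for k, arm in enumerate(_arm_specs(cfg)):
        arm_dir = ws / arm.name
        arm_dir.mkdir(parents=True, exist_ok=True)
        cmap = generate_cell_map(cfg.height, cfg.width, arm.n_cells,
                                 cfg.pixel_size_um, seed=cfg.seed + 1000 * k)
        eio.write_cell_map(arm_dir / "cellmap.tif", cmap)
        sim = simulate_traces(arm, cell_map=cmap, seed=cfg.seed * 13 + k)
        for rec in sim.recordings:
            movie = render_movie(
                rec.traces, cmap,
                baseline_counts=cfg.baseline_counts,
                read_noise_sd=cfg.read_noise_sd,
                bleach_rate_per_frame=cfg.bleach_rate_per_frame,
                seed=cfg.seed * 10007 + 101 * k + 17 * rec.animal
                + rec.tech_rep,
                frame_rate_hz=arm.frame_rate_hz,
                shot_noise=cfg.shot_noise)
            eio.write_movie(arm_dir / f"{_rec_tag(rec.animal, rec.tech_rep)}"
                            "_movie.tif", movie,
                            {"preset": cfg.preset, "arm": arm.name,
                             "animal": rec.animal, "tech_rep": rec.tech_rep,
                             "stim_frame": arm.stim_frame, "seed": cfg.seed})
            log.info("simulate %s %s: rendered %d frames", arm.name,
                     _rec_tag(rec.animal, rec.tech_rep), arm.n_frames)
        eio.write_ground_truth(
            ws / f"ground_truth_{arm.name}.csv", sim.ground_truth.events,
            {"preset": cfg.preset, "arm": arm.name, "seed": cfg.seed,
             "frame_rate_hz": arm.frame_rate_hz,
             "pixel_size_um": cfg.pixel_size_um})


def _load_remap(path) -> dict[int, int]:
    df = pd.read_csv(path)
    return dict(zip(df["old_id"].astype(int), df["new_id"].astype(int)))


def _stage_extract(cfg: RunConfig, ws: Path) -> None:
    for arm in _arm_specs(cfg):
        arm_dir = ws / arm.name
        cmap = eio.read_cell_map(arm_dir / "cellmap.tif")
        if cfg.remap_csv:
            remap = _load_remap(cfg.remap_csv)
            labels = cmap.labels.copy()
            for old, new in remap.items():
                labels[cmap.labels == old] = new
            cmap = CellMap(labels=labels, pixel_size_um=cmap.pixel_size_um)
        keep: set[int] | None = None
        if cfg.uncage_center is not None:
            keep = uncaging_mask(cmap, cfg.uncage_center,
                                 cfg.uncage_diameter_um,
                                 cfg.overlap_threshold)
            log.info("extract %s: uncaging mask keeps %d cells",
                     arm.name, len(keep))
        for movie_path in sorted(arm_dir.glob("*_movie.tif")):
            movie = eio.read_movie(movie_path)
            ts = extract_traces(movie, cmap)
            if keep is not None:
                sel = np.isin(ts.cell_ids, sorted(keep))
                ts = RawTraceSet(traces=ts.traces[sel],
                                 cell_ids=ts.cell_ids[sel],
                                 frame_rate_hz=ts.frame_rate_hz)
            out = movie_path.with_name(
                movie_path.name.replace("_movie.tif", "_raw.csv"))
            eio.write_traces_csv(out, ts)
            log.info("extract %s %s: %d traces", arm.name,
                     movie_path.stem, ts.traces.shape[0])


def _stage_process(cfg: RunConfig, ws: Path) -> None:
    from .traces import (detect_peaks, estimate_noise_sd, normalize_f_f0,
                         savgol_smooth)
    for arm in _arm_specs(cfg):
        arm_dir = ws / arm.name
        for raw_path in sorted(arm_dir.glob("*_raw.csv")):
            ts = eio.read_traces_csv(raw_path,
                                     frame_rate_hz=arm.frame_rate_hz)
            ff0_rows, peaks = [], {}
            for cid, trace in zip(ts.cell_ids, ts.traces):
                ff0 = normalize_f_f0(trace, cfg.baseline_frames,
                                     ts.frame_rate_hz)
                smoothed = savgol_smooth(ff0.values, cfg.sg_window,
                                         cfg.sg_polyorder)
                noise_sd = estimate_noise_sd(ff0, cfg.sg_window,
                                             cfg.sg_polyorder)
                peaks[int(cid)] = detect_peaks(
                    smoothed, ts.frame_rate_hz, noise_sd, cfg.k_sigma,
                    cfg.min_amplitude)
                ff0_rows.append(ff0.values)
            out_ff0 = RawTraceSet(traces=np.array(ff0_rows),
                                  cell_ids=ts.cell_ids,
                                  frame_rate_hz=ts.frame_rate_hz)
            eio.write_traces_csv(
                raw_path.with_name(raw_path.name.replace("_raw", "_ff0")),
                out_ff0, value_column="ff0")
            eio.write_peaks_csv(
                raw_path.with_name(raw_path.name.replace("_raw", "_peaks")),
                peaks)
            log.info("process %s %s: %d peaks", arm.name, raw_path.stem,
                     sum(len(v) for v in peaks.values()))


def _stage_summarize(cfg: RunConfig, ws: Path) -> None:
    all_rows = []
    for arm in _arm_specs(cfg):
        arm_dir = ws / arm.name
        for raw_path in sorted(arm_dir.glob("*_raw.csv")):
            tag = raw_path.stem.replace("_raw", "")
            animal, rep = (int(x[1:]) for x in tag.split("_"))
            ts = eio.read_traces_csv(raw_path,
                                     frame_rate_hz=arm.frame_rate_hz)
            df = process_recording(ts.traces, ts.frame_rate_hz,
                                   arm.stim_frame, cfg.processing(),
                                   cell_ids=ts.cell_ids)
            df["animal"] = animal
            df["tech_rep"] = rep
            df["condition"] = arm.name
            all_rows.append(df)
    summary = pd.concat(all_rows, ignore_index=True)
    summary.to_csv(ws / "summary.csv", index=False)
    log.info("summarize: %d cell rows", len(summary))


def _stage_stats(cfg: RunConfig, ws: Path) -> None:
    summary = pd.read_csv(ws / "summary.csv")
    table = aggregate(summary, "peak_amp")
    arms = [a.name for a in _arm_specs(cfg)]
    results = {"metric": "peak_amp", "alpha": cfg.alpha, "comparisons": []}
    for other in arms[1:]:
        res = paired_t_log(table, arms[0], other)
        results["comparisons"].append({
            "conditions": [arms[0], other],
            "t": res.statistic, "df": res.df, "p": res.p_value,
            "significant": bool(res.p_value < cfg.alpha),
            "geometric_means": res.geometric_means,
            "raw_means": res.raw_means, "sem": res.sem,
        })
    results["per_animal_means"] = table.animal_means.to_dict("records")
    with open(ws / "stats.json", "w") as fh:
        json.dump(results, fh, indent=2)
    log.info("stats: %d paired comparisons", len(results["comparisons"]))


def _stage_recover(cfg: RunConfig, ws: Path) -> None:
    cp = get_preset(cfg.preset)
    if cp.phases:
        out = patch_fractions(n_batches=cfg.recover_n_seeds, seed=cfg.seed,
                              noise=cfg.noise(), config=cfg.processing())
    else:
        report = recover_preset(cfg.preset, n_seeds=cfg.recover_n_seeds,
                                seed=cfg.seed, noise=cfg.noise(),
                                config=cfg.processing(), arms=cfg.arms)
        out = {
            "preset": report.preset_name,
            "n_seeds": report.n_seeds,
            "arms": {
                name: {"truth": a.truth_mean, "measured": a.grand_mean,
                       "mc_ci95": list(a.mc_ci95)}
                for name, a in report.arms.items()
            },
            "paired_tests": {
                f"{a} vs {b}": {k: (v.tolist() if isinstance(v, np.ndarray)
                                    else v) for k, v in res.items()}
                for (a, b), res in report.paired_tests.items()
            },
        }
        log.info("recover:\n%s", report.summary())
    with open(ws / "recovery.json", "w") as fh:
        json.dump(out, fh, indent=2)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "process": _stage_process,
    "summarize": _stage_summarize,
    "stats": _stage_stats,
    "recover": _stage_recover,
}


def run(config: RunConfig) -> int:
    """Execute the configured stages in canonical order.

    Returns 0 on success, 1 on configuration errors, 2 on data errors
    (missing or malformed inputs for a non-simulation stage).
    """
    try:
        config.validate()
    except (ValueError, KeyError) as exc:
        log.error("config error: %s", exc)
        return 1
    ws = Path(config.workspace)
    ws.mkdir(parents=True, exist_ok=True)
    config.to_yaml(ws / "config.yaml")
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("--- stage %s ---", stage)
        try:
            _STAGE_FUNCS[stage](config, ws)
        except FileNotFoundError as exc:
            log.error("stage %s: missing input: %s", stage, exc)
            return 2
        except (ValueError, KeyError) as exc:
            log.error("stage %s failed: %s", stage, exc)
            return 2
    return 0
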