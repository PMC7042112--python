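"""Parameter recovery: run the full pipeline on synthetic presets and
compare what it measures against the generator's encoded truth.

This is the package's validation backbone. Because no raw movies are
deposited for the experiments the presets encode, correctness is
demonstrated by recovery: simulate a condition at its published design
(animals, technical replicates, cells, record length), push the synthetic
data through extraction, F/F0 normalization, smoothing, peak detection and
hierarchical aggregation, and check that the grand mean of per-animal mean
peak amplitudes lands on the preset's encoded value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import (SPONTANEOUS_WINDOW, percent_active, spontaneous_activity,
                     summaries_to_frame, summarize_cell)
from .presets import ArmSpec, preset as get_preset
from .stats import ReplicateTable, aggregate, paired_t_log
from .synthetic import (ArmSimulation, NoiseModel, sample_roi_counts,
                        simulate_patch, simulate_traces)
from .traces import (DEFAULT_BASELINE_FRAMES, detect_peaks, estimate_noise_sd,
                     normalize_f_f0, savgol_smooth)

__all__ = [
    "ProcessingConfig",
    "process_recording",
    "measure_arm",
    "recover_preset",
    "patch_fractions",
    "RecoveryReport",
    "DEFAULT_ROI_PIXELS",
]

#: Nominal ROI size used by the distribution-exact fast render path: a
#: packed endothelial cell of ~10 x 40 um covers a few hundred 0.4-um
#: pixels once neighbour gaps are carved out.
DEFAULT_ROI_PIXELS = 400


@dataclass(frozen=True)
class ProcessingConfig:
    """Stage parameters of the trace-processing chain."""

    baseline_frames: int = DEFAULT_BASELINE_FRAMES
    sg_window: int = 21
    sg_polyorder: int = 3
    k_sigma: float = 3.0
    min_amplitude: float = 0.05
    response_window_frames: int | None = None  # None: to end of record


def process_recording(raw_traces: np.ndarray, frame_rate_hz: float,
                      stim_frame: int,
                      config: ProcessingConfig = ProcessingConfig(),
                      cell_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Raw per-cell traces -> per-cell event summaries (one recording).

    Each trace is F/F0-normalized, smoothed, peak-detected, summarized over
    the response window, and flagged for spontaneous baseline activity when
    the record covers the baseline window.
    """
    raw_traces = np.atleast_2d(np.asarray(raw_traces, dtype=float))
    n_cells, T = raw_traces.shape
    if cell_ids is None:
        cell_ids = np.arange(1, n_cells + 1)

    summaries = []
    for i in range(n_cells):
        ff0 = normalize_f_f0(raw_traces[i], config.baseline_frames,
                             frame_rate_hz)
        smoothed = savgol_smooth(ff0.values, config.sg_window,
                                 config.sg_polyorder)
        noise_sd = estimate_noise_sd(ff0, config.sg_window,
                                     config.sg_polyorder)
        peaks = detect_peaks(smoothed, frame_rate_hz, noise_sd,
                             config.k_sigma, config.min_amplitude)
        s = summarize_cell(ff0, peaks, stim_frame,
                           config.response_window_frames, smoothed=smoothed,
                           noise_sd=noise_sd, k_sigma=config.k_sigma,
                           min_amplitude=config.min_amplitude,
                           cell_id=int(cell_ids[i]))
        if T >= SPONTANEOUS_WINDOW[1]:
            s.spont_active = spontaneous_activity(ff0, peaks)
        summaries.append(s)
    return summaries_to_frame(summaries)


def measure_arm(arm: ArmSpec, seed: int,
                noise: NoiseModel | None = None,
                config: ProcessingConfig = ProcessingConfig(),
                animal_z: np.ndarray | None = None,
                roi_pixels: int = DEFAULT_ROI_PIXELS,
                sim: ArmSimulation | None = None) -> pd.DataFrame:
    """Simulate one arm and measure it with the full pipeline.

    Returns the per-cell summary table (columns: cell metrics plus animal,
    tech_rep, condition). The imaging step uses the distribution-exact
    ROI-mean sampler; pass a prebuilt ``sim`` to reuse a simulation.
    """
    noise = noise or NoiseModel()
    if sim is None:
        sim = simulate_traces(arm, seed=seed, animal_z=animal_z)
    n_pixels = np.full(sim.recordings[0].traces.shape[0], roi_pixels)

    ss = np.random.SeedSequence(entropy=seed, spawn_key=(101,))
    rec_rngs = [np.random.default_rng(s)
                for s in ss.spawn(len(sim.recordings))]

    frames = []
    for rec, rng in zip(sim.recordings, rec_rngs):
        raw = sample_roi_counts(rec.traces, n_pixels, noise, rng)
        df = process_recording(raw, arm.frame_rate_hz, arm.stim_frame, config)
        df["animal"] = rec.animal
        df["tech_rep"] = rec.tech_rep
        df["condition"] = arm.name
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass
class ArmRecovery:
    name: str
    truth_mean: float
    per_seed_grand_means: np.ndarray
    per_seed_truth_means: np.ndarray

    @property
    def grand_mean(self) -> float:
        return float(self.per_seed_grand_means.mean())

    @property
    def mc_sem(self) -> float:
        n = self.per_seed_grand_means.size
        return float(self.per_seed_grand_means.std(ddof=1) / np.sqrt(n))

    @property
    def mc_ci95(self) -> tuple[float, float]:
        m, s = self.grand_mean, self.mc_sem
        return (m - 1.96 * s, m + 1.96 * s)


@dataclass
class RecoveryReport:
    preset_name: str
    n_seeds: int
    arms: dict[str, ArmRecovery] = field(default_factory=dict)
    #: (arm_a, arm_b) -> fraction of seed batches with p < 0.05, mean p
    paired_tests: dict[tuple[str, str], dict] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"recovery report: {self.preset_name} "
                 f"({self.n_seeds} seed batches)"]
        for a in self.arms.values():
            lo, hi = a.mc_ci95
            lines.append(
                f"  {a.name:<24s} truth {a.truth_mean:7.3f}  "
                f"measured {a.grand_mean:7.3f}  95% CI [{lo:.3f}, {hi:.3f}]")
        for (x, y), res in self.paired_tests.items():
            lines.append(
                f"  paired t {x} vs {y}: significant in "
                f"{100 * res['fraction_significant']:.0f}% of batches "
                f"(mean p = {res['mean_p']:.3f})")
        return "\n".join(lines)


def recover_preset(name: str, n_seeds: int = 20, seed: int = 0,
                   noise: NoiseModel | None = None,
                   config: ProcessingConfig = ProcessingConfig(),
                   metric: str = "peak_amp",
                   arms: list[str] | None = None,
                   run_tests: bool = True) -> RecoveryReport:
    """Run generation -> extraction -> processing -> aggregation for each
    arm of a preset over ``n_seeds`` master seeds and report, per arm, the
    grand mean of per-animal means with its Monte-Carlo CI, plus paired
    test verdicts between the first arm and each later arm.

    Animal effects are shared across arms within a seed batch (the same
    animals are measured before and after treatment), so the paired tests
    see the pairing the experimental design implies.
    """
    cp = get_preset(name)
    if not cp.arms:
        raise ValueError(f"preset {name!r} has no amplitude arms; "
                         "use patch_fractions for the patch protocol")
    arm_specs = [cp.arm(a) for a in arms] if arms else list(cp.arms)

    per_arm_means = {a.name: [] for a in arm_specs}
    per_arm_truth = {a.name: [] for a in arm_specs}
    test_p: dict[tuple[str, str], list[float]] = {
        (arm_specs[0].name, a.name): [] for a in arm_specs[1:]
    } if run_tests and len(arm_specs) > 1 else {}

    master = np.random.SeedSequence(seed)
    batch_seeds = master.generate_state(n_seeds, dtype=np.uint32) % (2 ** 31)

    for b, bseed in enumerate(batch_seeds):
        bseed = int(bseed)
        z_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=bseed, spawn_key=(7,)))
        z = z_rng.standard_normal(arm_specs[0].n_animals)

        tables: dict[str, ReplicateTable] = {}
        for k, arm in enumerate(arm_specs):
            arm_seed = bseed * 13 + k
            sim = simulate_traces(arm, seed=arm_seed,
                                  animal_z=z[: arm.n_animals])
            cells = measure_arm(arm, seed=arm_seed, noise=noise,
                                config=config, sim=sim)
            table = aggregate(cells, metric)
            tables[arm.name] = table
            per_arm_means[arm.name].append(
                float(table.animal_means[metric].mean()))
            per_arm_truth[arm.name].append(
                float(sim.ground_truth.per_animal_mean.mean()))

        for (a_name, b_name) in test_p:
            merged = ReplicateTable(
                metric=metric,
                tech_rep_means=pd.concat(
                    [tables[a_name].tech_rep_means,
                     tables[b_name].tech_rep_means], ignore_index=True),
                animal_means=pd.concat(
                    [tables[a_name].animal_means,
                     tables[b_name].animal_means], ignore_index=True),
            )
            try:
                res = paired_t_log(merged, a_name, b_name)
                test_p[(a_name, b_name)].append(res.p_value)
            except ValueError:
                test_p[(a_name, b_name)].append(np.nan)

    report = RecoveryReport(preset_name=name, n_seeds=n_seeds)
    for arm in arm_specs:
        report.arms[arm.name] = ArmRecovery(
            name=arm.name,
            truth_mean=arm.mean_peak_amp,
            per_seed_grand_means=np.asarray(per_arm_means[arm.name]),
            per_seed_truth_means=np.asarray(per_arm_truth[arm.name]),
        )
    for key, ps in test_p.items():
        ps_arr = np.asarray(ps, dtype=float)
        ok = np.isfinite(ps_arr)
        report.paired_tests[key] = {
            "fraction_significant": float((ps_arr[ok] < 0.05).mean())
            if ok.any() else np.nan,
            "mean_p": float(ps_arr[ok].mean()) if ok.any() else np.nan,
            "p_values": ps_arr,
        }
    return report


def patch_fractions(n_batches: int = 5, seed: int = 0,
                    noise: NoiseModel | None = None,
                    config: ProcessingConfig | None = None,
                    roi_pixels: int = DEFAULT_ROI_PIXELS) -> dict[str, float]:
    """Measure the activity fractions of the sequential patch protocol.

    For each seed batch, simulate the patch preset, run peak detection, and
    apply the any-activity rule per phase window. Returns the mean
    percentage of active cells per phase across batches and patches, keyed
    ``ach_responder_pct``, ``caffeine_active_pct``, ``baseline_spont_pct``.
    """
    noise = noise or NoiseModel()
    cp = get_preset("patch_ach_caffeine")
    config = config or ProcessingConfig()

    percents: dict[str, list[float]] = {ph.name: [] for ph in cp.phases}
    master = np.random.SeedSequence(seed)
    batch_seeds = master.generate_state(n_batches, dtype=np.uint32) % (2 ** 31)

    for bseed in batch_seeds:
        sim = simulate_patch(cp, seed=int(bseed))
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(bseed), spawn_key=(11,)))
        for rec in sim.recordings:
            n_pixels = np.full(rec.traces.shape[0], roi_pixels)
            raw = sample_roi_counts(rec.traces, n_pixels, noise, rng)
            flags: dict[str, list[bool]] = {ph.name: [] for ph in cp.phases}
            for trace in raw:
                ff0 = normalize_f_f0(trace, config.baseline_frames,
                                     sim.frame_rate_hz)
                smoothed = savgol_smooth(ff0.values, config.sg_window,
                                         config.sg_polyorder)
                noise_sd = estimate_noise_sd(ff0, config.sg_window,
                                             config.sg_polyorder)
                peaks = detect_peaks(smoothed, sim.frame_rate_hz, noise_sd,
                                     config.k_sigma, config.min_amplitude)
                for ph_name, (w0, w1) in sim.windows.items():
                    flags[ph_name].append(
                        any(w0 <= p.frame < w1 for p in peaks))
            for ph_name in flags:
                percents[ph_name].append(percent_active(flags[ph_name]))

    return {
        "ach_responder_pct": float(np.mean(percents["ach"])),
        "caffeine_active_pct": float(np.mean(percents["caffeine"])),
        "baseline_spont_pct": float(np.mean(percents["baseline"])),
    }
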