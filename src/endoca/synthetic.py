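"""Synthetic en-face endothelium: cell fields, Ca2+ traces, and movies.

The generator emulates the imaging experiments the analysis pipeline was
designed for: a confluent field of elongated endothelial cells imaged at
10 frames/s, responding to either localized flash photolysis of caged IP3
(a ~70 um disc, stimulus at 15 s of a 1,000-frame record) or ACh perfusion
(2,000-frame records), with baseline spontaneous transients, oscillatory
activity after the initial response, photon (shot) noise, camera read noise
and slow photobleaching.

Ground truth is hierarchical, mirroring the experimental design: an
animal-level mean peak amplitude is drawn from the condition mean with a
between-animal SD, each cell's amplitude is drawn log-normally about its
animal's mean, and every recording (technical replicate) redraws cell
amplitudes. The per-animal true mean is the average amplitude of that
animal's responding cells, which is exactly the quantity the analysis
pipeline estimates — so the generator doubles as a parameter-recovery oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import CellMap, Movie
from .presets import ArmSpec, ConditionPreset

__all__ = [
    "generate_cell_map",
    "transient_kernel",
    "apex_offset_s",
    "simulate_traces",
    "simulate_patch",
    "render_movie",
    "sample_roi_counts",
    "NoiseModel",
    "Recording",
    "GroundTruth",
    "ArmSimulation",
    "PatchSimulation",
]

# Endothelial cells in en-face artery preparations are spindle shaped,
# roughly 10 um across and 40 um long, aligned with flow.
CELL_LENGTH_UM = 40.0
CELL_WIDTH_UM = 10.0

#: F/F0 assigned to background (non-cell) pixels when rendering.
BACKGROUND_FF0 = 0.1

#: Minimum gap between successive oscillation transients in one cell (s).
#: Successive store-release events cannot ride on top of each other within
#: the indicator decay, so the oscillation train is a renewal process with
#: exponential waiting plus this refractory period; the exponential rate is
#: adjusted so the mean event rate still equals ``oscillation_rate_hz``.
OSC_REFRACTORY_S = 2.5

#: Mean/SD of spontaneous (non-stimulus) transient amplitudes, dF/F0.
SPONT_AMP_MEAN = 0.35
SPONT_AMP_SD = 0.12

#: Oscillation transients scale with the cell's primary response.
OSC_AMP_FRACTION = 0.4
OSC_AMP_LOGSD = 0.25


# --------------------------------------------------------------------------
# cell fields


def generate_cell_map(height: int, width: int, n_cells: int,
                      pixel_size_um: float = 0.4, seed: int = 0) -> CellMap:
    """Generate a field of disjoint, elongated cell regions.

    Cells are seeded on a jittered grid and grown as anisotropic
    nearest-seed regions clipped to an ellipse of roughly 40 x 10 um
    (long axis along x), with a thin background gap between neighbours.
    Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        If ``n_cells`` cells of >= 20 pixels cannot be placed in the field
        (an over-dense request), after bounded retries.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if height < 8 or width < 8:
        raise ValueError("field too small")

    a = CELL_LENGTH_UM / 2.0 / pixel_size_um   # semi-axis along x, px
    b = CELL_WIDTH_UM / 2.0 / pixel_size_um    # semi-axis along y, px

    # grid shape proportioned to the cell aspect ratio
    r = (width * b) / (height * a)
    nx = max(1, math.ceil(math.sqrt(n_cells * r)))
    ny = max(1, math.ceil(n_cells / nx))
    while nx * ny < n_cells:
        nx += 1

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width].astype(float)

    for _ in range(10):
        gx = (np.arange(nx) + 0.5) * width / nx
        gy = (np.arange(ny) + 0.5) * height / ny
        centers = np.array([(x, y) for y in gy for x in gx])
        take = rng.choice(len(centers), size=n_cells, replace=False)
        centers = centers[take]
        centers[:, 0] += rng.uniform(-0.25, 0.25, n_cells) * width / nx
        centers[:, 1] += rng.uniform(-0.25, 0.25, n_cells) * height / ny

        # running top-2 anisotropic distances to keep memory flat
        d1 = np.full((height, width), np.inf)
        d2 = np.full((height, width), np.inf)
        owner = np.zeros((height, width), dtype=np.int32)
        for i, (cx, cy) in enumerate(centers):
            d = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
            closer = d < d1
            d2 = np.where(closer, d1, np.minimum(d2, d))
            owner = np.where(closer, i + 1, owner)
            d1 = np.where(closer, d, d1)

        gap = 1.5 / b  # ~1.5 px separation along the short axis
        labels = np.where((d1 <= 1.0) & (d2 - d1 >= gap), owner, 0)
        labels = _clean_regions(labels, n_cells)
        if labels is not None:
            return CellMap(labels=labels.astype(np.int32),
                           pixel_size_um=pixel_size_um)

    raise ValueError(
        f"could not place {n_cells} disjoint cells of >= 20 px in a "
        f"{height}x{width} field: request is over-dense"
    )


def _clean_regions(labels: np.ndarray, n_cells: int) -> np.ndarray | None:
    """Keep the largest 4-connected component of each cell; reject the field
    if any cell ends up below 20 pixels."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    out = np.zeros_like(labels)
    for i in range(1, n_cells + 1):
        mask = labels == i
        comp, n_comp = ndimage.label(mask, structure=structure)
        if n_comp == 0:
            return None
        if n_comp > 1:
            sizes = np.bincount(comp.ravel())[1:]
            mask = comp == (int(np.argmax(sizes)) + 1)
        if mask.sum() < 20:
            return None
        out[mask] = i
    return out


# --------------------------------------------------------------------------
# transient shape


def apex_offset_s(rise_tau_s: float, decay_tau_s: float) -> float:
    """Time from transient onset to its apex (closed form for the
    difference-of-exponentials shape)."""
    r, d = rise_tau_s, decay_tau_s
    return r * d / (d - r) * math.log(d / r)


def transient_kernel(t, t0: float, amplitude: float,
                     rise_tau_s: float = 0.3, decay_tau_s: float = 3.0):
    """Difference-of-exponentials Ca2+ transient, peak-normalized.

    Zero before ``t0``; rises with ``rise_tau_s``, decays with
    ``decay_tau_s``; internally renormalized so the continuous-time maximum
    equals ``amplitude`` exactly.
    """
    if not (0 < rise_tau_s < decay_tau_s):
        raise ValueError("need decay_tau_s > rise_tau_s > 0")
    t = np.asarray(t, dtype=float)
    dt = t - t0
    shape = np.where(
        dt >= 0,
        np.exp(-np.maximum(dt, 0.0) / decay_tau_s)
        - np.exp(-np.maximum(dt, 0.0) / rise_tau_s),
        0.0,
    )
    tp = apex_offset_s(rise_tau_s, decay_tau_s)
    peak = math.exp(-tp / decay_tau_s) - math.exp(-tp / rise_tau_s)
    return amplitude * shape / peak


# --------------------------------------------------------------------------
# hierarchical trace simulation


@dataclass
class Recording:
    animal: int
    tech_rep: int
    traces: np.ndarray  # (n_cells, T), noise-free F/F0


@dataclass
class GroundTruth:
    """True events and flags behind an arm simulation.

    ``events`` has one row per planted transient: animal, tech_rep, cell_id,
    frame (apex), time_s, amplitude, kind (stimulus/oscillation/spontaneous).
    ``per_animal_mean[a]`` is the average true amplitude of animal a's
    responding cells' stimulus-locked transients across its recordings.
    """

    events: pd.DataFrame
    responders: np.ndarray          # (n_animals, n_cells) bool
    spontaneous: np.ndarray         # (n_animals, n_reps, n_cells) bool
    animal_level_mean: np.ndarray   # (n_animals,) underlying draw
    per_animal_mean: np.ndarray     # (n_animals,) mean of responding cells
    seed: int = 0


@dataclass
class ArmSimulation:
    arm: ArmSpec
    recordings: list[Recording]
    ground_truth: GroundTruth

    def recording(self, animal: int, tech_rep: int) -> Recording:
        for rec in self.recordings:
            if rec.animal == animal and rec.tech_rep == tech_rep:
                return rec
        raise KeyError((animal, tech_rep))


def _add_transient(trace: np.ndarray, rate: float, t0: float, amp: float,
                   rise: float, decay: float) -> None:
    """Add a transient in place, evaluating the kernel only on its support
    (12 decay constants; the truncated tail is < 1e-5 of the amplitude)."""
    T = trace.size
    i0 = max(0, int(math.floor(t0 * rate)))
    i1 = min(T, i0 + int(12 * decay * rate) + 2)
    if i0 >= T:
        return
    t_local = np.arange(i0, i1) / rate
    trace[i0:i1] += transient_kernel(t_local, t0, amp, rise, decay)


def _lognormal(rng, mean: float, sd: float, size) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean and SD."""
    if sd <= 0:
        return np.full(size, mean)
    var = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - var / 2.0
    return rng.lognormal(mu, math.sqrt(var), size)


def _oscillation_times(rng, t_start: float, t_end: float,
                       rate_hz: float) -> np.ndarray:
    """Renewal train with mean rate ``rate_hz`` and a refractory gap."""
    if rate_hz <= 0 or t_end <= t_start:
        return np.empty(0)
    mean_gap = 1.0 / rate_hz
    if mean_gap <= OSC_REFRACTORY_S:
        exp_rate = 1.0 / (0.1 * mean_gap)  # refractory-dominated regime
    else:
        exp_rate = 1.0 / (mean_gap - OSC_REFRACTORY_S)
    times = []
    t = t_start
    while True:
        t = t + OSC_REFRACTORY_S + rng.exponential(1.0 / exp_rate)
        if t >= t_end:
            break
        times.append(t)
    return np.asarray(times)


def _truncated_animal_mean(rng, mean: float, sd: float, z: float) -> float:
    """Animal-level mean: normal(mean, sd) truncated to > 0. The shared
    deviate ``z`` preserves animal pairing across arms; it is redrawn from
    the animal's own stream only if the value falls at or below zero."""
    m = mean + z * sd
    while m <= 0:
        m = mean + rng.standard_normal() * sd
    return m


def simulate_traces(arm: ArmSpec,
                    cell_map: CellMap | None = None,
                    frame_rate_hz: float | None = None,
                    n_frames: int | None = None,
                    seed: int = 0,
                    animal_z: np.ndarray | None = None) -> ArmSimulation:
    """Simulate noise-free per-cell F/F0 traces for every recording of one
    condition arm (``n_animals`` x ``n_tech_reps``), plus ground truth.

    Responding cells carry a stimulus-locked transient whose amplitude is
    drawn hierarchically (animal, then cell, truncated positive), followed
    by an oscillation train; non-responders — and every cell of a
    ``stimulus='none'`` arm — carry only spontaneous baseline events for the
    spontaneous fraction of cells. The noise-free baseline is exactly 1.

    ``animal_z`` optionally supplies the per-animal standard-normal deviates
    so that paired arms of one preset share animal effects.
    """
    n_cells = cell_map.n_cells if cell_map is not None else arm.n_cells
    rate = frame_rate_hz if frame_rate_hz is not None else arm.frame_rate_hz
    T = n_frames if n_frames is not None else arm.n_frames
    if arm.stimulus != "none" and arm.stim_frame >= T:
        raise ValueError("stim_frame must precede the end of the record")

    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    animal_seeds = ss.spawn(arm.n_animals)

    if animal_z is None:
        animal_z = master.standard_normal(arm.n_animals)
    animal_z = np.asarray(animal_z, dtype=float)
    if animal_z.shape != (arm.n_animals,):
        raise ValueError("animal_z must have one deviate per animal")

    t_grid = np.arange(T) / rate
    apex = apex_offset_s(arm.rise_tau_s, arm.decay_tau_s)
    spont_window_end = min(arm.stim_frame, 150) if arm.stimulus != "none" else T - 20
    stimulated = arm.stimulus != "none"

    recordings: list[Recording] = []
    event_rows: list[tuple] = []
    responders = np.zeros((arm.n_animals, n_cells), dtype=bool)
    spontaneous = np.zeros((arm.n_animals, arm.n_tech_reps, n_cells), dtype=bool)
    animal_level = np.zeros(arm.n_animals)
    stim_amp_sums = np.zeros(arm.n_animals)
    stim_amp_counts = np.zeros(arm.n_animals)

    for a in range(arm.n_animals):
        a_rng = np.random.default_rng(animal_seeds[a])
        m_a = _truncated_animal_mean(a_rng, arm.mean_peak_amp,
                                     arm.between_animal_sd, animal_z[a])
        animal_level[a] = m_a
        responders[a] = a_rng.random(n_cells) < arm.responder_fraction

        for r in range(arm.n_tech_reps):
            rec_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=animal_seeds[a].entropy,
                                       spawn_key=(a, r, 7)))
            traces = np.ones((n_cells, T))
            spontaneous[a, r] = rec_rng.random(n_cells) < arm.spontaneous_fraction

            for c in range(n_cells):
                events: list[tuple[float, float, str]] = []  # (t0_s, amp, kind)

                if stimulated and responders[a, c]:
                    amp = float(_lognormal(rec_rng, m_a,
                                           arm.between_cell_sd, ()))
                    latency = rec_rng.uniform(0.0, 0.5)
                    t0 = arm.stim_frame / rate + latency
                    events.append((t0, amp, "stimulus"))
                    stim_amp_sums[a] += amp
                    stim_amp_counts[a] += 1
                    # oscillation train after the primary transient
                    osc_t = _oscillation_times(
                        rec_rng, t0 + apex + 1.5, t_grid[-1] - 1.0,
                        arm.oscillation_rate_hz)
                    for to in osc_t:
                        oamp = (OSC_AMP_FRACTION * amp
                                * rec_rng.lognormal(-OSC_AMP_LOGSD ** 2 / 2,
                                                    OSC_AMP_LOGSD))
                        events.append((to, oamp, "oscillation"))

                if spontaneous[a, r, c] and spont_window_end > 30:
                    n_ev = 1 + rec_rng.poisson(0.3)
                    for _ in range(n_ev):
                        ts = rec_rng.uniform(0.5, (spont_window_end - 10) / rate)
                        amp_s = float(np.clip(
                            rec_rng.normal(SPONT_AMP_MEAN, SPONT_AMP_SD),
                            0.12, None))
                        events.append((ts, amp_s, "spontaneous"))

                for t0, amp, kind in events:
                    _add_transient(traces[c], rate, t0, amp,
                                   arm.rise_tau_s, arm.decay_tau_s)
                    apex_frame = int(round((t0 + apex) * rate))
                    event_rows.append((a, r, c + 1, apex_frame,
                                       t0 + apex, amp, kind))

            recordings.append(Recording(animal=a, tech_rep=r, traces=traces))

    events_df = pd.DataFrame(
        event_rows,
        columns=["animal", "tech_rep", "cell_id", "frame", "time_s",
                 "amplitude", "kind"],
    )
    with np.errstate(invalid="ignore"):
        per_animal = np.where(stim_amp_counts > 0,
                              stim_amp_sums / np.maximum(stim_amp_counts, 1),
                              0.0)
    gt = GroundTruth(events=events_df, responders=responders,
                     spontaneous=spontaneous, animal_level_mean=animal_level,
                     per_animal_mean=per_animal, seed=seed)
    return ArmSimulation(arm=arm, recordings=recordings, ground_truth=gt)


# --------------------------------------------------------------------------
# sequential patch protocol


@dataclass
class PatchSimulation:
    preset: ConditionPreset
    recordings: list[Recording]          # one per patch/animal
    windows: dict[str, tuple[int, int]]  # phase name -> [start, end)
    active: dict[str, np.ndarray]        # phase name -> (n_animals, n_cells)
    frame_rate_hz: float
    seed: int


def simulate_patch(preset: ConditionPreset, seed: int = 0) -> PatchSimulation:
    """Simulate the sequential perfusion protocol on isolated endothelial
    patches: consecutive phases (baseline, agonist, caffeine) recorded on
    the same cells, with a preset fraction of cells active in each phase.

    Cells flagged active in a phase carry at least one transient with its
    apex inside that phase's window; phase-1 events are kept clear of the
    first 100 frames so the F0 estimate stays clean.
    """
    if not preset.phases:
        raise ValueError(f"preset {preset.name!r} has no phase protocol")
    rate = preset.frame_rate_hz
    n_cells = preset.n_cells
    rise, decay = 0.3, 3.0
    apex = apex_offset_s(rise, decay)

    windows: dict[str, tuple[int, int]] = {}
    start = 0
    for ph in preset.phases:
        windows[ph.name] = (start, start + ph.n_frames)
        start += ph.n_frames
    T = start

    ss = np.random.SeedSequence(seed)
    patch_seeds = ss.spawn(preset.n_animals)

    recordings: list[Recording] = []
    active = {ph.name: np.zeros((preset.n_animals, n_cells), dtype=bool)
              for ph in preset.phases}

    for a in range(preset.n_animals):
        rng = np.random.default_rng(patch_seeds[a])
        traces = np.ones((n_cells, T))
        for i_ph, ph in enumerate(preset.phases):
            w0, w1 = windows[ph.name]
            flags = rng.random(n_cells) < ph.active_fraction
            active[ph.name][a] = flags
            # keep phase-1 events off the F0 window; elsewhere a margin
            # keeps apexes inside the phase
            lo = w0 + (110 if i_ph == 0 else 20)
            hi = w1 - 40
            for c in np.nonzero(flags)[0]:
                if ph.stimulated:
                    amp = float(_lognormal(rng, ph.mean_amp,
                                           0.3 * ph.mean_amp, ()))
                    t0 = (w0 + rng.uniform(5, 15)) / rate
                    _add_transient(traces[c], rate, t0, amp, rise, decay)
                    for to in _oscillation_times(rng, t0 + apex + 1.5,
                                                 (w1 - 30) / rate, 0.15):
                        oamp = OSC_AMP_FRACTION * amp * rng.lognormal(
                            -OSC_AMP_LOGSD ** 2 / 2, OSC_AMP_LOGSD)
                        _add_transient(traces[c], rate, to, oamp, rise, decay)
                else:
                    n_ev = 1 + rng.poisson(0.5)
                    for _ in range(n_ev):
                        ts = rng.uniform(lo, hi) / rate
                        amp_s = float(np.clip(
                            rng.normal(SPONT_AMP_MEAN, SPONT_AMP_SD),
                            0.12, None))
                        _add_transient(traces[c], rate, ts, amp_s,
                                       rise, decay)
        recordings.append(Recording(animal=a, tech_rep=0, traces=traces))

    return PatchSimulation(preset=preset, recordings=recordings,
                           windows=windows, active=active,
                           frame_rate_hz=rate, seed=seed)


# --------------------------------------------------------------------------
# forward imaging model


@dataclass(frozen=True)
class NoiseModel:
    """Camera/photon model used when turning F/F0 into pixel counts.

    ``baseline_counts`` is the mean photon count per pixel at F/F0 = 1;
    read noise is additive Gaussian in counts; bleaching multiplies the
    signal by (1 - rate) each frame, producing the slow downward drift seen
    in long fluorescence records. Bleaching is off by default: the presets
    encode published summary values, which already absorb whatever drift
    the original recordings carried, so the calibrated recovery path must
    not degrade the signal twice. Set a positive rate to study how
    uncorrected drift biases amplitude estimates.
    """

    baseline_counts: float = 200.0
    read_noise_sd: float = 3.0
    bleach_rate_per_frame: float = 0.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.baseline_counts <= 0:
            raise ValueError("baseline_counts must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if not 0 <= self.bleach_rate_per_frame < 1:
            raise ValueError("bleach rate must be in [0, 1)")


def render_movie(traces: np.ndarray, cell_map: CellMap,
                 baseline_counts: float = 200.0,
                 read_noise_sd: float = 3.0,
                 bleach_rate_per_frame: float = 0.0,
                 seed: int = 0,
                 background_ff0: float = BACKGROUND_FF0,
                 frame_rate_hz: float = 10.0,
                 shot_noise: bool = True) -> Movie:
    """Render per-cell F/F0 traces into a noisy movie.

    Pixel value = Poisson(baseline_counts * F/F0 * (1 - bleach)^frame)
    + Gaussian read noise, clipped at 0. Background pixels carry a dim
    constant F/F0. With ``shot_noise=False`` and zero read noise the movie
    is the exact expectation (the zero-noise render used for round-trip
    checks). Deterministic for a fixed seed.
    """
    noise = NoiseModel(baseline_counts, read_noise_sd,
                       bleach_rate_per_frame, shot_noise)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_cells, T = traces.shape
    if cell_map.n_cells > n_cells:
        raise ValueError("cell map contains IDs without traces")
    labels = cell_map.labels
    rng = np.random.default_rng(seed)

    idx = np.clip(labels - 1, 0, None)
    in_cell = labels > 0
    frames = np.empty((T,) + labels.shape, dtype=np.float32)
    decay = 1.0
    for t in range(T):
        ff0 = np.where(in_cell, traces[idx, t], background_ff0)
        lam = noise.baseline_counts * ff0 * decay
        if noise.shot_noise:
            frame = rng.poisson(lam).astype(np.float64)
        else:
            frame = lam
        if noise.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, noise.read_noise_sd, lam.shape)
        frames[t] = np.clip(frame, 0.0, None)
        decay *= 1.0 - noise.bleach_rate_per_frame

    return Movie(frames=frames, frame_rate_hz=frame_rate_hz,
                 pixel_size_um=cell_map.pixel_size_um)


def sample_roi_counts(traces: np.ndarray, n_pixels: np.ndarray,
                      noise: NoiseModel | None = None,
                      seed_or_rng=0) -> np.ndarray:
    """Draw the per-cell ROI-mean raw trace directly, in count units.

    The ROI mean of ``render_movie`` followed by pixel averaging is, in
    distribution, Poisson(n_px * lambda) / n_px plus Gaussian read noise of
    SD ``read_noise_sd / sqrt(n_px)`` (a sum of independent Poisson pixels
    is Poisson). Sampling that statistic directly is exact and avoids
    materializing full frames, which is what makes many-seed parameter
    recovery cheap.
    """
    noise = noise or NoiseModel()
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_pixels = np.asarray(n_pixels, dtype=float).reshape(-1, 1)
    if n_pixels.shape[0] != traces.shape[0]:
        raise ValueError("need a pixel count per cell")
    T = traces.shape[1]
    decay = (1.0 - noise.bleach_rate_per_frame) ** np.arange(T)
    lam = noise.baseline_counts * traces * decay
    if noise.shot_noise:
        out = rng.poisson(lam * n_pixels) / n_pixels
    else:
        out = lam.copy()
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd / np.sqrt(n_pixels),
                               out.shape)
    return np.clip(out, 0.0, None)
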