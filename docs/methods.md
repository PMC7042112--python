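# Methods

This note documents the models, parameter choices and numerical decisions
behind `endoca`, and what its validation does and does not establish.

## What the pipeline computes

A recording is a T×H×W fluorescence movie plus an integer cell-label map.
For each cell the pipeline computes the ROI-mean trace, normalizes it by
the mean of the first `baseline_frames` (default 100) frames, smooths with
a Savitzky–Golay filter (window 21, order 3, mirror-padded edges), and
detects Ca²⁺ events as positive→negative zero crossings of the smoothed
trace's derivative. A candidate apex is retained when its amplitude —
smoothed F/F₀ minus 1 — reaches `max(k_sigma·σ, min_amplitude)` with
defaults k_sigma = 3 and min_amplitude = 0.05 ΔF/F₀; σ is 1.4826 × the MAD
of (raw − smoothed) F/F₀ over the baseline window. Per-cell metrics over a
response window (default: stimulus frame to end of record) are: peak
amplitude (max smoothed F/F₀ − 1 when ≥ 1 retained peak lies in the
window, else 0), peak count, mean F/F₀, duration (first to last crossing
of the detection threshold), a responder flag (≥ 1 peak in the window) and
a spontaneous-activity flag (≥ 1 retained peak in frames [0, 150)).

**Derivative choice.** The derivative driving the zero-crossing detector
is the first difference of the smoothed trace. Its sign change is exactly
the local-maximum condition — including flat tops, which resolve to their
first frame — so the detector provably equals an exhaustive local-maximum
scan. A centred difference was considered and rejected: it skips the
sample itself and can miss genuine single-frame maxima or fire twice
around an asymmetric apex.

**Known measurement bias.** On the default transient shape sampled at
10 frames/s, the 21-point cubic filter *overshoots* the apex by ≈ +2%
(a cubic fit across an asymmetric peak). The pipeline reports the smoothed
peak as-is — no compensation — so recovered amplitudes sit ~2% above the
planted truths; the validation suite accounts for this characterized gain
explicitly rather than hiding it in loose tolerances.

## Statistics

Metrics climb the replication hierarchy by plain means: cells → technical
replicate (a repeat recording in the same preparation) → animal. Tests run
on per-animal means. Peak amplitudes are natural-log transformed; the
paired t statistic is mean(d)/(sd(d)/√n) on log differences with
df = n − 1 (identical arms give t = 0, p = 1 by convention); reported test
means are back-transformed, i.e. geometric means, with raw means ± SEM
alongside. The two-way ANOVA (statsmodels OLS, type-II sums of squares,
interaction included) and Tukey HSD over factor-combination cells operate
on the same log scale; the factor structure is caller-declared. Log base
is irrelevant to t and F statistics and to geometric means. A non-positive
per-animal mean is an error, not something to offset silently; an
`exclude_nonresponders` option drops inactive cells before aggregation.
α = 0.05 throughout.

## The synthetic generator

The generator emulates the experimental designs the pipeline targets, and
its presets *are* the study conditions: published condition means, printed
"±" values interpreted as SEM at the printed n (between-animal SD =
SEM·√n), published animal counts, triplicate technical replicates, record
lengths (1,000 frames for uncaging and the ryanodine panel, 2,000 for ACh
perfusion), stimulus frames (150 for uncaging = 15 s; 300 for the
ryanodine panel = 30 s; 200 for ACh, a design choice since perfusion onset
is not frame-locked in the protocol), and 30 cells for uncaging arms
versus 100 for agonist arms. Printed summary values are treated uniformly
as peak ΔF/F₀ above a baseline of 1, and the ryanodine-panel "arbitrary
fluorescence unit" values are read in the same units; both conventions are
single documented choices. The replicate-count conflict in the
cypermethrin comparison (body text n = 7 for IP₃, legend n = 5) follows
the body text.

Hierarchy: animal-level mean ~ Normal(mean, between-animal SD) truncated
positive (redrawn from the animal's own stream if ≤ 0); per-cell, per-
recording amplitudes log-normal with arithmetic mean equal to the animal
mean and SD = 0.30 × the condition mean (the per-cell scatter in this
preparation is wide; 30% CV is a single realistic choice). Log-normal at
the cell level matches the positivity of amplitudes and the log transform
the statistics apply. Responder and spontaneous flags are Bernoulli per
cell (responders fixed per animal; spontaneous redrawn per recording).

Transients are peak-normalized differences of exponentials, rise 0.3 s,
decay 3 s (no kinetics are published for this preparation; these values
make ~5-s-spaced oscillations resolvable at 10 fps). Oscillation trains
after the initial response are renewal processes — exponential waiting
plus a 2.5 s refractory period, with the exponential rate adjusted so the
mean rate equals `oscillation_rate_hz` (0.1 Hz uncaging, 0.2 Hz ACh).
The refractory period reflects store refilling between release events and
keeps successive transients resolvable rather than stacking into spurious
super-amplitude peaks. Spontaneous events (amplitude ~ Normal(0.35, 0.12)
clipped at 0.12 ΔF/F₀) occupy the pre-stimulus window. The sequential
patch protocol (baseline → ACh → caffeine on the same 100 cells) uses
60-s windows per phase with planted active fractions 0.48 / 0.96 / 0.16;
phase-1 events avoid the first 100 frames so F₀ stays clean.

Imaging model: pixel value = Poisson(baseline_counts · F/F₀ ·
(1 − bleach)^frame) + Gaussian read noise, clipped at 0; background pixels
carry a dim constant F/F₀ (0.1). Defaults: 200 photons/pixel at baseline,
read noise SD 3 counts, bleaching **off**. Bleaching is a supported,
tested feature, but the calibrated default is zero: the presets encode
*published* summary values, which already absorb whatever drift the
original recordings carried, so injecting additional uncorrected drift
into the calibration path would degrade the signal twice — a 10⁻⁴/frame
rate, for instance, lowers the running baseline ~2.5% by a frame-300
stimulus and subtracts a constant ~0.025 from every measured ΔF/F₀.
Setting a positive rate is the supported way to study exactly that bias.

**Fast imaging path.** The ROI mean of a rendered movie is, in
distribution, Poisson(n_px·λ)/n_px plus Gaussian read noise of SD
σ_read/√n_px (a sum of independent Poisson pixels is Poisson).
`sample_roi_counts` samples that statistic directly; recovery runs use it
with a nominal 400-pixel ROI so many-seed validation is cheap, and a test
verifies its agreement with the full render → extract route. The
zero-noise round-trip check uses the full render path.

All generation is a pure function of (preset, seed): a master seed spawns
per-animal streams and per-recording substreams; paired arms can share
per-animal standard-normal deviates so the same "animals" are measured
before and after treatment, which is what gives the paired t test its
power in recovery runs.

## Validation: what it shows and what it does not

Because no raw movies are deposited for the experiments the presets
encode, validation is by parameter recovery at the published designs:
grand means of per-animal mean peak ΔF/F₀ recovered within Monte-Carlo
error of the encoded values (after the characterized +2% filter gain),
activity fractions within binomial error, type-I error of the paired test
calibrated at the nominal 5% over 500 null batches, and the
null-effect preset yielding non-significant verdicts in most batches.
`scripts/acceptance.py` reports amplitude targets as grand means over
50 master seed batches — with n = 5 animals and between-animal SEMs up to
±0.25, a 20-batch mean still carries ~±8% Monte-Carlo error, and 50
batches tighten the same unbiased estimate to ~±3% — and the patch
fractions over 5 batches.

Passing these checks shows the pipeline measures, essentially without
bias, exactly the hierarchical quantities it claims to measure, under a
generator whose idealizations are explicit. It does **not** certify
performance on real movies with features the generator omits: tissue
motion and contraction, cell-shape irregularity and segmentation error,
focus drift, indicator saturation or photophysics, spatially correlated
background, or wave-like inter-cell propagation. Manual cross-session
cell registration is likewise out of scope (synthetic sessions share one
cell map; an ID-remap table is accepted for real data).

## Degenerate inputs and tie-breaks

Non-positive F₀, empty label maps, shape mismatches, discs entirely
outside the field, single-level ANOVA factors and empty response windows
raise errors rather than returning silent defaults. Plateau apexes report
their first frame. Cells with zero retained peaks contribute peak_amp = 0
and duration 0 and stay in per-cell tables. Over-dense cell-map requests
fail after bounded retries. Trace generation evaluates transient kernels
on a 12-decay-constant support (truncation < 10⁻⁵ of amplitude).

## Problem sizes

Unit tests run on scaled-down arms (2 animals × 1 replicate × ~5 cells,
a few hundred frames); acceptance-level recovery runs the full published
designs (up to 6 animals × 3 replicates × 100 cells × 2,000 frames) over
20 seed batches in the test suite and 50 in the acceptance script —
sizes chosen so the whole validation completes in minutes on one CPU
while keeping Monte-Carlo error well inside the comparison bands.
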