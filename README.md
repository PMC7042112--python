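# endoca

Single-cell Ca²⁺ imaging analysis for native (en-face) artery endothelium,
with a calibrated synthetic-data generator for end-to-end validation.

## The problem

Endothelial cells in intact arteries signal through intracellular Ca²⁺
release from the endoplasmic reticulum, mainly via IP₃ receptors. Typical
experiments image a Cal-520-loaded endothelial monolayer at 10 frames/s
(512×512 EMCCD), stimulate IP₃ receptors either by ACh perfusion or by
flash photolysis of caged IP₃ inside a ~70 µm disc, and compare paired
responses in the same preparation before and after a drug (FK506,
rapamycin, calcineurin inhibitors). Analysis reduces each movie to
per-cell F/F₀ traces, detects Ca²⁺ events, and climbs a replication
hierarchy — cells → triplicate recordings (technical replicates) →
animals (biological replicates) — before paired statistics.

No raw movies are publicly deposited for this kind of study, so the
package ships a synthetic-movie generator whose **condition presets encode
the published summary values as ground truth**. Every stage is then
validated by parameter recovery: simulate at the published design, run the
full pipeline, and check that it reads back what was planted.

## The method

Per cell, with raw ROI-mean trace F(t):

- **F/F₀**: divide by the mean of the first 100 frames (F₀),
- **smoothing**: 21-point, 3rd-order Savitzky–Golay filter,
- **event detection**: positive→negative zero crossings of the smoothed
  trace's derivative, retained when amplitude (smoothed F/F₀ − 1) ≥
  max(3σ_noise, 0.05), with σ_noise a robust (MAD) estimate of baseline
  noise,
- **metrics**: peak ΔF/F₀ in the response window, oscillation count,
  response duration (threshold-crossing envelope), mean F/F₀, responder
  flag (any activity in the window) and spontaneous-activity flag (any
  retained peak in the first 150 frames).

Cell metrics average to technical-replicate means, then to per-animal
means. Peak amplitudes are log-transformed for testing — paired Student's
t on log differences (t = mean(d)/(sd(d)/√n), df = n − 1) or two-way
ANOVA with Tukey's HSD — and means are back-transformed (geometric means),
with raw means ± SEM reported alongside. α = 0.05.

The generator is hierarchical: an animal-level mean peak amplitude ~
Normal(condition mean, between-animal SD) truncated positive (between-animal
SD = published SEM × √n), per-cell amplitudes log-normal about the animal
mean, redrawn per recording. Transients are peak-normalized
difference-of-exponentials (rise 0.3 s, decay 3 s); oscillation trains
follow the initial response; imaging applies Poisson photon noise,
Gaussian read noise and (optionally) photobleaching.

## Worked example

`examples/paired_statistics.py` measures both arms of the FK506/IP₃
uncaging comparison (5 animals × 3 technical replicates × 30 uncaged
cells, 1,000 frames at 10 fps; the same animals in both arms) and runs the
paired log-scale t test:

```
 control: per-animal means [1.27 1.19 1.41 1.61 1.73]
   fk506: per-animal means [1.5  1.31 1.77 2.13 2.41]
geometric means: control 1.43, FK506 1.78
paired t(4) = 5.34, p = 0.0059 -> significant at alpha = 0.05
```

The per-animal means scatter around the encoded condition means (1.41
control, 1.81 FK506); the paired test detects the planted potentiation.
`examples/recover_condition.py` does the same for the rapamycin preset,
which encodes a null effect (1.45 → 1.48) and correctly comes out
non-significant, and recovers the patch-protocol activity fractions
(planted 96/16/48%):

```
recovery report: ip3_rapamycin (8 seed batches)
  control       truth 1.450  measured 1.362  95% CI [1.261, 1.463]
  rapamycin     truth 1.480  measured 1.397  95% CI [1.317, 1.477]
  paired t control vs rapamycin: significant in 0% of batches (mean p = 0.293)
```

Other examples: `simulate_and_render.py` (movie synthesis + TIFF output),
`detect_events.py` (single-trace processing), `uncaging_mask_demo.py`
(photolysis-disc cell selection).

A thin CLI wraps the same pipeline for shell use:

```bash
endoca all --preset ip3_fk506 --workspace run1 --seed 1   # simulate→stats
endoca recover --preset ip3_rapamycin --n-seeds 8
```

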