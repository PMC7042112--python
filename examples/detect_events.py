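"""Process one noisy trace: F/F0, smoothing, peak detection, cell metrics.

Builds a raw fluorescence trace with two Ca2+ transients plus photon-scale
noise, runs the full trace-processing chain, and prints what the detector
and the per-cell summary report.
"""

import numpy as np

from endoca import (detect_peaks, estimate_noise_sd, normalize_f_f0,
                    savgol_smooth, summarize_cell, transient_kernel)

rng = np.random.default_rng(7)
t = np.arange(1000) / 10.0  # 100 s at 10 frames/s

# raw counts: baseline 200 photons, transients at 20 s (dF/F0 = 1.4)
# and 40 s (dF/F0 = 0.6), ~0.4% multiplicative noise
clean = 1.0 + transient_kernel(t, 20.0, 1.4) + transient_kernel(t, 40.0, 0.6)
raw = 200.0 * clean * (1 + rng.normal(0, 0.004, t.size))

ff0 = normalize_f_f0(raw, baseline_frames=100, frame_rate_hz=10.0)
smoothed = savgol_smooth(ff0.values)          # 21-point cubic
sigma = estimate_noise_sd(ff0)                # robust baseline noise SD
peaks = detect_peaks(smoothed, 10.0, sigma)   # threshold max(3*sigma, 0.05)

print(f"baseline noise SD: {sigma:.4f} F/F0 "
      f"-> amplitude threshold {max(3 * sigma, 0.05):.3f}")
for p in peaks:
    print(f"  peak at {p.time_s:5.1f} s  amplitude {p.amplitude:.3f} dF/F0")

summary = summarize_cell(ff0, peaks, stim_frame=150, smoothed=smoothed,
                         noise_sd=sigma)
print(f"cell summary: peak_amp {summary.peak_amp:.3f}, "
      f"n_peaks {summary.n_peaks}, duration {summary.duration_s:.1f} s, "
      f"responder {summary.responder}")
# Detected amplitudes sit ~2% above the planted 1.4 / 0.6: the 21-point
# cubic filter slightly overshoots this transient shape. Both peaks clear
# the noise threshold comfortably; the duration spans the time the
# smoothed trace stays above it.
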