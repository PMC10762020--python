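"""Steady mechanical-ventilation analog: constant 12 bpm.

Generates a two-minute synthetic ECG at heart rate 60 bpm whose QRS
amplitude is modulated 10% by breathing at a constant 12 bpm, with
additive noise at 2% of the R amplitude, runs the full estimator, and
reports the accuracy plus a paired TOST equivalence verdict.
"""
import numpy as np

from ecgresp import (
    EstimatorConfig, SyntheticConfig, align, estimate_rr, generate, tost_equivalence,
)

truth = generate(SyntheticConfig(
    fs=1000.0, duration=120.0, hr=60.0, hr_jitter_sd=0.01,
    rr=12.0, mod_depth=0.10, noise_sd=0.02, seed=1,
))
rr = estimate_rr(truth.record, EstimatorConfig(rr_band=(5.0, 40.0)))

err = np.abs(rr.rr_smoothed - 12.0)
print(f"determinations      : {len(rr)}")
print(f"mean estimated RR   : {rr.rr_smoothed.mean():.3f} bpm (truth 12.000)")
print(f"mean absolute error : {err.mean():.3f} bpm")
print(f"mean relative error : {100 * err.mean() / 12:.3f} %")

aligned = align(rr, rr.times, truth.true_rr_at(rr.times))
tost = tost_equivalence(aligned, delta=2.0, conf=0.90)
print(f"TOST (+/-2 bpm, 90% CI): bias {tost.bias:+.3f} bpm, "
      f"CI [{tost.ci_low:+.3f}, {tost.ci_high:+.3f}] -> equivalent: {tost.equivalent}")
# Sub-0.1 bpm errors mean the spectral peak sits within one frequency
# grid step of the true modulation; equivalence at +/-2 bpm is the
# clinical acceptance threshold.
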