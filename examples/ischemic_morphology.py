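"""Robustness to ischemia-like ECG morphology change.

Myocardial ischemia elevates the ST segment and reshapes the T wave.
Because the estimator reads breathing off the *modulation* of the QRS
amplitude, not its absolute shape, such morphology changes should not
move the RR estimate. Two otherwise identical records are compared:
one healthy, one with a 0.12 mV ST offset and a 50% larger T wave.
"""
from ecgresp import EstimatorConfig, SyntheticConfig, estimate_rr, generate

base = dict(fs=1000.0, duration=120.0, hr=60.0, hr_jitter_sd=0.01,
            rr=12.0, mod_depth=0.10, noise_sd=0.02, seed=5)
cfg = EstimatorConfig(rr_band=(5.0, 40.0))

healthy = estimate_rr(generate(SyntheticConfig(**base)).record, cfg)
ischemic = estimate_rr(
    generate(SyntheticConfig(**base, st_shift=0.12, t_wave_scale=1.5)).record, cfg
)

m_h = healthy.rr_smoothed.mean()
m_i = ischemic.rr_smoothed.mean()
print(f"mean RR, healthy morphology : {m_h:.3f} bpm")
print(f"mean RR, ischemic morphology: {m_i:.3f} bpm")
print(f"shift                       : {abs(m_i - m_h):.4f} bpm")
# A shift well under 0.2 bpm: the ST/T change rescales every beat's RMS
# by the same factor, leaving the modulation frequency untouched.
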