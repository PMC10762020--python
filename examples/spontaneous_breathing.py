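"""Spontaneous-breathing analog: slowly varying RR with co-varying HR.

Ten minutes in which the true respiratory rate sweeps ~8-35 bpm while
the heart rate co-varies 60-100 bpm (fast breathing accompanies fast
heart rates, keeping the modulation below the beat-domain Nyquist).
Reports the cycle-to-cycle linear-fit quality against the known truth.
"""
from ecgresp import (
    EstimatorConfig, SyntheticConfig, align, error_metrics, estimate_rr, generate,
    sinusoid,
)

truth = generate(SyntheticConfig(
    fs=1000.0, duration=600.0,
    hr=sinusoid(80.0, 20.0, 600.0), hr_jitter_sd=0.01,
    rr=sinusoid(21.5, 13.5, 600.0),
    mod_depth=0.10, noise_sd=0.02, seed=3,
))
rr = estimate_rr(truth.record, EstimatorConfig(rr_band=(5.0, 40.0)))
report = error_metrics(align(rr, rr.times, truth.true_rr_at(rr.times)))
print(report)
# An R^2 above ~0.91 with RMSE around 1 bpm shows the estimator tracks
# a drifting rate; the residual comes mostly from the causal smoothing
# lag during the fastest rate changes.
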