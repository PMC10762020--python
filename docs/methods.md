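# Methods

## Signal model

A surface ECG records one heartbeat waveform per cardiac cycle.
Respiration tilts the cardiac axis relative to a fixed electrode, which
to first order rescales the projected QRS complex multiplicatively:

    x(t) = Σ_b [1 + m · sin φ(t_b)] · g(t − t_b) + w(t) + ε(t)

where `g` is the beat waveform, `t_b` the beat times, `m` the
modulation depth, `φ` a phase advancing at the breathing rate
(dφ/dt = 2π·RR/60), `w` baseline wander and `ε` measurement noise.
Because the RMS amplitude of a window around each R-peak is linear in
the beat's scale factor, the per-beat RMS series is — up to a constant
— a sampled sinusoid at the breathing frequency, sampled once per
heartbeat. Estimating RR therefore reduces to finding the dominant
frequency of a short per-beat series, which is what the pipeline does.

## Pipeline and parameters

| stage | parameter | default | why |
|---|---|---|---|
| band-pass | 8–40 Hz, order-3 Butterworth, forward–backward | — | isolates QRS energy; zero-phase so detected peak times (and hence the RMS windows centred on them) are not skewed |
| R-peak detection | w_qrs = 97 ms, w_beat = 611 ms, β = 0.08, refractory = 200 ms, rectifier = squaring | — | dual-moving-average event detection; the window pair matches QRS and beat durations at rest and the published values of the method are kept as defaults; all are configurable, and absolute-value rectification is available |
| QRS RMS | 80 ms window centred on the R-peak | — | wide enough to cover a ~20 ms R wave plus Q/S, short enough to exclude P and T |
| spectrum | 16-beat window, step 1 beat, mean-subtracted, zero-padded 512-point FFT | — | 16 beats resolves the modulation without over-smoothing rate changes (32- or 64-beat windows respond visibly later — a settling-delay test demonstrates the monotone trade-off); zero-padding gives a 1/512 cycles/beat search grid |
| peak search | anticipated RR band, default 1.8–18 bpm, study setting 5–40 bpm | — | converts to cycles/beat via f = RR·mean(R–R)/60 per window; clipped at the beat-domain Nyquist (0.5 cycles/beat) with a warning; ties break to the lower frequency for determinism |
| conversion | RR = 60·f_peak/mean(R–R in window) | — | cycles/beat ÷ seconds/beat = Hz; the window's own mean interval keeps the conversion correct when heart rate drifts |
| smoothing | trailing median over 16 determinations | — | removes isolated spectral misses; trailing (causal) so the output could be produced in a streaming setting; the window shrinks at the start so output length equals input length |

Each determination is timestamped at the **last beat of its spectral
window**. Centre-stamping would halve the apparent tracking lag but
breaks causality; the choice is deliberate and documented here because
the fit statistics on drifting-rate signals include that lag.

## Design choices where the design was open

- **Detrending before the FFT.** The 16-point rectangular window has a
  wide DC lobe; without mean subtraction it can dominate the low end of
  the RR band. The window mean is therefore always removed.
- **RMS on the filtered signal.** Computing beat RMS on the band-passed
  signal rather than the raw ECG removes baseline wander that would
  otherwise contaminate the amplitude envelope additively.
- **Beats treated as evenly spaced.** The spectrum is taken on the beat
  index axis and converted with the per-window mean interval; no
  Lomb–Scargle or interval resampling. For the ±2% interval jitter of
  a resting or ventilated subject the frequency error of this
  approximation is far below the spectral grid spacing.
- **Amplitude-scale and DC invariance.** Squaring plus a threshold
  proportional to the signal's own mean power makes detection invariant
  to positive rescaling; the band-pass removes any DC offset. Both
  invariances are asserted as property tests.

## Numerical behaviour and edge cases

- A single spectral window whose respiratory sinusoid has an unlucky
  phase can place its peak several grid bins (up to ≈ 6/512
  cycles/beat) away from the true frequency because of
  negative-frequency leakage through the 16-sample rectangular window.
  Sliding the window one beat at a time sweeps the phase, and the
  median filter averages the residual wander; the end-to-end error on a
  steady signal is an order of magnitude below the single-window worst
  case.
- Windows whose converted band contains no grid point (extreme
  tachycardia with a narrow low band) are skipped and logged, not
  fatal. Beats whose 80 ms window would cross a record boundary are
  dropped and logged.
- Zero detected peaks is a valid (empty) result for detection, but the
  estimator raises a descriptive error when fewer beats than one
  spectral window survive.
- TOST with zero-variance differences is handled as the analytic limit
  (the confidence interval collapses to the point estimate).
- Rank-sum comparisons use the exact null distribution up to n = 10
  per group without ties, and the tie-corrected normal approximation
  otherwise; an all-tied pair returns p = 1.

## The synthetic generator

The generator emulates the conditions the estimator is meant for:
steady mechanical ventilation (constant RR, default 12 bpm),
stepped ventilator protocols (default pattern 11/10/12/10/11 bpm,
~2 min per level), slowly varying spontaneous breathing (sinusoidal
protocols for RR and co-varying heart rate), baseline wander, white
noise, per-beat interval jitter, and ischemia-like morphology
(ST-segment offset plus T-wave rescaling). Default conditions used
throughout the tests: heart rate 60 bpm with 10 ms interval jitter,
modulation depth 10%, noise SD 2% of the 1 mV R amplitude, 120 s
records (600 s for the stepped and drifting protocols). All randomness
flows from one seeded generator in a fixed draw order (interval jitter
per beat, wander phase, noise array), so records reproduce bit-exactly.

What the generator does **not** model: respiratory sinus arrhythmia
(frequency modulation of the heart rate), respiration-driven baseline
wander correlated with the breathing phase, electrode motion artifacts,
ectopic beats, and non-stationary noise. Passing the synthetic suite
therefore demonstrates that the algorithm chain is implemented
correctly and is robust to amplitude-scale, offset, noise and
morphology perturbations — not that it attains the same accuracy on
arbitrary clinical recordings.

## Problem sizes

The test suite and the acceptance script use 90–600 s records at
500–1000 Hz: long enough that each run yields ~100–600 overlapping
spectral windows and the pooled error statistics are stable to well
under the margins being checked, while a full run of either completes
in seconds.

## Known limitations

- RR above half the beat rate aliases in the beat-domain spectrum and
  is rejected by the generator and clipped by the estimator; subjects
  whose breathing approaches half the heart rate need a different
  modality.
- The estimator reports the dominant amplitude-modulation frequency; if
  another periodic process modulates QRS amplitude inside the RR band
  more strongly than breathing does, that frequency wins.
- Only the amplitude-modulation channel is used; fusing it with
  frequency-modulation or baseline-wander channels is out of scope.
- The WFDB reader needs the optional `wfdb` package; the core pipeline
  has no such dependency.
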