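# ecgresp

Respiratory-rate (RR) estimation from a **single-lead ECG**.

Breathing moves the chest, and with it the electrical axis of the
heart, so the amplitude of each QRS complex in a surface ECG is
modulated at the breathing frequency. `ecgresp` turns that modulation
into a continuous RR estimate without any dedicated respiration sensor
— useful to physiologists and engineers working with ambulatory ECG
monitors, ventilated animal preparations, or remote-monitoring
prototypes, where only one ECG stream is available.

## Method

1. **Band-pass filter** the ECG at 8–40 Hz (zero-phase Butterworth) to
   isolate QRS energy and reject baseline wander.
2. **Detect R-peaks** with a dual-moving-average detector: the
   rectified (squared) signal is averaged over a QRS-scale window
   (97 ms) and a beat-scale window (611 ms); runs where the short
   average exceeds the long one (plus an offset β·mean) mark beats.
3. **Per-beat QRS RMS**: the root-mean-square amplitude of an 80 ms
   window centered on each R-peak gives one sample of the
   respiration-modulated envelope per beat.
4. **Sliding beat-domain spectrum**: for every window of 16 consecutive
   RMS values (step one beat), a mean-subtracted, zero-padded 512-point
   FFT gives a power spectrum in cycles/beat. The dominant peak
   *f*<sub>peak</sub> is searched within a user-set anticipated RR band
   (default 1.8–18 bpm; 5–40 bpm for exercise or ventilation studies).
5. **Convert and smooth**:

   RR (bpm) = 60 · *f*<sub>peak</sub> / mean(R–R interval in the window)

   followed by a trailing median over 16 determinations.

The package also contains a **synthetic ECG generator** (sum-of-Gaussians
P-QRS-T template, configurable heart-rate and respiratory-rate
protocols, baseline wander, noise, ischemia-like ST/T changes) that
provides exact ground truth for every stage, and an **evaluation
module** (absolute/relative error, linear-fit R²/RMSE, paired TOST
equivalence at ±2 bpm, Wilcoxon rank-sum group comparison).

## Worked example

```python
import numpy as np
from ecgresp import (EstimatorConfig, SyntheticConfig, estimate_rr, generate)

truth = generate(SyntheticConfig(
    fs=1000.0, duration=120.0, hr=60.0, hr_jitter_sd=0.01,
    rr=12.0, mod_depth=0.10, noise_sd=0.02, seed=1))
rr = estimate_rr(truth.record, EstimatorConfig(rr_band=(5.0, 40.0)))
print(f"mean estimated RR   : {rr.rr_smoothed.mean():.3f} bpm")
print(f"mean absolute error : {np.abs(rr.rr_smoothed - 12).mean():.3f} bpm")
```

prints

```
mean estimated RR   : 11.979 bpm
mean absolute error : 0.036 bpm
```

i.e. on a ventilated-subject analog (heart rate 60 bpm, true RR fixed
at 12 bpm, 10% QRS amplitude modulation, noise at 2% of the R
amplitude) the estimate sits within a few hundredths of a breath per
minute of the ventilator setting; the small bias reflects the
1/512-cycles-per-beat spectral grid. The scripts in `examples/` run
the other study conditions — a stepped ventilator protocol resolved at
1 bpm, a drifting spontaneous-breathing protocol tracked with
R² ≈ 0.99, and an ischemia-morphology challenge that shifts the
estimate by < 0.0001 bpm — each printing its own numbers.

## Command line

```sh
ecgresp synth --hr 60 --rr 12 --duration 120 --fs 500 --seed 1 --out-dir demo
ecgresp estimate --input demo/ecg.bin --fs 500 --scale 0.001 --out-dir demo_rr
ecgresp eval --est demo_rr/rr.csv --ref demo/truth.csv --out-dir demo_eval
```

`estimate` accepts raw 16-bit binary (all four endian/signedness
encodings), delimited text/CSV, or WFDB records, resamples to 1000 Hz
by default, and writes `rr.csv`, `peaks.csv`, plots and a JSON run
manifest. See `examples/cli_pipeline.sh` for the full chain.

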