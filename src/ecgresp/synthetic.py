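"""Synthetic single-lead ECG with known respiratory amplitude modulation.

The generator renders a fixed sum-of-Gaussians beat template (P, Q, R,
S, T) at quasi-periodic beat times and scales each beat by
``1 + mod_depth * sin(phi(t))`` where ``phi`` advances at the configured
true respiratory rate. That multiplicative scaling is exactly the
amplitude-modulation mechanism a QRS-RMS estimator exploits, so the
generator provides ground truth for every pipeline stage: beat times,
instantaneous true RR, and a record contaminated (optionally) with
baseline wander, additive Gaussian noise, and an ischemia-like ST bump.

Rate protocols (heart rate and respiratory rate) are plain callables
``t_seconds -> bpm``; :func:`constant`, :func:`stepped_protocol` and
:func:`sinusoid` build the common ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .containers import ECGRecord
from .errors import ConfigError

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "constant",
    "stepped_protocol",
    "sinusoid",
    "generate",
]

RateProtocol = Callable[[np.ndarray], np.ndarray]


def constant(bpm: float) -> RateProtocol:
    """A constant-rate protocol."""
    if bpm <= 0:
        raise ConfigError("rate must be > 0")
    return lambda t: np.full_like(np.asarray(t, dtype=float), float(bpm))


class _Stepped:
    def __init__(self, levels: Sequence[float], segment_s: float | Sequence[float]):
        levels = list(levels)
        if not levels:
            raise ConfigError("stepped protocol needs at least one level")
        if any(lv <= 0 for lv in levels):
            raise ConfigError("all protocol levels must be > 0")
        if np.isscalar(segment_s):
            segs = [float(segment_s)] * len(levels)
        else:
            segs = [float(s) for s in segment_s]
            if len(segs) != len(levels):
                raise ConfigError("one segment duration per level required")
        if any(s <= 0 for s in segs):
            raise ConfigError("segment durations must be > 0")
        self.levels = levels
        self.segments = segs
        self.edges = np.concatenate([[0.0], np.cumsum(segs)])

    @property
    def duration(self) -> float:
        return float(self.edges[-1])

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.edges, t, side="right") - 1, 0, len(self.levels) - 1)
        return np.asarray(self.levels, dtype=float)[idx]


def stepped_protocol(levels: Sequence[float], segment_s: float | Sequence[float]) -> _Stepped:
    """Piecewise-constant rate: ``levels[i]`` bpm held for ``segment_s`` seconds.

    ``stepped_protocol([11, 10, 12, 10, 11], 120)`` reproduces a
    ventilator sequence of five ~2-minute settings.
    """
    return _Stepped(levels, segment_s)


def sinusoid(mean: float, amplitude: float, period_s: float, phase: float = 0.0) -> RateProtocol:
    """Slowly varying rate: mean + amplitude * sin(2*pi*t/period + phase)."""
    if mean - abs(amplitude) <= 0:
        raise ConfigError("sinusoid rate must stay positive")
    if period_s <= 0:
        raise ConfigError("period must be > 0")
    return lambda t: mean + amplitude * np.sin(
        2 * np.pi * np.asarray(t, dtype=float) / period_s + phase
    )


# Beat template: (amplitude mV, center s relative to R, width s).
# R width ~20 ms so an 80 ms QRS window captures the whole complex.
_TEMPLATE = {
    "P": (0.12, -0.200, 0.025),
    "Q": (-0.10, -0.018, 0.008),
    "R": (1.00, 0.000, 0.0085),
    "S": (-0.18, 0.018, 0.008),
    "T": (0.30, 0.240, 0.045),
}
_ST_BUMP = (0.100, 0.040)  # center s, width s of the ischemia-like ST offset
_TEMPLATE_SPAN = (-0.30, 0.45)  # template support, s relative to R


def beat_template(
    t: np.ndarray, st_shift: float = 0.0, t_wave_scale: float = 1.0
) -> np.ndarray:
    """Evaluate the P-QRS-T template at times ``t`` (s, relative to the R-peak)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for name, (amp, mu, sig) in _TEMPLATE.items():
        a = amp * t_wave_scale if name == "T" else amp
        out += a * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    if st_shift:
        mu, sig = _ST_BUMP
        out += st_shift * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    return out


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic record.

    fs : Hz (>= 250)
        Sampling rate of the rendered record.
    duration : s
        Record length.
    hr : bpm, scalar or protocol callable
        Heart rate driving the beat times.
    hr_jitter_sd : s
        Gaussian jitter added to each inter-beat interval.
    rr : bpm, scalar or protocol callable
        True respiratory rate; must stay below half the beat rate
        (the beat-domain Nyquist), else the modulation aliases.
    mod_depth : fraction in [0, 1)
        Peak fractional QRS amplitude modulation (10% is a typical
        resting value).
    wander_amp, wander_freq : mV, Hz
        Sinusoidal baseline wander (random phase).
    noise_sd : mV
        Additive white Gaussian noise.
    st_shift : mV
        Ischemia-like ST-segment offset added to the beat template.
    t_wave_scale : float
        Multiplier on the T-wave amplitude (morphology-change challenge).
    seed : int
        Seeds all randomness; a fixed seed reproduces the record
        bit-exactly.
    """

    fs: float = 1000.0
    duration: float = 120.0
    hr: float | RateProtocol = 60.0
    hr_jitter_sd: float = 0.0
    rr: float | RateProtocol = 12.0
    mod_depth: float = 0.10
    wander_amp: float = 0.0
    wander_freq: float = 0.25
    noise_sd: float = 0.0
    st_shift: float = 0.0
    t_wave_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 250:
            raise ConfigError("fs must be >= 250 Hz to resolve the QRS")
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")
        if not 0 <= self.mod_depth < 1:
            raise ConfigError("mod_depth must be in [0, 1)")
        if self.hr_jitter_sd < 0 or self.noise_sd < 0 or self.wander_amp < 0:
            raise ConfigError("jitter, noise and wander amplitudes must be >= 0")


@dataclass
class SyntheticTruth:
    """Generator output: the record plus its ground truth."""

    record: ECGRecord
    beat_times: np.ndarray
    true_rr: RateProtocol
    config: SyntheticConfig = field(repr=False, default=None)

    def true_rr_at(self, t) -> np.ndarray:
        """Instantaneous true RR (bpm) at times ``t`` (s)."""
        return self.true_rr(np.asarray(t, dtype=float))


def _as_protocol(x: float | RateProtocol) -> RateProtocol:
    return x if callable(x) else constant(float(x))


def generate(cfg: SyntheticConfig) -> SyntheticTruth:
    """Render one synthetic record with known truth.

    Randomness is drawn from a single seeded generator in a fixed order
    — per-beat interval jitter (sequentially), then the wander phase,
    then the noise array — so records are reproducible across platforms.
    """
    hr = _as_protocol(cfg.hr)
    rr = _as_protocol(cfg.rr)
    rng = np.random.default_rng(cfg.seed)

    n = int(round(cfg.duration * cfg.fs))
    t_grid = np.arange(n) / cfg.fs
    rr_grid = rr(t_grid)
    hr_grid = hr(t_grid)
    if np.any(rr_grid <= 0):
        raise ConfigError("respiratory-rate protocol must stay positive")
    if np.any(rr_grid >= hr_grid / 2):
        raise ConfigError(
            "true RR reaches half the beat rate (beat-domain Nyquist); "
            "the modulation would alias and be untestable"
        )

    # beat times: integrate the HR process with optional interval jitter
    beats: list[float] = []
    t = -_TEMPLATE_SPAN[0]  # first beat late enough that its P-wave fits
    while t < cfg.duration - _TEMPLATE_SPAN[1]:
        beats.append(t)
        iv = 60.0 / float(hr(np.asarray([t]))[0])
        if cfg.hr_jitter_sd:
            iv += rng.normal(0.0, cfg.hr_jitter_sd)
            iv = max(iv, 0.2)  # physiological floor
        t += iv
    beat_times = np.asarray(beats)

    # respiratory phase: phi(t) = 2*pi/60 * integral of rr(u) du
    phi_grid = 2 * np.pi / 60.0 * np.cumsum(rr_grid) / cfg.fs
    phi_beats = np.interp(beat_times, t_grid, phi_grid)
    scales = 1.0 + cfg.mod_depth * np.sin(phi_beats)

    sig = np.zeros(n)
    lo, hi = _TEMPLATE_SPAN
    for tb, sc in zip(beat_times, scales):
        i0 = max(int(np.ceil((tb + lo) * cfg.fs)), 0)
        i1 = min(int(np.floor((tb + hi) * cfg.fs)) + 1, n)
        rel = t_grid[i0:i1] - tb
        sig[i0:i1] += sc * beat_template(rel, cfg.st_shift, cfg.t_wave_scale)

    if cfg.wander_amp:
        phase = rng.uniform(0, 2 * np.pi)
        sig += cfg.wander_amp * np.sin(2 * np.pi * cfg.wander_freq * t_grid + phase)
    elif cfg.noise_sd:
        # keep the stream order fixed whether or not wander is on
        rng.uniform(0, 2 * np.pi)
    if cfg.noise_sd:
        sig += rng.normal(0.0, cfg.noise_sd, n)

    rec = ECGRecord(samples=sig, fs=cfg.fs, label="synthetic ECG")
    return SyntheticTruth(record=rec, beat_times=beat_times, true_rr=rr, config=cfg)
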