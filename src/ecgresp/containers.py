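"""Core data containers shared across the pipeline.

These are thin, validated dataclasses: an ECG voltage trace with its
sampling rate, detected R-peaks, the per-beat QRS RMS series that carries
the respiratory amplitude modulation, one spectral window of that series,
and the final respiratory-rate (RR) time series.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "ECGRecord",
    "RPeakList",
    "BeatRMSSeries",
    "SpectrumWindow",
    "RRSeries",
]


@dataclass
class ECGRecord:
    """A uniformly sampled single-lead voltage series.

    Parameters
    ----------
    samples : ndarray
        Voltage samples, millivolts (or raw ADC counts times a scale).
    fs : float
        Sampling frequency in Hz, > 0.
    label : str
        Free-text channel name.
    """

    samples: np.ndarray
    fs: float
    label: str = "ECG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ConfigError(f"sampling frequency must be > 0, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InputError("ECG record needs a 1-D series of at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("ECG record contains non-finite samples")

    @property
    def duration(self) -> float:
        """Record duration in seconds (n samples / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class RPeakList:
    """Detected R-peak sample positions on a record of sampling rate ``fs``."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise InputError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def times(self) -> np.ndarray:
        """Peak times in seconds."""
        return self.indices / self.fs

    @property
    def rr_intervals(self) -> np.ndarray:
        """Successive inter-beat intervals in seconds (length n-1)."""
        if len(self) < 2:
            raise InputError("need at least 2 peaks for inter-beat intervals")
        return np.diff(self.times)


@dataclass
class BeatRMSSeries:
    """Per-beat QRS RMS amplitudes: the respiration-modulated carrier."""

    rms: np.ndarray
    beat_times: np.ndarray

    def __post_init__(self) -> None:
        self.rms = np.asarray(self.rms, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.rms.shape != self.beat_times.shape:
            raise InputError("rms and beat_times must have equal length")
        if np.any(self.rms < 0):
            raise InputError("RMS values must be nonnegative")
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise InputError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.rms.size)

    @property
    def intervals(self) -> np.ndarray:
        """Intervals between consecutive retained beats, seconds."""
        return np.diff(self.beat_times)


@dataclass
class SpectrumWindow:
    """Power spectrum of one beat-domain RMS window.

    ``freqs`` are cycles per beat on the grid k/nfft, k = 0 .. nfft//2;
    ``mean_interval`` is the mean R-R interval (seconds) inside the window
    and converts cycles/beat to Hz.
    """

    freqs: np.ndarray
    power: np.ndarray
    mean_interval: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise InputError("freqs and power must have equal length")
        if np.any(self.power < -1e-12):
            raise InputError("spectral power must be nonnegative")
        if self.mean_interval <= 0:
            raise InputError("mean R-R interval must be positive")


@dataclass
class RRSeries:
    """Time-stamped respiratory-rate estimates, raw and median-smoothed."""

    times: np.ndarray
    rr_raw: np.ndarray
    rr_smoothed: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rr_raw = np.asarray(self.rr_raw, dtype=float)
        self.rr_smoothed = np.asarray(self.rr_smoothed, dtype=float)
        if not (self.times.shape == self.rr_raw.shape == self.rr_smoothed.shape):
            raise InputError("times, rr_raw, rr_smoothed must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise InputError("estimate timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)
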