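"""R-peak detection with the two-event-related-moving-average method.

The detector band-passes the ECG at 8-40 Hz to isolate QRS energy,
rectifies it (squaring by default), and compares a short moving average
(QRS-scale, 97 ms) against a long one (beat-scale, 611 ms) plus a small
data-driven offset. Runs where the short average exceeds the long one
mark candidate QRS complexes; each run at least one QRS-window wide
yields one R-peak at the sample of maximum rectified amplitude.

The detector is deliberately pluggable: anything callable as
``detector(rec, cfg) -> RPeakList`` can replace :func:`detect_rpeaks`
in the downstream estimator.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .containers import ECGRecord, RPeakList
from .errors import ConfigError, InputError

log = logging.getLogger(__name__)

__all__ = ["DetectionConfig", "bandpass_filter", "detect_rpeaks", "rr_intervals"]


@dataclass
class DetectionConfig:
    """Parameters of the dual-moving-average R-peak detector.

    band_low, band_high : Hz
        Passband isolating QRS energy (default 8-40 Hz).
    w_qrs : ms
        First moving-average window, matched to QRS duration (97 ms).
    w_beat : ms
        Second moving-average window, matched to one beat (611 ms).
    beta : float
        Offset factor; the detection threshold adds ``beta * mean(rectified)``
        to the beat-scale average.
    refractory : ms
        Minimum separation of accepted peaks; closer pairs are merged,
        keeping the larger.
    rectifier : {"square", "abs"}
        How the filtered signal is rectified before averaging.
    filter_order : int
        Butterworth section order (applied forward-backward, so the
        effective attenuation is doubled).
    """

    band_low: float = 8.0
    band_high: float = 40.0
    w_qrs: float = 97.0
    w_beat: float = 611.0
    beta: float = 0.08
    refractory: float = 200.0
    rectifier: str = "square"
    filter_order: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ConfigError("need 0 < band_low < band_high")
        if not 0 < self.w_qrs < self.w_beat:
            raise ConfigError("need 0 < w_qrs < w_beat")
        if self.beta < 0:
            raise ConfigError("beta must be >= 0")
        if self.refractory <= 0:
            raise ConfigError("refractory must be > 0")
        if self.rectifier not in ("square", "abs"):
            raise ConfigError("rectifier must be 'square' or 'abs'")


def bandpass_filter(rec: ECGRecord, cfg: DetectionConfig | None = None) -> ECGRecord:
    """Zero-phase Butterworth band-pass of the ECG.

    Forward-backward filtering keeps R-peak timing unskewed, which
    matters because the QRS RMS windows downstream are centered on the
    detected peaks. DC and respiratory-band baseline wander are rejected.
    """
    cfg = cfg or DetectionConfig()
    nyq = rec.fs / 2
    if cfg.band_high >= nyq:
        raise ConfigError(
            f"band_high {cfg.band_high} Hz must be below Nyquist ({nyq} Hz) for fs {rec.fs}"
        )
    sos = butter(
        cfg.filter_order, [cfg.band_low / nyq, cfg.band_high / nyq], btype="band", output="sos"
    )
    out = sosfiltfilt(sos, rec.samples)
    return ECGRecord(samples=out, fs=rec.fs, label=rec.label)


def _rectify(x: np.ndarray, how: str) -> np.ndarray:
    return x * x if how == "square" else np.abs(x)


def detect_rpeaks(rec: ECGRecord, cfg: DetectionConfig | None = None) -> RPeakList:
    """Detect R-peaks; returns an empty list (not an error) when none exist.

    Steps: band-pass; rectify; moving means over ``w_qrs`` and ``w_beat``;
    keep runs where the QRS-scale mean exceeds the beat-scale mean plus
    ``beta * mean(rectified)``; discard runs shorter than ``w_qrs``; take
    the rectified maximum of each surviving run; merge peaks closer than
    the refractory period, keeping the larger.
    """
    cfg = cfg or DetectionConfig()
    n_beat = max(int(round(cfg.w_beat * rec.fs / 1000)), 2)
    n_refr = int(round(cfg.refractory * rec.fs / 1000))
    if rec.samples.size < max(n_beat, 2 * n_refr):
        raise InputError(
            f"record of {rec.samples.size} samples is too short for "
            f"w_beat={cfg.w_beat} ms / refractory={cfg.refractory} ms at fs={rec.fs}"
        )
    filt = bandpass_filter(rec, cfg).samples
    rect = _rectify(filt, cfg.rectifier)
    n_qrs = max(int(round(cfg.w_qrs * rec.fs / 1000)), 1)
    ma_qrs = uniform_filter1d(rect, n_qrs, mode="nearest")
    ma_beat = uniform_filter1d(rect, n_beat, mode="nearest")
    thr = ma_beat + cfg.beta * float(rect.mean())
    above = ma_qrs > thr

    # contiguous runs of True; blocks touching the boundaries are kept
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    stops = np.nonzero(edges == -1)[0] + 1
    if above.size and above[0]:
        starts = np.r_[0, starts]
    if above.size and above[-1]:
        stops = np.r_[stops, above.size]

    peaks: list[int] = []
    for a, b in zip(starts, stops):
        if b - a < n_qrs:
            continue
        peaks.append(a + int(np.argmax(rect[a:b])))

    # refractory merge: of any pair closer than n_refr keep the larger
    merged: list[int] = []
    for p in peaks:
        if merged and p - merged[-1] < n_refr:
            if rect[p] > rect[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)
    return RPeakList(indices=np.asarray(merged, dtype=np.int64), fs=rec.fs)


def rr_intervals(peaks: RPeakList) -> np.ndarray:
    """Successive inter-beat intervals in seconds (requires >= 2 peaks)."""
    return peaks.rr_intervals
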