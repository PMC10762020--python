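"""Respiratory rate from QRS amplitude modulation.

Chest movement during breathing modulates the QRS amplitude of a
single-lead ECG. The estimator extracts the RMS amplitude of an 80 ms
window centered on each R-peak, slides a 16-beat window over that
per-beat RMS series one beat at a time, takes a zero-padded 512-point
power spectrum of each (mean-subtracted) window on the beat-index axis,
finds the dominant peak inside the user's anticipated RR band, and
converts cycles/beat to breaths/min with the window's mean R-R interval:

    RR_bpm = 60 * f_peak / mean(R-R interval in window)

A trailing 16-determination median filter removes spurious jumps.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .containers import BeatRMSSeries, ECGRecord, RPeakList, RRSeries, SpectrumWindow
from .detection import DetectionConfig, bandpass_filter, detect_rpeaks
from .errors import ConfigError, InputError

log = logging.getLogger(__name__)

__all__ = [
    "EstimatorConfig",
    "extract_qrs_rms",
    "window_spectrum",
    "dominant_frequency",
    "rr_from_peak",
    "median_smooth",
    "estimate_rr",
]

#: Default anticipated RR band, bpm (0.03-0.3 Hz at one beat per second).
DEFAULT_RR_BAND = (1.8, 18.0)
#: Wider band suited to exercise or ventilated subjects.
WIDE_RR_BAND = (5.0, 40.0)


@dataclass
class EstimatorConfig:
    """Tunable parameters of the RR estimator.

    qrs_window : ms
        Width of the RMS window centered on each R-peak (default 80 ms).
    spectral_window : beats
        Beats per spectral window (default 16: large enough to resolve
        the modulation, small enough not to over-smooth).
    nfft : int
        Zero-padded FFT length (default 512), setting the frequency grid
        spacing of 1/nfft cycles per beat.
    rr_band : (float, float)
        Anticipated RR range in bpm searched for the dominant peak.
    median_window : int
        Trailing median window, in RR determinations (default 16).
    """

    qrs_window: float = 80.0
    spectral_window: int = 16
    nfft: int = 512
    rr_band: tuple[float, float] = DEFAULT_RR_BAND
    median_window: int = 16

    def __post_init__(self) -> None:
        if self.qrs_window <= 0:
            raise ConfigError("qrs_window must be > 0")
        if self.spectral_window < 4:
            raise ConfigError("spectral_window must be >= 4")
        if self.nfft < self.spectral_window:
            raise ConfigError("nfft must be >= spectral_window")
        lo, hi = self.rr_band
        if not 0 < lo < hi:
            raise ConfigError("rr_band must satisfy 0 < rr_min < rr_max")
        if self.median_window < 1:
            raise ConfigError("median_window must be >= 1")


def extract_qrs_rms(
    rec: ECGRecord, peaks: RPeakList, cfg: EstimatorConfig | None = None
) -> BeatRMSSeries:
    """Per-beat RMS amplitude over a window centered on each R-peak.

    ``rec`` should be the band-pass-filtered signal so that baseline
    wander does not contaminate the amplitude modulation. Peaks whose
    window would run off either end of the record are dropped (logged).
    """
    cfg = cfg or EstimatorConfig()
    half = int(round(cfg.qrs_window / 2 * rec.fs / 1000))
    if half < 1:
        raise ConfigError("qrs_window shorter than one sample at this fs")
    n = rec.samples.size
    keep = (peaks.indices - half >= 0) & (peaks.indices + half + 1 <= n)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d beat(s) with incomplete QRS windows", dropped)
    idx = peaks.indices[keep]
    if idx.size == 0:
        raise InputError("no beats with complete QRS windows")
    offs = np.arange(-half, half + 1)
    seg = rec.samples[idx[:, None] + offs[None, :]]
    rms = np.sqrt(np.mean(seg * seg, axis=1))
    return BeatRMSSeries(rms=rms, beat_times=idx / rec.fs)


def window_spectrum(
    rms_window: np.ndarray,
    intervals: np.ndarray,
    cfg: EstimatorConfig | None = None,
) -> SpectrumWindow:
    """Power spectrum of one RMS window on the beat-index axis.

    The window mean is subtracted first so the DC lobe of the short
    rectangular window cannot mask a slow respiratory peak; the series
    is then zero-padded to ``nfft`` points.
    """
    cfg = cfg or EstimatorConfig()
    x = np.asarray(rms_window, dtype=float)
    if x.size != cfg.spectral_window:
        raise InputError(
            f"need exactly {cfg.spectral_window} RMS values, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise InputError("RMS window contains non-finite values")
    iv = np.asarray(intervals, dtype=float)
    if iv.size == 0 or np.any(iv <= 0):
        raise InputError("window needs positive R-R intervals")
    spec = np.fft.rfft(x - x.mean(), n=cfg.nfft)
    power = np.abs(spec) ** 2
    freqs = np.arange(power.size) / cfg.nfft
    return SpectrumWindow(freqs=freqs, power=power, mean_interval=float(iv.mean()))


def dominant_frequency(spec: SpectrumWindow, cfg: EstimatorConfig | None = None) -> float:
    """Frequency (cycles/beat) of maximum power inside the RR band.

    The bpm band converts to cycles/beat via f = rr * mean_interval / 60
    and is clipped at the beat-domain Nyquist of 0.5 cycles/beat (with a
    warning when the user band extends beyond it). Ties break toward the
    lower frequency so the output is deterministic.
    """
    cfg = cfg or EstimatorConfig()
    lo_bpm, hi_bpm = cfg.rr_band
    lo = lo_bpm * spec.mean_interval / 60.0
    hi = hi_bpm * spec.mean_interval / 60.0
    if hi > 0.5:
        log.debug(
            "rr_band upper edge %.3g bpm exceeds the beat-domain Nyquist "
            "(%.3g bpm at this heart rate); clipping",
            hi_bpm,
            30.0 / spec.mean_interval,
        )
        hi = 0.5
    in_band = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not np.any(in_band):
        raise InputError("converted RR band contains no spectral grid points")
    band_power = np.where(in_band, spec.power, -np.inf)
    return float(spec.freqs[int(np.argmax(band_power))])  # argmax takes first max


def rr_from_peak(f_peak: float, mean_interval: float) -> float:
    """Convert a beat-domain peak frequency to breaths per minute.

    cycles/beat divided by seconds/beat gives Hz; times 60 gives bpm.
    """
    if f_peak < 0:
        raise InputError("peak frequency must be >= 0")
    if mean_interval <= 0:
        raise InputError("mean R-R interval must be > 0")
    return 60.0 * f_peak / mean_interval


def median_smooth(rr_raw: np.ndarray, cfg: EstimatorConfig | None = None) -> np.ndarray:
    """Trailing median over up to ``median_window`` determinations.

    The window shrinks at the start so output length equals input
    length; an even-count median is the mean of the two central values.
    """
    cfg = cfg or EstimatorConfig()
    x = np.asarray(rr_raw, dtype=float)
    if x.size == 0:
        raise InputError("need at least one RR determination")
    w = cfg.median_window
    return np.array([np.median(x[max(0, i + 1 - w) : i + 1]) for i in range(x.size)])


def estimate_rr(
    rec: ECGRecord,
    cfg: EstimatorConfig | None = None,
    det_cfg: DetectionConfig | None = None,
    detector: Callable[[ECGRecord, DetectionConfig], RPeakList] | None = None,
) -> RRSeries:
    """Full pipeline: ECG record in, smoothed RR time series out.

    Composes band-pass filtering, R-peak detection (pluggable via
    ``detector``), per-beat QRS RMS, the sliding beat-domain spectrum
    (step one beat), in-band peak picking, bpm conversion, and median
    smoothing. Each determination is stamped at the last beat of its
    spectral window, so the output is causal.
    """
    cfg = cfg or EstimatorConfig()
    det_cfg = det_cfg or DetectionConfig()
    detector = detector or detect_rpeaks
    filt = bandpass_filter(rec, det_cfg)
    peaks = detector(rec, det_cfg)
    if len(peaks) < 2:
        raise InputError(f"detected only {len(peaks)} beat(s); cannot estimate RR")
    beats = extract_qrs_rms(filt, peaks, cfg)
    w = cfg.spectral_window
    if len(beats) < w:
        raise InputError(
            f"only {len(beats)} usable beats; need at least {w} for one spectral window"
        )
    mean_iv = float(beats.intervals.mean())
    if cfg.rr_band[1] * mean_iv / 60.0 > 0.5:
        log.warning(
            "rr_band upper edge %.3g bpm exceeds the beat-domain Nyquist "
            "(about %.3g bpm at the observed heart rate); the search is clipped there",
            cfg.rr_band[1],
            30.0 / mean_iv,
        )
    times: list[float] = []
    raw: list[float] = []
    intervals = beats.intervals
    skipped = 0
    for i in range(len(beats) - w + 1):
        spec = window_spectrum(beats.rms[i : i + w], intervals[i : i + w - 1], cfg)
        try:
            f_peak = dominant_frequency(spec, cfg)
        except InputError:
            skipped += 1
            continue
        times.append(float(beats.beat_times[i + w - 1]))
        raw.append(rr_from_peak(f_peak, spec.mean_interval))
    if skipped:
        log.info("skipped %d window(s) with no spectral grid point in band", skipped)
    if not raw:
        raise InputError("no spectral window produced an in-band RR determination")
    raw_arr = np.asarray(raw)
    smoothed = median_smooth(raw_arr, cfg)
    return RRSeries(
        times=np.asarray(times),
        rr_raw=raw_arr,
        rr_smoothed=smoothed,
        meta={"n_beats": len(beats), "n_windows_skipped": skipped},
    )
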