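"""Reading and writing single-lead ECG and RR series.

Supported inputs: raw 16-bit binary streams (all four endian/signedness
encodings), delimited text/CSV, and — when the optional ``wfdb`` package
is installed — WFDB records. Resampling uses polyphase band-limited
interpolation so that R-peak amplitudes survive the rate change.
"""
from __future__ import annotations

import logging
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .containers import ECGRecord, RRSeries
from .errors import ConfigError, FormatError

log = logging.getLogger(__name__)

_ENCODINGS = {
    "int16-le": "<i2",
    "int16-be": ">i2",
    "uint16-le": "<u2",
    "uint16-be": ">u2",
}

DEFAULT_ENCODING = "int16-le"


def read_binary_ecg(
    path,
    fs: float,
    encoding: str = DEFAULT_ENCODING,
    scale: float = 1.0,
    label: str = "ECG",
) -> ECGRecord:
    """Read a raw 16-bit binary voltage stream.

    Parameters
    ----------
    path : path-like
        File containing a bare sequence of 2-byte words (no header).
    fs : float
        Sampling frequency in Hz (must be supplied; the format carries none).
    encoding : {"int16-le", "int16-be", "uint16-le", "uint16-be"}
        Word signedness and byte order. Default little-endian signed.
    scale : float
        Millivolts per count; samples are multiplied by it.
    """
    if fs <= 0:
        raise ConfigError(f"fs must be > 0, got {fs}")
    try:
        dtype = np.dtype(_ENCODINGS[encoding])
    except KeyError:
        raise ConfigError(
            f"unknown encoding {encoding!r}; choose one of {sorted(_ENCODINGS)}"
        ) from None
    raw = Path(path).read_bytes()
    if len(raw) == 0:
        raise FormatError(f"{path}: empty file")
    if len(raw) % 2:
        raise FormatError(f"{path}: truncated file ({len(raw)} bytes is not a whole number of 16-bit words)")
    samples = np.frombuffer(raw, dtype=dtype).astype(float) * scale
    return ECGRecord(samples=samples, fs=fs, label=label)


def write_binary_ecg(rec: ECGRecord, path, encoding: str = DEFAULT_ENCODING, scale: float = 1.0) -> None:
    """Write a record as raw 16-bit binary (inverse of :func:`read_binary_ecg`).

    Samples are divided by ``scale`` and rounded to the nearest count;
    values outside the encoding's range raise rather than wrap.
    """
    try:
        dtype = np.dtype(_ENCODINGS[encoding])
    except KeyError:
        raise ConfigError(f"unknown encoding {encoding!r}") from None
    counts = np.rint(rec.samples / scale)
    info = np.iinfo(dtype)
    if counts.min() < info.min or counts.max() > info.max:
        raise FormatError(
            f"samples out of range for {encoding}: counts span "
            f"[{counts.min():.0f}, {counts.max():.0f}]"
        )
    counts.astype(dtype).tofile(path)


def read_text_ecg(path, fs: float, column: int = 0, label: str = "ECG") -> ECGRecord:
    """Read one numeric column from a delimited text/CSV file.

    A header row is skipped automatically. A non-numeric cell in the body
    raises :class:`FormatError` naming the offending line.
    """
    if fs <= 0:
        raise ConfigError(f"fs must be > 0, got {fs}")
    import csv

    sample = Path(path).read_text()[:4096]
    try:
        sep = csv.Sniffer().sniff(sample, delimiters=",;\t ").delimiter
    except csv.Error:
        sep = ","  # single column
    try:
        df = pd.read_csv(path, sep=sep, engine="python", header=None, comment="#",
                         skipinitialspace=True)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse delimited text ({exc})") from exc
    if df.shape[1] <= column or column < 0:
        raise FormatError(f"{path}: column {column} out of range (file has {df.shape[1]} columns)")
    col = df.iloc[:, column]
    values = pd.to_numeric(col, errors="coerce")
    start = 0
    if len(values) and np.isnan(values.iloc[0]) and isinstance(col.iloc[0], str):
        start = 1  # header row
    values = values.iloc[start:]
    bad = np.nonzero(values.isna().to_numpy())[0]
    if bad.size:
        raise FormatError(f"{path}: non-numeric value on line {bad[0] + start + 1}")
    return ECGRecord(samples=values.to_numpy(dtype=float), fs=fs, label=label)


def read_wfdb_ecg(record_name, channel: int = 0) -> ECGRecord:
    """Read one channel of a WFDB record (requires the optional ``wfdb`` package).

    The header-declared sampling frequency and gain take precedence over
    any user-supplied values, which is why this reader takes none.
    """
    try:
        import wfdb  # noqa: PLC0415
    except ImportError as exc:
        raise ImportError(
            "WFDB support requires the optional 'wfdb' package "
            "(pip install ecgresp[wfdb])"
        ) from exc
    rec = wfdb.rdrecord(str(record_name), channels=[channel], physical=True)
    name = rec.sig_name[0] if rec.sig_name else "ECG"
    return ECGRecord(samples=rec.p_signal[:, 0], fs=float(rec.fs), label=name)


def resample(rec: ECGRecord, target_fs: float) -> ECGRecord:
    """Resample to ``target_fs`` with band-limited (polyphase) interpolation.

    Duration is preserved to within one target-rate sample, and a pure
    tone below the smaller Nyquist rate keeps its amplitude within 1%.
    """
    if target_fs <= 0:
        raise ConfigError(f"target_fs must be > 0, got {target_fs}")
    if target_fs == rec.fs:
        return ECGRecord(samples=rec.samples.copy(), fs=rec.fs, label=rec.label)
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = resample_poly(rec.samples, ratio.numerator, ratio.denominator, padtype="line")
    return ECGRecord(samples=out, fs=target_fs, label=rec.label)


def write_rr_csv(rr: RRSeries, path) -> None:
    """Write RR estimates as a headered two-column CSV (time_s, rr_bpm).

    The smoothed series is the headline output; the raw series rides
    along as a third column for diagnostics.
    """
    df = pd.DataFrame(
        {"time_s": rr.times, "rr_bpm": rr.rr_smoothed, "rr_raw_bpm": rr.rr_raw}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_rr_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (time_s, rr_bpm) CSV, e.g. a reference RR series.

    Returns ``(times, rr)`` arrays; extra columns are ignored.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns (time_s, rr_bpm)")
    t = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    v = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = np.nonzero((t.isna() | v.isna()).to_numpy())[0]
    if bad.size:
        raise FormatError(f"{path}: non-numeric value on line {bad[0] + 2}")
    return t.to_numpy(dtype=float), v.to_numpy(dtype=float)
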