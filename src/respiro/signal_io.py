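"""Reading, writing and resampling of waveforms and derived series.

All on-disk formats are plain delimited text with a header row; the
delimiter is auto-detected among comma, tab and semicolon.  Waveform
files carry ``time,value`` columns (seconds, arbitrary units); IBI files
carry ``peak_time,ibi`` (both seconds).  Timestamps are seconds
throughout and sample indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Waveform",
    "RespiroError",
    "FormatError",
    "SamplingError",
    "InputError",
    "ParameterError",
    "read_waveform",
    "resample",
    "read_table",
    "write_table",
    "write_waveform",
    "detect_delimiter",
]


class RespiroError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RespiroError):
    """A file does not have the expected columns or layout."""


class SamplingError(RespiroError):
    """Timestamps are not uniformly spaced within tolerance."""


class InputError(RespiroError):
    """An input file is empty or unreadable as data."""


class ParameterError(RespiroError):
    """An argument violates a precondition."""


# Relative tolerance on time-step uniformity when inferring fs.
TIME_STEP_RTOL = 0.01

_DELIMITERS = (",", "\t", ";")


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled single-channel signal.

    Attributes
    ----------
    t0 : float
        Time of the first sample, seconds.
    fs : float
        Sampling rate in Hz, strictly positive.
    values : numpy.ndarray
        Amplitude at each sample (arbitrary units).  The implied
        timestamps are ``t0 + k / fs``.
    """

    t0: float
    fs: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be > 0, got {self.fs}")
        if values.ndim != 1 or values.size < 1:
            raise ParameterError("values must be a non-empty 1-D sequence")

    @property
    def times(self) -> np.ndarray:
        """Timestamps of the samples, seconds."""
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        """Span from first to last sample, seconds."""
        return (self.values.size - 1) / self.fs


def detect_delimiter(path) -> str:
    """Pick the delimiter among comma/tab/semicolon from the header line."""
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    if not header.strip():
        raise InputError(f"empty file: {path}")
    counts = {d: header.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def read_table(path) -> pd.DataFrame:
    """Read a delimited numeric table (header required) into a DataFrame."""
    sep = detect_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty file: {path}") from exc
    if df.shape[1] == 0 or len(df.columns) != len(set(df.columns)):
        raise FormatError(f"table in {path} has missing or duplicate column names")
    return df


def write_table(path, table: pd.DataFrame) -> None:
    """Write a numeric table as CSV, full precision; NaN as empty field."""
    df = pd.DataFrame(table)
    lengths = {len(df[c]) for c in df.columns}
    if len(lengths) > 1:  # pragma: no cover - DataFrame construction enforces this
        raise FormatError("ragged columns")
    df.to_csv(path, index=False, float_format="%.17g")


def _numeric_column(df: pd.DataFrame, name: str, path) -> np.ndarray:
    if name not in df.columns:
        raise FormatError(f"column {name!r} not found in {path} (have {list(df.columns)})")
    col = pd.to_numeric(df[name], errors="coerce")
    good = col.notna()
    return col[good].to_numpy(dtype=float), good.to_numpy()


def read_waveform(path, time_col: str | None = "time", value_col: str = "value",
                  fs: float | None = None) -> Waveform:
    """Read a waveform from a delimited text file.

    Either ``time_col`` must name a uniformly spaced time column (fs is
    then inferred from the median step) or ``fs`` must be given
    explicitly with ``time_col=None``.  Non-numeric rows are dropped.
    """
    df = read_table(path)
    values, vmask = _numeric_column(df, value_col, path)
    if time_col is None:
        if fs is None:
            raise ParameterError("either a time column or an explicit fs is required")
        return Waveform(t0=0.0, fs=float(fs), values=values)

    times, tmask = _numeric_column(df, time_col, path)
    mask = vmask & tmask
    times = pd.to_numeric(df[time_col], errors="coerce")[mask].to_numpy(dtype=float)
    values = pd.to_numeric(df[value_col], errors="coerce")[mask].to_numpy(dtype=float)
    if values.size == 0:
        raise InputError(f"no numeric rows in {path}")
    if fs is None:
        if times.size < 2:
            raise SamplingError("cannot infer sampling rate from fewer than 2 samples")
        steps = np.diff(times)
        med = float(np.median(steps))
        if med <= 0:
            raise SamplingError("timestamps must be strictly increasing")
        if np.any(np.abs(steps - med) > TIME_STEP_RTOL * med):
            raise SamplingError(
                "non-uniform time steps (beyond 1% relative tolerance); "
                "resample or pass fs explicitly"
            )
        fs = 1.0 / med
    return Waveform(t0=float(times[0]), fs=float(fs), values=values)


def write_waveform(path, w: Waveform) -> None:
    """Write a waveform as a ``time,value`` CSV."""
    write_table(path, pd.DataFrame({"time": w.times, "value": w.values}))


def resample(w: Waveform, target_fs: float) -> Waveform:
    """Resample a waveform onto a uniform grid at ``target_fs`` Hz.

    Linear interpolation onto ``t0 + k/target_fs`` covering the original
    span.  At the original rate this is the identity on the samples.
    """
    if not target_fs > 0:
        raise ParameterError(f"target_fs must be > 0, got {target_fs}")
    if target_fs == w.fs:
        return w
    n_out = int(np.floor(w.duration * target_fs)) + 1
    new_t = w.t0 + np.arange(n_out) / target_fs
    new_v = np.interp(new_t, w.times, w.values)
    return Waveform(t0=w.t0, fs=float(target_fs), values=new_v)
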