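"""lowPSD: spectral-exponent estimation restricted to low frequencies.

A fractal (1/f-like) series has periodogram power falling off as a
power law, P(f) ~ f^(-beta).  The lowPSD recipe makes the slope
estimate robust for short biomedical records: subtract the mean, taper
with a parabolic window, bridge-detrend (subtract the line through the
first and last samples), take the raw periodogram, and fit the log-log
slope by ordinary least squares using only the lowest fraction of the
positive-frequency range (default the lowest 1/8).  The spectral
exponent is beta = -slope; for fractional Gaussian noise with Hurst
exponent H, beta = 2H - 1.

Each preprocessing step is independently switchable so the variant in
use is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .signal_io import ParameterError, RespiroError

__all__ = ["PSDResult", "FitError", "preprocess_for_psd", "periodogram", "low_psd",
           "DEFAULT_LOW_FRACTION"]

DEFAULT_LOW_FRACTION = 1.0 / 8.0


class FitError(RespiroError):
    """Too few frequencies in the requested fit range."""


@dataclass(frozen=True)
class PSDResult:
    """Periodogram plus the low-frequency log-log fit.

    ``freqs`` are in Hz for waveform/IBI input with a time step (or
    cycles/interval when ``dt=1``); DC is excluded.  The fitted line is
    ``log10 power = intercept + slope * log10 freq`` with
    ``beta = -slope``, so the plot data can be regenerated exactly.
    """

    freqs: np.ndarray
    power: np.ndarray
    beta: float
    intercept: float
    slope: float
    fit_lo: float
    fit_hi: float
    r2: float


def preprocess_for_psd(x, *, subtract_mean: bool = True, window: bool = True,
                       bridge_detrend: bool = True) -> np.ndarray:
    """Mean removal, parabolic tapering and bridge detrending.

    The parabolic window is ``w_j = 1 - (2j/(N+1) - 1)^2`` for
    j = 1..N; bridge detrending subtracts the straight line through the
    first and last samples, pinning both endpoints to zero.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise ParameterError(f"need at least 8 samples, got {n}")
    y = x - x.mean() if subtract_mean else x.copy()
    if window:
        j = np.arange(1, n + 1)
        y = y * (1.0 - (2.0 * j / (n + 1) - 1.0) ** 2)
    if bridge_detrend:
        y = y - np.linspace(y[0], y[-1], n)
    return y


def periodogram(y, dt: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Raw one-sided periodogram, DC excluded.

    Normalized so that summing ``power`` over the full (two-sided)
    spectrum and dividing by N recovers the mean square of the input;
    the one-sided ordinates returned here carry the factor 2 for the
    interior bins.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    spec = np.abs(np.fft.rfft(y)) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=dt)
    # one-sided: double interior bins (not DC, not Nyquist when n even)
    scale = np.full(spec.size, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power = spec * scale / n
    return freqs[1:], power[1:]


def low_psd(x, dt: float = 1.0, low_fraction: float = DEFAULT_LOW_FRACTION,
            *, subtract_mean: bool = True, window: bool = True,
            bridge_detrend: bool = True) -> PSDResult:
    """Estimate the spectral exponent beta from the low-frequency slope."""
    x = np.asarray(x, dtype=float)
    if not 0 < low_fraction <= 1:
        raise ParameterError(f"low_fraction must be in (0, 1], got {low_fraction}")
    if x.size < 16:
        raise ParameterError(f"need at least 16 samples, got {x.size}")
    y = preprocess_for_psd(x, subtract_mean=subtract_mean, window=window,
                           bridge_detrend=bridge_detrend)
    freqs, power = periodogram(y, dt=dt)
    f_cut = freqs[-1] * low_fraction
    in_fit = (freqs <= f_cut) & (power > 0)
    if in_fit.sum() < 4:
        raise FitError(
            f"only {int(in_fit.sum())} frequencies in the fit range; "
            "increase low_fraction or use a longer series"
        )
    lf = np.log10(freqs[in_fit])
    lp = np.log10(power[in_fit])
    fit = scipy.stats.linregress(lf, lp)
    return PSDResult(
        freqs=freqs,
        power=power,
        beta=-float(fit.slope),
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        fit_lo=float(freqs[in_fit][0]),
        fit_hi=float(freqs[in_fit][-1]),
        r2=float(fit.rvalue ** 2),
    )
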