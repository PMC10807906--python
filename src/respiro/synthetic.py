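"""Synthetic signals with known ground truth.

Three generators back every analysis in the package with an exact
oracle:

* a deterministic binomial multiplicative cascade (the p-model), whose
  generalized Hurst exponent has the closed form
  ``h(q) = 1/q - ln(a^q + (1-a)^q)/(q ln 2)`` — the same functional form
  as the extended BMF model with (alpha, beta) = (max(a, 1-a), min(...));
* fractional Gaussian noise with exact target autocovariance via
  circulant embedding (Davies-Harte), the monofractal oracle for DFA
  and spectral-exponent estimators (beta = 2H - 1);
* a cyclic respiratory waveform — one raised-cosine breath pulse after
  another with truncated-normal cycle durations and additive white
  noise — with the exact apex times recorded as truth for peak/IBI
  recovery tests.

All generators are pure functions of their arguments including the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .signal_io import ParameterError, RespiroError, Waveform

__all__ = [
    "RespSimTruth",
    "gen_binomial_cascade",
    "cascade_hq",
    "fgn_autocovariance",
    "gen_fgn",
    "gen_respiration",
]


@dataclass(frozen=True)
class RespSimTruth:
    """Ground truth of a simulated respiratory record: exact apex times,
    the implied IBI values, and the generating parameters."""

    peak_times: np.ndarray
    ibi_values: np.ndarray
    params: dict


def gen_binomial_cascade(levels: int, a: float, seed: int | None = None) -> np.ndarray:
    """Deterministic binomial cascade of length 2**levels.

    Element i (0-based) has value ``a**ones(i) * (1-a)**(levels-ones(i))``
    where ``ones(i)`` counts 1-bits of i; the series sums to 1 exactly
    (binomial theorem).  ``seed`` is reserved for an optional shuffled
    variant and ignored in the default deterministic form.
    """
    if not 1 <= levels <= 24:
        raise ParameterError(f"levels must be in [1, 24], got {levels}")
    if not 0 < a < 1:
        raise ParameterError(f"a must be in (0, 1), got {a}")
    idx = np.arange(2 ** levels, dtype=np.uint32)
    ones = np.zeros(idx.size, dtype=np.int64)
    v = idx.copy()
    while v.any():
        ones += v & 1
        v >>= 1
    return a ** ones * (1.0 - a) ** (levels - ones)


def cascade_hq(q, a: float):
    """Closed-form generalized Hurst exponent of the binomial cascade."""
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = 1.0 / q - np.log(a ** q + (1.0 - a) ** q) / (q * np.log(2.0))
    h = np.where(q == 0, -(np.log(a) + np.log(1 - a)) / (2 * np.log(2.0)), h)
    return float(h) if h.ndim == 0 else h


def fgn_autocovariance(k, H: float):
    """Autocovariance of unit-variance fGn: gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2."""
    k = np.abs(np.asarray(k, dtype=float))
    return 0.5 * (np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))


def gen_fgn(n: int, H: float, seed: int) -> np.ndarray:
    """Fractional Gaussian noise with exact covariance (circulant embedding).

    The target autocovariance is embedded in a circulant matrix whose
    eigenvalues are obtained by FFT; a rare non-positive-definite
    embedding at small n is retried with the embedding length doubled.
    """
    if not 0 < H < 1:
        raise ParameterError(f"H must be in (0, 1), got {H}")
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    m = n
    for _ in range(3):
        gamma = fgn_autocovariance(np.arange(m + 1), H)
        row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2m
        eig = np.fft.fft(row).real
        if np.all(eig > -1e-10):
            eig = np.maximum(eig, 0.0)
            break
        m *= 2
    else:
        raise RespiroError("circulant embedding not positive semi-definite")
    # With z_k complex, Re/Im each standard normal, and weights
    # sqrt(lambda_k / M), the real part of the FFT has covariance gamma.
    two_m = row.size
    z = rng.standard_normal(two_m) + 1j * rng.standard_normal(two_m)
    f = np.fft.fft(np.sqrt(eig / two_m) * z)
    return f[:n].real


def gen_respiration(duration_s: float, fs: float, ibi_mean: float, ibi_sd: float,
                    amplitude: float = 1.0, noise_sd: float = 0.0,
                    seed: int = 0) -> tuple[Waveform, RespSimTruth]:
    """Simulate a cyclic respiratory airflow waveform with known apexes.

    Cycle durations are truncated-normal (mean ``ibi_mean``, SD
    ``ibi_sd``, lower bound ``ibi_mean - 2 ibi_sd``); each cycle is a
    raised-cosine pulse of the drawn duration, peaking at its midpoint,
    with white Gaussian noise of SD ``noise_sd`` added.  The truth holds
    the exact apex times (on the continuous axis) and their successive
    differences.
    """
    if ibi_sd < 0 or ibi_mean <= 2 * ibi_sd:
        raise ParameterError("require ibi_mean > 2*ibi_sd and ibi_sd >= 0")
    if fs * ibi_mean < 10:
        raise ParameterError("need at least ~10 samples per cycle: fs*ibi_mean >= 10")
    if duration_s <= 0 or amplitude <= 0 or noise_sd < 0:
        raise ParameterError("duration and amplitude must be > 0, noise_sd >= 0")
    rng = np.random.default_rng(seed)

    # draw cycle durations until the record is covered
    starts, durations = [], []
    t = 0.0
    while t < duration_s:
        if ibi_sd == 0:
            d = ibi_mean
        else:
            lo = (ibi_mean - 2 * ibi_sd - ibi_mean) / ibi_sd  # = -2
            d = float(scipy.stats.truncnorm.rvs(lo, np.inf, loc=ibi_mean,
                                                scale=ibi_sd, random_state=rng))
        starts.append(t)
        durations.append(d)
        t += d
    starts = np.asarray(starts)
    durations = np.asarray(durations)

    n = int(round(duration_s * fs)) + 1
    tt = np.arange(n) / fs
    values = np.zeros(n)
    cyc = np.searchsorted(starts, tt, side="right") - 1
    phase = (tt - starts[cyc]) / durations[cyc]
    values = amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(phase, 0, 1)))
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n)

    apex = starts + durations / 2.0
    apex = apex[apex <= tt[-1]]
    truth = RespSimTruth(
        peak_times=apex,
        ibi_values=np.diff(apex),
        params=dict(duration_s=duration_s, fs=fs, ibi_mean=ibi_mean,
                    ibi_sd=ibi_sd, amplitude=amplitude, noise_sd=noise_sd,
                    seed=seed),
    )
    return Waveform(t0=0.0, fs=fs, values=values), truth
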