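"""Sample entropy, coarse-graining, and multiscale sample entropy (MSE).

Sample entropy SampEn(m, r) is the negative log of the conditional
probability that two sequences matching for m points (within an
absolute tolerance r, Chebyshev distance) also match for m+1 points.
Self-matches are excluded and unordered template pairs i < j are
counted, with both template sets ranging over i <= N - m, following the
convention of the classic C implementation this measure descends from.

MSE coarse-grains the series into non-overlapping block means at scales
tau = 1..tau_max and reports SampEn per scale.  The tolerance r is fixed
once from the SD of the *original* series and held constant across
scales (the per-scale alternative is available via ``r_per_scale``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import ParameterError, RespiroError

__all__ = [
    "MSEResult",
    "UndefinedEntropyError",
    "coarse_grain",
    "sample_entropy",
    "sampen_counts",
    "mse",
]


class UndefinedEntropyError(RespiroError):
    """No template matches at length m (B=0) or m+1 (A=0): SampEn undefined."""


@dataclass(frozen=True)
class MSEResult:
    """Multiscale sample entropy curve.

    ``entropies[k]`` is SampEn at scale ``scales[k]`` in nats; NaN marks
    scales where the entropy is undefined (zero template matches).
    """

    scales: np.ndarray
    entropies: np.ndarray
    m: int
    r: float
    r_coef: float


def coarse_grain(x, tau: int) -> np.ndarray:
    """Non-overlapping block means of length ``tau``; remainder dropped."""
    x = np.asarray(x, dtype=float)
    if tau < 1:
        raise ParameterError(f"tau must be >= 1, got {tau}")
    if tau > x.size:
        raise ParameterError(f"tau={tau} exceeds series length {x.size}")
    if tau == 1:
        return x.copy()
    n_blocks = x.size // tau
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


def sampen_counts(x, m: int, r: float) -> tuple[int, int]:
    """Unordered template-pair match counts (A, B) at lengths m+1 and m.

    Both counts range over pairs i < j with i, j <= N - m (0-based:
    i, j in [0, N-m)), so A and B are computed on the same template set.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if m < 1:
        raise ParameterError(f"m must be >= 1, got {m}")
    if n <= m + 1:
        raise ParameterError(f"series length {n} must exceed m+1={m + 1}")
    if not r > 0:
        raise ParameterError(f"tolerance r must be > 0, got {r}")

    n_templ = n - m
    a = b = 0
    # Chunked O(N^2) pair counting; running max over the m (then m+1)
    # offsets keeps memory at O(chunk * N).
    chunk = max(1, min(n_templ, 2 ** 22 // max(n_templ, 1) + 1))
    for start in range(0, n_templ - 1, chunk):
        stop = min(start + chunk, n_templ - 1)
        i_idx = np.arange(start, stop)[:, None]  # (ci, 1)
        j_off = np.arange(1, n_templ)            # j = i + off, clipped below
        d_m = np.zeros((stop - start, n_templ), dtype=float)
        for k in range(m):
            d_m = np.maximum(d_m, np.abs(x[i_idx + k] - x[None, k:k + n_templ]))
        valid = np.arange(n_templ)[None, :] > i_idx  # j > i
        match_m = (d_m <= r) & valid
        b += int(match_m.sum())
        d_m1 = np.maximum(d_m, np.abs(x[i_idx + m] - x[None, m:m + n_templ]))
        a += int(((d_m1 <= r) & valid).sum())
        del d_m, d_m1, match_m, valid, j_off
    return a, b


def sample_entropy(x, m: int = 2, r: float = 0.2) -> float:
    """SampEn(m, r) in nats: ``-ln(A/B)`` over unordered template pairs.

    Raises :class:`UndefinedEntropyError` when no pairs match (B=0) or
    no pairs extend (A=0), which is distinguishable from a zero value.
    """
    a, b = sampen_counts(x, m, r)
    if b == 0 or a == 0:
        raise UndefinedEntropyError(
            f"sample entropy undefined: A={a}, B={b} template matches"
        )
    return -float(np.log(a / b))


def mse(x, tau_max: int = 10, m: int = 2, r_coef: float = 0.15,
        *, r_per_scale: bool = False) -> MSEResult:
    """Multiscale sample entropy at scales 1..tau_max.

    Undefined entropies are reported as NaN, never silently as 0 or inf.
    ``r_per_scale=True`` recomputes the tolerance from the coarse-grained
    series at each scale instead of holding it fixed.
    """
    x = np.asarray(x, dtype=float)
    if tau_max < 1:
        raise ParameterError(f"tau_max must be >= 1, got {tau_max}")
    if x.size // tau_max <= m + 1:
        max_tau = max(1, x.size // (m + 2))
        raise ParameterError(
            f"series too short for tau_max={tau_max} with m={m}; "
            f"maximal feasible tau is {max_tau}"
        )
    sd = float(np.std(x, ddof=1))
    r = r_coef * sd
    if not r > 0:
        # constant series: every template matches at every length
        return MSEResult(
            scales=np.arange(1, tau_max + 1),
            entropies=np.zeros(tau_max),
            m=m, r=0.0, r_coef=r_coef,
        )
    ent = np.empty(tau_max)
    for tau in range(1, tau_max + 1):
        y = coarse_grain(x, tau)
        r_tau = r_coef * float(np.std(y, ddof=1)) if r_per_scale else r
        try:
            ent[tau - 1] = sample_entropy(y, m, r_tau)
        except UndefinedEntropyError:
            ent[tau - 1] = np.nan
    return MSEResult(
        scales=np.arange(1, tau_max + 1),
        entropies=ent,
        m=m, r=r, r_coef=r_coef,
    )
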