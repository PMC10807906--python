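"""Multifractal detrended fluctuation analysis (MFDFA).

The analysis proceeds in the classical steps: (1) integrate the
mean-subtracted series into a profile; (2) cut the profile into
non-overlapping windows of size s, from the start *and* from the end so
no tail is ever discarded (2*N_s segments); (3) detrend each window
with a least-squares polynomial of order m and record the mean squared
residual F^2(nu, s); (4) average the residuals into the q-order
fluctuation function

    F_q(s) = { (1/2N_s) sum_nu [F^2]^(q/2) }^(1/q),        q != 0
    F_0(s) = exp{ (1/4N_s) sum_nu ln F^2 },

and (5) read the generalized Hurst exponent h(q) off the log-log slope
of F_q(s) against s.  The mass exponent is tau(q) = q h(q) - 1 and the
multifractal (singularity) spectrum is its Legendre transform,
alpha = dtau/dq, f(alpha) = q alpha - tau(q), evaluated by central
finite differences on the interior of the q grid.

A q-dependent h indicates multifractality; for a monofractal h(q) is
flat and tau(q) exactly linear.  Negative generalized Hurst exponents
require a sign-modified variant of the method; this implementation
covers the standard range and raises if h(2) falls below 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.special
import scipy.stats

from .signal_io import ParameterError, RespiroError

__all__ = [
    "MFDFAParams",
    "MFDFAResult",
    "DegenerateDetrendError",
    "NegativeHurstError",
    "default_scales",
    "profile",
    "fluctuation_function",
    "hurst_exponents",
    "mass_exponent",
    "multifractal_spectrum",
    "mfdfa",
]

H2_MINIMUM = 0.1  # below this the sign-modified MFDFA variant is needed


class DegenerateDetrendError(RespiroError):
    """A segment is an exact polynomial: zero residual, F_q undefined."""


class NegativeHurstError(RespiroError):
    """h(2) too small for standard MFDFA; a sign-modified variant is needed."""


class FitError(RespiroError):
    """Too few scales inside the regression range."""


def default_scales(n: int, n_scales: int = 20, s_min: int = 16,
                   s_max: int | None = None, poly_order: int = 1) -> np.ndarray:
    """Log-spaced integer window sizes, by default 16 .. N/10.

    For series too short for that grid the range degrades gracefully to
    ``poly_order + 2 .. N/4`` so that at least 4 scales remain.
    """
    if s_max is None:
        s_max = n // 10
        if s_max < 2 * s_min:  # short record: widen both ends
            s_min = max(poly_order + 2, 4)
            s_max = n // 4
    if s_max < s_min + 3:
        raise ParameterError(
            f"series of length {n} too short for a scaling fit "
            f"(scale range {s_min}..{s_max})"
        )
    raw = np.geomspace(s_min, s_max, n_scales)
    return np.unique(np.round(raw).astype(int))


@dataclass(frozen=True)
class MFDFAParams:
    """Window sizes, q moments, detrending order and h(q) fit range."""

    scales: np.ndarray
    q_list: np.ndarray = field(default_factory=lambda: np.arange(-10.0, 11.0))
    poly_order: int = 1
    fit_range: tuple[float, float] | None = None

    def __post_init__(self):
        scales = np.asarray(self.scales, dtype=int)
        q_list = np.asarray(self.q_list, dtype=float)
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "q_list", q_list)
        if self.poly_order < 1:
            raise ParameterError("poly_order must be >= 1")
        if scales.size == 0 or np.any(np.diff(scales) <= 0):
            raise ParameterError("scales must be strictly increasing")
        if scales[0] < self.poly_order + 2:
            raise ParameterError(
                f"smallest scale {scales[0]} must be >= poly_order + 2 = {self.poly_order + 2}"
            )
        if not np.all(np.isfinite(q_list)):
            raise ParameterError("q_list must be finite")


@dataclass(frozen=True)
class MFDFAResult:
    """Fluctuation matrix and derived exponents.

    ``Fq[i, j]`` is F_q(s) for ``params.q_list[i]`` at
    ``params.scales[j]``.  ``alpha_s``/``f_alpha`` cover the interior q
    (length ``len(q_list) - 2``).
    """

    params: MFDFAParams
    Fq: np.ndarray
    hq: np.ndarray
    hq_r2: np.ndarray
    tauq: np.ndarray
    alpha_s: np.ndarray
    f_alpha: np.ndarray


def profile(x) -> np.ndarray:
    """Cumulative sum of the mean-subtracted series (the 'random walk')."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ParameterError("need at least 2 samples")
    return np.cumsum(x - x.mean())


def _segment_msr(Y: np.ndarray, s: int, poly_order: int) -> np.ndarray:
    """Mean squared detrending residual per segment, both-ends cut."""
    n = Y.size
    n_s = n // s
    segs = np.concatenate([
        Y[: n_s * s].reshape(n_s, s),
        Y[n - n_s * s:].reshape(n_s, s),
    ])
    t = np.arange(s, dtype=float)
    V = np.vander(t, poly_order + 1)  # shared design matrix
    coef, *_ = np.linalg.lstsq(V, segs.T, rcond=None)
    resid = segs.T - V @ coef
    return np.mean(resid ** 2, axis=0)


def fluctuation_function(Y, s: int, q_list, poly_order: int = 1) -> np.ndarray:
    """q-order fluctuation F_q(s) at a single scale, one value per q."""
    Y = np.asarray(Y, dtype=float)
    q_list = np.asarray(q_list, dtype=float)
    if s < poly_order + 2:
        raise ParameterError(f"scale {s} must be >= poly_order + 2 = {poly_order + 2}")
    if s > Y.size:
        raise ParameterError(f"scale {s} exceeds profile length {Y.size}")
    f2 = _segment_msr(Y, s, poly_order)
    # relative threshold: residuals at float rounding level count as zero
    floor = 1e-22 * max(float(np.mean(Y ** 2)), np.finfo(float).tiny)
    if np.any(f2 <= floor):
        raise DegenerateDetrendError(
            f"zero detrending residual in {int(np.sum(f2 <= floor))} segment(s) "
            f"at scale {s}: input is exactly polynomial there"
        )
    ln_f2 = np.log(f2)
    n2 = f2.size  # = 2 * N_s
    out = np.empty(q_list.size)
    for i, q in enumerate(q_list):
        if q == 0:
            out[i] = np.exp(ln_f2.mean() / 2.0)
        else:
            # log-space moment average, stable for large negative q
            lse = scipy.special.logsumexp(0.5 * q * ln_f2) - np.log(n2)
            out[i] = np.exp(lse / q)
    return out


def hurst_exponents(Fq: np.ndarray, scales, q_list,
                    fit_range: tuple[float, float] | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-q log2-log2 regression slope of F_q(s) on s, with fit R^2."""
    Fq = np.asarray(Fq, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if fit_range is None:
        in_fit = np.ones(scales.size, dtype=bool)
    else:
        lo, hi = fit_range
        in_fit = (scales >= lo) & (scales <= hi)
    if in_fit.sum() < 4:
        raise FitError(
            f"only {int(in_fit.sum())} scales inside the fit range; need >= 4"
        )
    log_s = np.log2(scales[in_fit])
    hq = np.empty(len(q_list))
    r2 = np.empty(len(q_list))
    for i in range(len(q_list)):
        fit = scipy.stats.linregress(log_s, np.log2(Fq[i, in_fit]))
        hq[i] = fit.slope
        r2[i] = fit.rvalue ** 2
    return hq, r2


def mass_exponent(hq, q_list) -> np.ndarray:
    """Mass exponent tau(q) = q h(q) - 1; tau(0) = -1 exactly."""
    return np.asarray(q_list, dtype=float) * np.asarray(hq, dtype=float) - 1.0


def multifractal_spectrum(tauq, q_list) -> tuple[np.ndarray, np.ndarray]:
    """Legendre transform of tau(q) by central differences on interior q."""
    tauq = np.asarray(tauq, dtype=float)
    q = np.asarray(q_list, dtype=float)
    if q.size < 3:
        raise ParameterError("need at least 3 q values for the spectrum")
    if np.any(np.diff(q) <= 0):
        raise ParameterError("q_list must be sorted strictly increasing")
    alpha = (tauq[2:] - tauq[:-2]) / (q[2:] - q[:-2])
    f_alpha = q[1:-1] * alpha - tauq[1:-1]
    return alpha, f_alpha


def mfdfa(x, params: MFDFAParams | None = None) -> MFDFAResult:
    """Run the full analysis; h(2) is always estimated as a sanity guard."""
    x = np.asarray(x, dtype=float)
    if params is None:
        params = MFDFAParams(scales=default_scales(x.size))
    if params.scales[-1] > x.size:
        raise ParameterError(
            f"largest scale {params.scales[-1]} exceeds series length {x.size}"
        )
    Y = profile(x)

    q_list = params.q_list
    guard_q = 2.0 not in q_list
    q_eval = np.append(q_list, 2.0) if guard_q else q_list

    Fq = np.empty((q_eval.size, params.scales.size))
    for j, s in enumerate(params.scales):
        Fq[:, j] = fluctuation_function(Y, int(s), q_eval, params.poly_order)

    hq_all, r2_all = hurst_exponents(Fq, params.scales, q_eval, params.fit_range)
    h2 = hq_all[-1] if guard_q else hq_all[np.where(q_list == 2.0)[0][0]]
    if h2 < H2_MINIMUM:
        raise NegativeHurstError(
            f"h(2) = {h2:.3f} < {H2_MINIMUM}: standard MFDFA is unreliable here; "
            "use the sign-modified variant for negative Hurst exponents"
        )
    if guard_q:
        Fq, hq_all, r2_all = Fq[:-1], hq_all[:-1], r2_all[:-1]

    tauq = mass_exponent(hq_all, q_list)
    if q_list.size >= 3:
        alpha_s, f_alpha = multifractal_spectrum(tauq, q_list)
    else:
        alpha_s, f_alpha = np.empty(0), np.empty(0)
    return MFDFAResult(params=params, Fq=Fq, hq=hq_all, hq_r2=r2_all,
                       tauq=tauq, alpha_s=alpha_s, f_alpha=f_alpha)
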