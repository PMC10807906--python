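"""Extended binomial multifractal (BMF) model of the generalized Hurst
exponent, and its nonlinear least-squares fit.

The model has two parameters alpha, beta in (0, 1):

    h(q) = 1/q - ln(alpha^q + beta^q) / (q ln 2),       q != 0,

with the removable singularity at q = 0 filled by the analytic limit
-(ln alpha + ln beta) / (2 ln 2).  The limiting exponents

    h_min = lim_{q->+inf} h(q) = -ln(alpha) / ln 2
    h_max = lim_{q->-inf} h(q) = -ln(beta)  / ln 2

describe the scaling of the weakest and strongest fluctuations, and the
width delta_h = h_max - h_min = (ln alpha - ln beta)/ln 2 quantifies the
degree of multifractality (delta_h ~ 0 means the multifractal is almost
vanishing).  The goodness of fit is the Pearson correlation between
observed and model-predicted h(q); RMSE is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.special
import scipy.stats

from .signal_io import ParameterError

__all__ = ["BMFFit", "bmf_hq", "fit_bmf", "bmf_summary"]

LN2 = np.log(2.0)

# Deterministic multi-start grid (alpha, beta); includes the monofractal
# point and straddles the alpha<->beta symmetry of the residual.
_STARTS = [(0.5, 0.5), (0.7, 0.3), (0.9, 0.6), (0.6, 0.2), (0.8, 0.45)]


@dataclass(frozen=True)
class BMFFit:
    """Fitted BMF parameters and derived exponents; beta <= alpha so
    that h_max >= h_min."""

    alpha: float
    beta: float
    goodness: float
    rmse: float
    h_min: float
    h_max: float
    delta_h: float
    converged: bool
    n_iter: int


def _check_ab(alpha: float, beta: float) -> None:
    if not (0 < alpha < 1) or not (0 < beta < 1):
        raise ParameterError(
            f"alpha and beta must lie in (0, 1), got alpha={alpha}, beta={beta}"
        )


def bmf_hq(q, alpha: float, beta: float):
    """Model h(q); accepts scalar or array q, continuous through q = 0."""
    _check_ab(alpha, beta)
    q = np.asarray(q, dtype=float)
    la, lb = np.log(alpha), np.log(beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        # ln(alpha^q + beta^q) computed in log space for large |q|
        ln_sum = np.logaddexp(q * la, q * lb)
        h = 1.0 / q - ln_sum / (q * LN2)
    h = np.where(q == 0, -(la + lb) / (2.0 * LN2), h)
    return float(h) if h.ndim == 0 else h


def bmf_summary(alpha: float, beta: float) -> tuple[float, float, float]:
    """Limiting exponents (h_min, h_max, delta_h) from the parameters."""
    _check_ab(alpha, beta)
    h_min = -np.log(alpha) / LN2
    h_max = -np.log(beta) / LN2
    return float(h_min), float(h_max), float(h_max - h_min)


# Logit-scale bound keeping expit(theta) strictly inside (0, 1) in floats.
_THETA_MAX = 30.0


def _residuals(theta: np.ndarray, q: np.ndarray, h_obs: np.ndarray,
               weights: np.ndarray) -> np.ndarray:
    alpha, beta = scipy.special.expit(np.clip(theta, -_THETA_MAX, _THETA_MAX))
    return (h_obs - bmf_hq(q, alpha, beta)) * weights


def fit_bmf(q_list, hq_observed, weights=None, max_iter: int = 2000) -> BMFFit:
    """Fit (alpha, beta) to observed h(q) by bounded least squares.

    The optimizer works on logit-transformed parameters so (0, 1) is
    enforced without constraint machinery, restarting from a small
    deterministic grid to dodge the alpha<->beta symmetry; parameters
    are ordered beta <= alpha afterwards.  q = 0 is handled by the
    analytic limit and participates in the fit.  Equal weights by
    default; per-q weights optional.
    """
    q = np.asarray(q_list, dtype=float)
    h_obs = np.asarray(hq_observed, dtype=float)
    if q.size != h_obs.size:
        raise ParameterError("q_list and hq_observed must have equal length")
    ok = np.isfinite(q) & np.isfinite(h_obs)
    q, h_obs = q[ok], h_obs[ok]
    if q.size < 4:
        raise ParameterError(f"need at least 4 finite (q, h) pairs, got {q.size}")
    w = np.ones_like(q) if weights is None else np.sqrt(np.asarray(weights, dtype=float)[ok])

    best = None
    total_nfev = 0
    for a0, b0 in _STARTS:
        theta0 = scipy.special.logit([a0, b0])
        sol = scipy.optimize.least_squares(
            _residuals, theta0, args=(q, h_obs, w),
            method="trf", bounds=(-_THETA_MAX, _THETA_MAX),
            max_nfev=max_iter, xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        total_nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol

    alpha, beta = scipy.special.expit(np.clip(best.x, -_THETA_MAX, _THETA_MAX))
    if beta > alpha:
        alpha, beta = beta, alpha
    h_pred = bmf_hq(q, alpha, beta)
    rmse = float(np.sqrt(np.mean((h_obs - h_pred) ** 2)))
    if np.std(h_pred) == 0 or np.std(h_obs) == 0:
        # constant h: monofractal, correlation undefined -> perfect fit iff rmse 0
        goodness = 1.0 if rmse < 1e-12 else np.nan
    else:
        goodness = float(scipy.stats.pearsonr(h_obs, h_pred)[0])
    h_min, h_max, delta_h = bmf_summary(alpha, beta)
    return BMFFit(
        alpha=float(alpha), beta=float(beta), goodness=goodness, rmse=rmse,
        h_min=h_min, h_max=h_max, delta_h=delta_h,
        converged=bool(best.success), n_iter=int(total_nfev),
    )
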