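"""Exponentiated Gumbel (EG) distribution core.

The EG(alpha, lam) distribution is the proportional-reversed-hazard
family built on the Gumbel (smallest-extreme-value-type) baseline:

    F(x) = exp(-alpha * exp(-lam * x)),   -inf < x < inf,

with shape ``alpha > 0`` and scale/rate ``lam > 0``.  ``lam`` multiplies
``x`` directly (it is a *rate*, units 1/time); the "Scale" column of the
worked steel-lifetime example is this ``lam``, not ``1/lam``.

This module provides the density, distribution and quantile functions,
inverse-CDF random generation, the i.i.d.-sample maximum-likelihood fit
via the profile likelihood, and a Kolmogorov-Smirnov goodness-of-fit
test against a fitted EG law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import kstest

__all__ = [
    "EGParams",
    "GOFResult",
    "eg_cdf",
    "eg_logcdf",
    "eg_pdf",
    "eg_logpdf",
    "eg_quantile",
    "eg_sample",
    "eg_fit_mle",
    "eg_ks_test",
]


@dataclass(frozen=True)
class EGParams:
    """Parameters of one EG population.

    Attributes
    ----------
    alpha : float
        Shape parameter, > 0.
    lam : float
        Scale/rate parameter, > 0, units 1/time.
    """

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"shape alpha must be a positive finite real, got {self.alpha!r}")
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValueError(f"rate lam must be a positive finite real, got {self.lam!r}")


@dataclass(frozen=True)
class GOFResult:
    """Kolmogorov-Smirnov goodness-of-fit summary for a fitted EG law."""

    params: EGParams
    ks_stat: float
    p_value: float
    n: int


def eg_logcdf(x, params: EGParams):
    """log F(x) = -alpha * exp(-lam * x); vectorized in ``x``."""
    x = np.asarray(x, dtype=float)
    out = -params.alpha * np.exp(-params.lam * x)
    return out if out.ndim else float(out)


def eg_cdf(x, params: EGParams):
    """EG distribution function exp(-alpha * e^(-lam x)).

    Evaluated through the log-CDF so the extreme left tail underflows
    to 0 gracefully instead of overflowing inside the inner exponential.
    """
    x = np.asarray(x, dtype=float)
    # exp(-alpha e^{-lam x}): the inner exponential can overflow for very
    # negative x; clip its log so the result underflows to exactly 0.
    inner = -params.lam * x + math.log(params.alpha)
    out = np.exp(-np.exp(np.minimum(inner, 709.0)))
    return out if out.ndim else float(out)


def eg_logpdf(x, params: EGParams):
    """log f(x) = ln(alpha) + ln(lam) - lam*x - alpha*exp(-lam*x)."""
    x = np.asarray(x, dtype=float)
    out = (
        math.log(params.alpha)
        + math.log(params.lam)
        - params.lam * x
        - params.alpha * np.exp(-params.lam * x)
    )
    return out if out.ndim else float(out)


def eg_pdf(x, params: EGParams):
    """EG density alpha*lam*e^(-lam x)*exp(-alpha e^(-lam x)), computed in log space."""
    x = np.asarray(x, dtype=float)
    inner = -params.lam * x + math.log(params.alpha)
    logf = math.log(params.lam) + inner - np.exp(np.minimum(inner, 709.0))
    out = np.exp(logf)
    return out if out.ndim else float(out)


def eg_quantile(u, params: EGParams):
    """Inverse CDF: x = -(1/lam) * ln(-ln(u) / alpha) for u in (0, 1)."""
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("quantile argument u must lie strictly inside (0, 1)")
    out = -np.log(-np.log(u) / params.alpha) / params.lam
    return out if out.ndim else float(out)


def eg_sample(n: int, params: EGParams, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. EG variates by inverse-CDF on uniforms.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.uniform(size=n)
    # uniform() can return 0.0; fold to the open interval
    u = np.where(u == 0.0, np.nextafter(0.0, 1.0), u)
    return eg_quantile(u, params)


def _profile_negloglik(lam: float, data: np.ndarray) -> float:
    # For fixed lam the shape MLE is alpha(lam) = n / sum(exp(-lam*x));
    # substituting gives the profile log-likelihood up to constants.
    n = data.size
    s = np.exp(-lam * data).sum()
    return -(n * math.log(n / s) + n * math.log(lam) - lam * data.sum() - n)


def eg_fit_mle(data) -> EGParams:
    """Maximum-likelihood fit of EG(alpha, lam) to an i.i.d. sample.

    Maximizes ``n ln a + n ln lam - lam*sum(x) - a*sum(exp(-lam x))`` via
    the profile likelihood: for fixed lam, ``a(lam) = n / sum(exp(-lam x))``,
    leaving a one-dimensional bounded search over lam.  The bracket starts
    at [1e-8, 10/mean(|x|)] and is widened whenever the optimum lands on a
    boundary.

    Raises
    ------
    ValueError
        Fewer than 3 observations, or a degenerate (constant) sample.
    RuntimeError
        The 1-D optimizer fails to converge or keeps hitting the bracket.
    """
    data = np.asarray(data, dtype=float).ravel()
    if data.size < 3:
        raise ValueError("EG fit needs at least 3 observations")
    if np.ptp(data) == 0.0:
        raise ValueError("degenerate sample: all observations equal, lam is unbounded")

    scale = float(np.mean(np.abs(data)))
    if scale == 0.0:
        scale = float(np.std(data))
    lo, hi = 1e-8, 10.0 / scale
    for _ in range(8):
        res = minimize_scalar(
            _profile_negloglik,
            bounds=(lo, hi),
            args=(data,),
            method="bounded",
            options={"xatol": 1e-13},
        )
        if not res.success:
            raise RuntimeError(f"profile-likelihood optimizer failed: {res.message}")
        lam = float(res.x)
        if hi - lam < 1e-4 * (hi - lo):
            hi *= 10.0
        elif lam - lo < 1e-10 * (hi - lo):
            lo /= 10.0
        else:
            alpha = data.size / float(np.exp(-lam * data).sum())
            return EGParams(alpha=alpha, lam=lam)
    raise RuntimeError("profile-likelihood optimum kept hitting the bracket boundary")


def eg_ks_test(data, params: EGParams) -> GOFResult:
    """One-sample Kolmogorov-Smirnov test of ``data`` against EG(params).

    Returns the sup distance between the empirical CDF and the plug-in
    fitted CDF.  The p-value is scipy's standard one-sample K-S p-value
    (exact for small samples); with estimated parameters it is known to
    be conservative, which is documented rather than corrected.
    """
    data = np.asarray(data, dtype=float).ravel()
    if data.size == 0:
        raise ValueError("K-S test requires a nonempty sample")
    res = kstest(data, lambda t: eg_cdf(t, params))
    return GOFResult(
        params=params,
        ks_stat=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(data.size),
    )
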