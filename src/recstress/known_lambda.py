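"""Exact inference on R = P(X > Y) when the common scale is known.

With lam known the data can be rescaled (x -> lam0 * x) so that lam = 1
without loss of generality, and everything becomes tractable:

* ``2*alpha*exp(-X_n)`` and ``2*beta*exp(-Y_m)`` are chi-square with 2n
  and 2m degrees of freedom, so the quantity
  (R/(1-R)) * ((1-R_hat)/R_hat) is an exact F(2n, 2m) pivot, giving an
  exact (not asymptotic) confidence interval for R.
* Under independent gamma priors the posteriors of alpha and beta are
  independent gammas, and R = alpha/(alpha+beta) has the closed-form
  density  c * r^(shape_x-1) * (1-r)^(shape_y-1) * (1-z*r)^-(shape_x+shape_y)
  on (0,1) — a Beta law tilted by the rate imbalance z = 1 - rate_x/rate_y.
  Its moments are Gauss hypergeometric (2F1) expressions via the Euler
  integral, giving a closed-form posterior mean (the Bayes estimator
  under squared-error loss) and variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.special as sc
from scipy.stats import f as f_dist

from .bayes_records import PriorSpec
from .mle_records import ReliabilityCI
from .records import LowerRecordSample

__all__ = [
    "KnownLambdaPosterior",
    "exact_ci",
    "posterior_density_r",
    "bayes_estimate_closed_form",
    "sample_posterior_r",
]


@dataclass(frozen=True)
class KnownLambdaPosterior:
    """Posterior of R on (0,1) when lam is known (data scaled to lam = 1).

    shape_x = a1 + n, rate_x = b1 + exp(-x_n) parameterize the gamma
    posterior of alpha; shape_y, rate_y likewise for beta.  The density
    of R depends on the rates only through z = 1 - rate_x/rate_y < 1
    (negative when X's posterior rate exceeds Y's).
    """

    shape_x: float
    shape_y: float
    rate_x: float
    rate_y: float

    def __post_init__(self) -> None:
        for name in ("shape_x", "shape_y", "rate_x", "rate_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def z(self) -> float:
        return 1.0 - self.rate_x / self.rate_y

    @property
    def log_c(self) -> float:
        """Log normalizer: Gamma(sx+sy)/(Gamma(sx)Gamma(sy)) * (rate_x/rate_y)^sx."""
        return -sc.betaln(self.shape_x, self.shape_y) + self.shape_x * (
            math.log(self.rate_x) - math.log(self.rate_y)
        )

    @classmethod
    def from_records(
        cls,
        x_records: LowerRecordSample,
        y_records: LowerRecordSample,
        priors: PriorSpec | None = None,
        lam0: float = 1.0,
    ) -> "KnownLambdaPosterior":
        """Build the posterior from record samples, rescaling by the known lam0."""
        if lam0 <= 0:
            raise ValueError("lam0 must be positive")
        p = priors or PriorSpec()
        return cls(
            shape_x=p.a1 + x_records.n,
            shape_y=p.a2 + y_records.n,
            rate_x=p.b1 + math.exp(-lam0 * x_records.last),
            rate_y=p.b2 + math.exp(-lam0 * y_records.last),
        )


def exact_ci(
    x_records: LowerRecordSample,
    y_records: LowerRecordSample,
    gamma: float = 0.05,
    lam0: float = 1.0,
) -> ReliabilityCI:
    """Exact 100(1-gamma)% confidence interval for R from the F pivot.

    Endpoints are 1 / (1 + (m*e^(y_m) / (n*e^(x_n))) * F_{q; 2m, 2n}) at
    q = 1 - gamma/2 (lower) and q = gamma/2 (upper), where F_{q;d1,d2}
    denotes the 100q-th percentile.  Records are rescaled by the known
    lam0 first.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must be in (0, 1)")
    if lam0 <= 0:
        raise ValueError("lam0 must be positive")
    n, m = x_records.n, y_records.n
    # m*e^{y_m} / (n*e^{x_n}) in log space to survive large rescaled records
    log_ratio = math.log(m) - math.log(n) + lam0 * (y_records.last - x_records.last)
    f_hi = f_dist.ppf(1.0 - gamma / 2.0, 2 * m, 2 * n)
    f_lo = f_dist.ppf(gamma / 2.0, 2 * m, 2 * n)
    lower = 1.0 / (1.0 + math.exp(log_ratio) * f_hi)
    upper = 1.0 / (1.0 + math.exp(log_ratio) * f_lo)
    return ReliabilityCI(lower=lower, upper=upper, level=1.0 - gamma)


def posterior_density_r(r, post: KnownLambdaPosterior):
    """Closed-form posterior density of R at r in (0, 1), evaluated in log space."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0) or np.any(r >= 1.0):
        raise ValueError("r must lie strictly inside (0, 1)")
    a = post.shape_x + post.shape_y
    logpdf = (
        post.log_c
        + (post.shape_x - 1.0) * np.log(r)
        + (post.shape_y - 1.0) * np.log1p(-r)
        - a * np.log1p(-post.z * r)
    )
    out = np.exp(logpdf)
    return out if out.ndim else float(out)


def _hyp2f1(a: float, b: float, c: float, z: float) -> float:
    v = float(sc.hyp2f1(a, b, c, z))
    if math.isfinite(v):
        return v
    # Pfaff transformation maps z < 0 into (0, 1) where the series converges
    w = z / (z - 1.0)
    return (1.0 - z) ** (-b) * float(sc.hyp2f1(c - a, b, c, w))


def bayes_estimate_closed_form(
    post: KnownLambdaPosterior,
) -> tuple[float, float, float]:
    """Posterior mean, second moment, and variance of R via 2F1.

    By the Euler integral, E(R^k) = c * B(shape_x + k, shape_y)
    * 2F1(shape_x + shape_y, shape_x + k; shape_x + shape_y + k; z).
    Returns (mean, second_moment, variance).
    """
    a = post.shape_x + post.shape_y
    z = post.z
    mean = math.exp(post.log_c + sc.betaln(post.shape_x + 1.0, post.shape_y)) * _hyp2f1(
        a, post.shape_x + 1.0, a + 1.0, z
    )
    second = math.exp(post.log_c + sc.betaln(post.shape_x + 2.0, post.shape_y)) * _hyp2f1(
        a, post.shape_x + 2.0, a + 2.0, z
    )
    if not (math.isfinite(mean) and math.isfinite(second)):
        raise ArithmeticError("hypergeometric evaluation of the posterior moments failed")
    return mean, second, second - mean**2


def sample_posterior_r(
    post: KnownLambdaPosterior,
    n_draws: int,
    seed=None,
    method: str = "gamma_ratio",
) -> np.ndarray:
    """Draw i.i.d. samples of R from the known-lam posterior.

    ``method="gamma_ratio"`` (default) draws A ~ Gamma(shape_x, rate_x),
    B ~ Gamma(shape_y, rate_y) and returns A/(A+B) — an exact sampler for
    the closed-form density.  ``method="accept_reject"`` instead rejects
    from a Beta(shape_x, shape_y) envelope, the indirect algorithm the
    tilted-Beta form suggests; the two agree in distribution.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if method == "gamma_ratio":
        a = rng.gamma(post.shape_x, 1.0 / post.rate_x, size=n_draws)
        b = rng.gamma(post.shape_y, 1.0 / post.rate_y, size=n_draws)
        return a / (a + b)

    if method == "accept_reject":
        # target / envelope = (1 - z*r)^-(sx+sy); bounded by (1-z)^-(sx+sy)
        # for z in (0,1) (supremum at r -> 1) and by 1 for z <= 0.
        aexp = post.shape_x + post.shape_y
        z = post.z
        log_bound = -aexp * math.log1p(-z) if z > 0 else 0.0
        out = np.empty(n_draws)
        filled = 0
        while filled < n_draws:
            batch = max(2 * (n_draws - filled), 64)
            r = rng.beta(post.shape_x, post.shape_y, size=batch)
            log_accept = -aexp * np.log1p(-z * r) - log_bound
            keep = np.log(rng.uniform(size=batch)) <= log_accept
            kept = r[keep]
            take = min(kept.size, n_draws - filled)
            out[filled : filled + take] = kept[:take]
            filled += take
        return out

    raise ValueError("method must be 'gamma_ratio' or 'accept_reject'")
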