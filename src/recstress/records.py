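"""Lower record values: extraction, the s-th record density, and simulation.

In a sequence of i.i.d. continuous observations, an observation is a
*lower record* if it is strictly smaller than everything before it; the
first observation is a record by convention.  For an EG(alpha, lam)
parent, the transformed variable ``alpha * exp(-lam * X_s)`` of the s-th
lower record is the s-th arrival of a unit-rate Poisson process, i.e.
Gamma(s, 1) — which yields both the closed-form record density and an
exact O(n) simulation of a record sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaincc, gammaln

from .eg_model import EGParams

__all__ = [
    "LowerRecordSample",
    "extract_lower_records",
    "record_pdf",
    "record_cdf",
    "simulate_lower_records",
]


@dataclass(frozen=True)
class LowerRecordSample:
    """A strictly decreasing sequence of lower record values.

    Attributes
    ----------
    values : tuple of float
        The record values in occurrence order (strictly decreasing).
    source_length : int or None
        Length of the originating observation sequence, if known.
    """

    values: tuple
    source_length: int | None = field(default=None)

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 1:
            raise ValueError("a record sample holds at least one value")
        if any(b >= a for a, b in zip(vals, vals[1:])):
            raise ValueError("lower record values must be strictly decreasing")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def last(self) -> float:
        """The smallest (most recent) record value."""
        return self.values[-1]

    def to_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def extract_lower_records(seq) -> LowerRecordSample:
    """Extract the lower record values from an observation sequence.

    The first observation always opens the record list; a later value is
    a new record only if *strictly* below the running minimum (ties are
    not records).  Occurrence order is preserved.
    """
    seq = [float(v) for v in np.asarray(seq, dtype=float).ravel()]
    if len(seq) == 0:
        raise ValueError("cannot extract records from an empty sequence")
    records = [seq[0]]
    for v in seq[1:]:
        if v < records[-1]:
            records.append(v)
    return LowerRecordSample(values=tuple(records), source_length=len(seq))


def record_pdf(x, s: int, params: EGParams):
    """Density of the s-th lower record from EG(alpha, lam).

    f_{X_s}(x) = alpha^s * lam * exp(-s*lam*x - alpha*e^(-lam*x)) / Gamma(s);
    for s = 1 this is the parent EG density.
    """
    if s < 1:
        raise ValueError(f"record index s must be >= 1, got {s}")
    x = np.asarray(x, dtype=float)
    # inner = ln(alpha) - lam*x; clip before exponentiating so the far left
    # tail underflows to density 0 instead of overflowing
    inner = math.log(params.alpha) - params.lam * x
    logf = (
        -gammaln(s)
        + math.log(params.lam)
        + s * inner
        - np.exp(np.minimum(inner, 709.0))
    )
    out = np.exp(logf)
    return out if out.ndim else float(out)


def record_cdf(x, s: int, params: EGParams):
    """CDF of the s-th lower record: Q(s, alpha*e^(-lam x)).

    Follows from alpha*e^(-lam X_s) ~ Gamma(s, 1): the record falls below
    ``x`` exactly when the gamma arrival exceeds ``alpha*e^(-lam x)``, so the
    CDF is the upper regularized incomplete gamma function at that point.
    """
    if s < 1:
        raise ValueError(f"record index s must be >= 1, got {s}")
    x = np.asarray(x, dtype=float)
    inner = math.log(params.alpha) - params.lam * x
    out = gammaincc(s, np.exp(np.minimum(inner, 709.0)))
    return out if out.ndim else float(out)


def simulate_lower_records(n: int, params: EGParams, seed=None) -> LowerRecordSample:
    """Simulate the first ``n`` lower records of an EG(alpha, lam) sequence.

    Uses the gamma-arrival representation: with G_s the s-th cumulative
    sum of i.i.d. standard exponentials, X_s = -(1/lam) * ln(G_s / alpha)
    has exactly the joint law of the first n lower records.  Exact, O(n),
    no rejection loops.
    """
    if n < 1:
        raise ValueError(f"number of records must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    arrivals = np.cumsum(rng.standard_exponential(n))
    values = -(np.log(arrivals) - math.log(params.alpha)) / params.lam
    return LowerRecordSample(values=tuple(values))
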