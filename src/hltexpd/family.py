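"""Truncated T-X family composition.

A new lifetime law is generated by evaluating the cdf R of a *generator*
random variable T (supported on [0, inf)) at the cumulative hazard of a
left-truncated *base* variable X | X > tau:

    G(x) = R( H(x) ),   H(x) = -log(1 - F(x | x > tau)),
    g(x) = r( H(x) ) * h(x),

where h = f/(1-F) is the base hazard.  With an exponential base of rate
theta the composition collapses to the scale-location form

    g(x) = theta * r(theta * (x - a)),   x > a,

and with a half-logistic generator this yields the half logistic-truncated
exponential distribution implemented in :mod:`hltexpd.distribution`.

The exponential base uses the standard cdf 1 - exp(-theta*x); evaluators are
pure functions of x (samples here are tiny, no caching).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "TruncatedBase",
    "GeneratorDistribution",
    "cumulative_hazard",
    "composed_cdf",
    "composed_pdf",
    "compose_with_exponential",
    "half_logistic_generator",
    "exponential_base",
    "standard_exponential_generator",
]

# survival probabilities below this are treated as exactly 0 density
_SF_FLOOR = 1e-15


@dataclass(frozen=True)
class TruncatedBase:
    """Left-truncated base distribution X | X > tau.

    ``cdf``/``pdf`` are the *conditional* distribution and density on
    [tau, inf); cdf(tau) = 0 and cdf -> 1.
    """

    threshold: float
    cdf: Callable[[np.ndarray], np.ndarray]
    pdf: Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class GeneratorDistribution:
    """Generator variable T on [0, inf) with density ``pdf`` and cdf ``cdf``."""

    pdf: Callable[[np.ndarray], np.ndarray]
    cdf: Callable[[np.ndarray], np.ndarray]


def _check_domain(base: TruncatedBase, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < base.threshold):
        raise ValueError(
            f"x below the truncation threshold {base.threshold}"
        )
    return x


def cumulative_hazard(base: TruncatedBase, x):
    """H(x) = -log(1 - F(x | x > tau)); 0 at tau, nondecreasing.

    Returns +inf where the conditional cdf reaches 1.
    """
    x = _check_domain(base, x)
    sf = 1.0 - np.asarray(base.cdf(x), dtype=float)
    with np.errstate(divide="ignore"):
        out = -np.log(sf)
    return out if out.ndim else float(out)


def composed_cdf(gen: GeneratorDistribution, base: TruncatedBase, x):
    """cdf of the composed law, R(H(x))."""
    h = np.asarray(cumulative_hazard(base, x), dtype=float)
    out = np.where(np.isinf(h), 1.0, np.asarray(gen.cdf(np.where(np.isinf(h), 0.0, h)), dtype=float))
    return out if out.ndim else float(out)


def composed_pdf(gen: GeneratorDistribution, base: TruncatedBase, x):
    """Density of the composed law, r(H(x)) * f(x)/(1-F(x)).

    Where the base survival 1-F(x) has vanished (below 1e-15) the correct
    limit 0 is returned rather than a 0/0 ratio.
    """
    x = _check_domain(base, x)
    F = np.asarray(base.cdf(x), dtype=float)
    f = np.asarray(base.pdf(x), dtype=float)
    sf = 1.0 - F
    dead = sf <= _SF_FLOOR
    sf_safe = np.where(dead, 1.0, sf)
    with np.errstate(divide="ignore"):
        h = -np.log(sf_safe)
    out = np.where(dead, 0.0, np.asarray(gen.pdf(h), dtype=float) * f / sf_safe)
    return out if out.ndim else float(out)


def compose_with_exponential(gen: GeneratorDistribution, theta: float, a: float = 0.0):
    """Return the density x -> theta * r(theta*(x - a)) of the composed law
    with an exponential base of rate ``theta`` truncated at ``a``.

    Algebraically identical to :func:`composed_pdf` with
    ``exponential_base(theta, a)``: the exponential cumulative hazard is
    linear, H(x) = theta*(x-a), and its hazard is the constant theta.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")

    def density(x):
        x = np.asarray(x, dtype=float)
        out = np.where(x < a, 0.0, theta * np.asarray(gen.pdf(theta * (x - a)), dtype=float))
        return out if out.ndim else float(out)

    return density


def half_logistic_generator() -> GeneratorDistribution:
    """Standard half-logistic generator: r(t) = 2e^{-t}/(1+e^{-t})^2."""

    def pdf(t):
        t = np.asarray(t, dtype=float)
        e = np.exp(-t)
        return 2.0 * e / (1.0 + e) ** 2

    def cdf(t):
        t = np.asarray(t, dtype=float)
        e = np.exp(-t)
        return (1.0 - e) / (1.0 + e)

    return GeneratorDistribution(pdf=pdf, cdf=cdf)


def standard_exponential_generator() -> GeneratorDistribution:
    """Unit-rate exponential generator; composing it returns the base itself."""

    def pdf(t):
        return np.exp(-np.asarray(t, dtype=float))

    def cdf(t):
        return -np.expm1(-np.asarray(t, dtype=float))

    return GeneratorDistribution(pdf=pdf, cdf=cdf)


def exponential_base(theta: float, tau: float = 0.0) -> TruncatedBase:
    """Exponential base of rate ``theta`` left-truncated at ``tau``.

    By the memoryless property the conditional law is a shifted exponential:
    F(x | x > tau) = 1 - exp(-theta*(x - tau)).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")

    def cdf(x):
        x = np.asarray(x, dtype=float)
        return -np.expm1(-theta * (x - tau))

    def pdf(x):
        x = np.asarray(x, dtype=float)
        return theta * np.exp(-theta * (x - tau))

    return TruncatedBase(threshold=tau, cdf=cdf, pdf=pdf)
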