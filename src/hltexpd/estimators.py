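"""Scikit-learn style maximum-likelihood estimators for lifetime models.

Each estimator consumes a 1-d array (or single-column 2-d array) of positive
lifetimes via ``fit`` and exposes the fitted law through ``score_samples``
(per-observation log-density), ``score`` (total log-likelihood), ``sample``
and a frozen ``dist_`` object.  Fitted attributes carry the trailing
underscore; ``get_params``/``set_params``/``clone`` work as usual so the
estimators compose with sklearn model-selection utilities.

The half logistic-truncated exponential fit follows the profile scheme: the
threshold is fixed at the sample minimum (its MLE, since the density is
positive at the support edge) and the rate solves the one-dimensional score
equation

    n/theta - sum d_i + 2 sum d_i e^{-theta d_i} / (1 + e^{-theta d_i}) = 0,

d_i = x_i - a.  The score is strictly decreasing in theta with limits +inf
at 0+ and -sum d_i < 0, so the root is unique; it is bracketed starting from
the moment initialiser theta0 = log(4) / (mean - a) and solved by Brent's
method.  AIC/BIC use k = 1 (the rate; the threshold is treated as fixed at
the minimum).  Standard errors come from observed information.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .distribution import HalfLogisticTruncExp

__all__ = [
    "HalfLogisticTruncExpMLE",
    "ExponentialMLE",
    "TruncatedExponentialMLE",
]


def _validate_lifetimes(X, min_n: int = 1) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError("expected a 1-d array of lifetimes")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("lifetimes must be finite")
    return x


class _LifetimeMLE(BaseEstimator):
    """Shared plumbing: information criteria and sampling."""

    _n_params = 1  # k used in AIC/BIC

    def _finalize(self, n: int) -> None:
        self.n_obs_ = int(n)
        k = self._n_params
        self.aic_ = 2.0 * k - 2.0 * self.loglik_
        self.bic_ = k * np.log(n) - 2.0 * self.loglik_

    def score_samples(self, X):
        return self.dist_.logpdf(_validate_lifetimes(X))

    def score(self, X, y=None):
        """Total log-likelihood of ``X`` under the fitted law."""
        return float(np.sum(self.score_samples(X)))

    def sample(self, n_samples: int = 1, random_state=None):
        rng = np.random.default_rng(random_state)
        return self.dist_.ppf(rng.uniform(size=n_samples))


class HalfLogisticTruncExpMLE(_LifetimeMLE):
    """MLE of the half logistic-truncated exponential lifetime model.

    Parameters
    ----------
    tol : float
        Relative tolerance of the Brent root solve for the rate.

    Attributes
    ----------
    a_ : float
        Threshold estimate, the sample minimum.
    theta_ : float
        Rate estimate, root of the score equation.
    se_theta_ : float
        Observed-information standard error of ``theta_``.
    loglik_, aic_, bic_ : float
        Maximised log-likelihood and information criteria (k = 1).
    converged_ : bool
    n_iter_ : int
        Brent iterations used.
    dist_ : HalfLogisticTruncExp
        Frozen fitted distribution.
    """

    def __init__(self, tol: float = 1e-10):
        self.tol = tol

    @staticmethod
    def log_likelihood(theta: float, a: float, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        d = x - a
        if np.any(d < 0):
            raise ValueError("all observations must be >= a")
        n = d.size
        return float(
            n * np.log(2.0)
            + n * np.log(theta)
            - theta * d.sum()
            - 2.0 * np.log1p(np.exp(-theta * d)).sum()
        )

    @staticmethod
    def score_theta(theta: float, a: float, x: np.ndarray) -> float:
        """d/d(theta) of the log-likelihood at fixed threshold."""
        d = np.asarray(x, dtype=float) - a
        e = np.exp(-theta * d)
        return float(d.size / theta - d.sum() + 2.0 * np.sum(d * e / (1.0 + e)))

    @staticmethod
    def observed_information(theta: float, a: float, x: np.ndarray) -> float:
        """-d2/d(theta)2 log-likelihood = n/theta^2 + 2 sum d^2 e^{-td}/(1+e^{-td})^2."""
        d = np.asarray(x, dtype=float) - a
        e = np.exp(-theta * d)
        return float(d.size / theta**2 + 2.0 * np.sum(d**2 * e / (1.0 + e) ** 2))

    def fit(self, X, y=None):
        x = _validate_lifetimes(X, min_n=2)
        a = float(x.min())
        d = x - a
        if d.sum() <= 0:
            raise ValueError("degenerate sample: all observations are equal")

        # moment initialiser (model mean is a + log4/theta), then geometric
        # bracket expansion; the score decreases strictly in theta so one
        # sign change pins the unique root
        theta0 = 2.0 * np.log(2.0) / d.mean()
        lo, hi = theta0 / 10.0, theta0 * 10.0
        while self.score_theta(lo, a, x) <= 0:
            lo /= 10.0
        while self.score_theta(hi, a, x) >= 0:
            hi *= 10.0
        theta, res = optimize.brentq(
            self.score_theta, lo, hi, args=(a, x), rtol=self.tol, full_output=True
        )

        self.a_ = a
        self.theta_ = float(theta)
        self.converged_ = bool(res.converged)
        self.n_iter_ = int(res.iterations)
        self.loglik_ = self.log_likelihood(theta, a, x)
        self.se_theta_ = 1.0 / np.sqrt(self.observed_information(theta, a, x))
        self.dist_ = HalfLogisticTruncExp(a=a, theta=theta)
        self._finalize(x.size)
        return self


class ExponentialMLE(_LifetimeMLE):
    """Exponential baseline: rate = n / sum(x), closed form."""

    def fit(self, X, y=None):
        x = _validate_lifetimes(X, min_n=1)
        if np.any(x <= 0):
            raise ValueError("exponential fit requires strictly positive data")
        n = x.size
        rate = n / x.sum()
        self.rate_ = float(rate)
        self.se_rate_ = float(rate / np.sqrt(n))
        self.loglik_ = float(n * np.log(rate) - rate * x.sum())
        self.converged_ = True
        self.n_iter_ = 0
        self.dist_ = stats.expon(scale=1.0 / rate)
        self._finalize(n)
        return self


class TruncatedExponentialMLE(_LifetimeMLE):
    """Shifted (left-truncated) exponential baseline.

    Threshold at the sample minimum, rate = n / sum(x - min); k = 1 in the
    information criteria, matching the half-logistic fit's convention.
    """

    def fit(self, X, y=None):
        x = _validate_lifetimes(X, min_n=2)
        a = float(x.min())
        d = x - a
        if d.sum() <= 0:
            raise ValueError("degenerate sample: all observations are equal")
        n = x.size
        rate = n / d.sum()
        self.a_ = a
        self.rate_ = float(rate)
        self.se_rate_ = float(rate / np.sqrt(n))
        self.loglik_ = float(n * np.log(rate) - rate * d.sum())
        self.converged_ = True
        self.n_iter_ = 0
        self.dist_ = stats.expon(loc=a, scale=1.0 / rate)
        self._finalize(n)
        return self
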