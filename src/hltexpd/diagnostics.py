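"""Model-fit and failure-rate-shape diagnostics.

Numeric series behind the standard reliability plots: the scaled total-time-
on-test (TTT) transform, probability-probability and quantile-quantile
pairs against a fitted law, and the empirical cdf.  Plotting positions:
the ecdf and P-P use i/n, Q-Q uses (i - 0.5)/n.  Rendering is left to the
caller; the tested artifact is the numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.distributions.empirical_distribution import ECDF

__all__ = ["TTTCurve", "ttt_curve", "pp_points", "qq_points", "ecdf_series"]


@dataclass(frozen=True)
class TTTCurve:
    """Scaled total-time-on-test coordinates.

    ``u[i] = i/n`` and ``t[i]`` is the scaled TTT statistic; a concave curve
    indicates an increasing failure rate, the diagonal a constant one.
    """

    u: np.ndarray
    t: np.ndarray


def ttt_curve(values) -> TTTCurve:
    """Scaled TTT transform of a lifetime sample.

    With order statistics x_(1) <= ... <= x_(n):

        T_i = [ sum_{j<=i} x_(j) + (n - i) x_(i) ] / sum_j x_(j),  T_0 = 0.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("TTT requires at least 2 observations")
    if np.any(x < 0):
        raise ValueError("TTT requires nonnegative lifetimes")
    total = x.sum()
    if total <= 0:
        raise ValueError("degenerate all-zero sample")
    csum = np.cumsum(x)
    i = np.arange(1, n + 1)
    t = (csum + (n - i) * x) / total
    return TTTCurve(
        u=np.concatenate(([0.0], i / n)),
        t=np.concatenate(([0.0], t)),
    )


def pp_points(fit, values):
    """P-P pairs: (empirical cdf i/n, fitted cdf) at the order statistics.

    ``fit`` is a :class:`~hltexpd.estimation.FitResult` (its frozen ``dist``
    is used) or any object exposing ``cdf``.
    """
    dist = getattr(fit, "dist", fit)
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    emp = np.arange(1, n + 1) / n
    return np.column_stack([emp, np.asarray(dist.cdf(x), dtype=float)])


def qq_points(fit, values):
    """Q-Q pairs: (model quantile at (i-0.5)/n, order statistic x_(i))."""
    dist = getattr(fit, "dist", fit)
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    p = (np.arange(1, n + 1) - 0.5) / n
    return np.column_stack([np.asarray(dist.ppf(p), dtype=float), x])


def ecdf_series(values):
    """Right-continuous empirical cdf.

    Returns a callable (vectorised) with ``.x``/``.y`` step coordinates.
    """
    return ECDF(np.asarray(values, dtype=float), side="right")
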