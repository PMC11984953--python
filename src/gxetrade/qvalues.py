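"""Storey q-values with smoothed estimation of the null proportion pi0.

pi0 is estimated as pi0(lambda) = #{p > lambda} / (N (1 - lambda)) over a
lambda grid, smoothed with a cubic spline and read off at the largest
lambda; q-values are the step-down minima q_(i) = min_{j >= i}
pi0 * p_(j) * N / j in sorted order.  Forcing pi0 = 1 recovers the
Benjamini-Hochberg adjusted p-values exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

__all__ = ["QValueResult", "estimate_pi0", "compute_qvalues"]

_PI0_FLOOR = 1e-8
DEFAULT_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


@dataclass(frozen=True)
class QValueResult:
    qvalues: np.ndarray
    pi0: float


def _validate(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not np.isfinite(p).all() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in (0, 1]")
    return p


def estimate_pi0(pvalues, lambda_grid=None) -> float:
    """Estimate the proportion of true nulls among the p-values.

    Uses the Storey-Tibshirani smoother: a cubic spline through
    pi0(lambda) evaluated at the largest grid value.  Falls back to the
    single point lambda = 0.5 for short vectors (< 100), where the
    spline is unstable; a warning is emitted there.  The estimate is
    clamped to [1e-8, 1].
    """
    p = _validate(pvalues)
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.ndim != 1 or lam.size == 0 or (lam <= 0).any() or (lam >= 1).any():
        raise ValueError("lambda grid values must lie in (0, 1)")
    lam = np.sort(lam)
    n = p.size
    if n < 100:
        warnings.warn(
            f"only {n} p-values; pi0 estimated at fixed lambda=0.5", stacklevel=2
        )
        pi0 = np.mean(p > 0.5) / 0.5
    elif lam.size < 4:
        pi0 = np.mean(p > lam[-1]) / (1.0 - lam[-1])
    else:
        pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
        spline = UnivariateSpline(lam, pi0_lam, k=3)
        pi0 = float(spline(lam[-1]))
    return float(np.clip(pi0, _PI0_FLOOR, 1.0))


def compute_qvalues(pvalues, lambda_grid=None, pi0: float | None = None) -> QValueResult:
    """q-values in the input order, plus the pi0 estimate used.

    Parameters
    ----------
    pi0 : float, optional
        Override the estimated null proportion (``pi0=1`` yields BH
        adjusted p-values).
    """
    p = _validate(pvalues)
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid)
    elif not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return QValueResult(qvalues=q, pi0=float(pi0))
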