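"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["mvn_draw"]


def mvn_draw(mean, cov, size: int, rng: np.random.Generator) -> np.ndarray:
    """Multivariate normal draws that stay exact for singular covariances.

    Uses the eigendecomposition and drops (numerically) zero modes, so a
    rank-1 covariance yields draws lying exactly on its line — perfect
    cross-context correlation holds to machine precision, which matters
    for amplification components.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    vals, vecs = np.linalg.eigh(cov)
    tol = max(vals.max(), 0.0) * 1e-12
    if vals.min() < -tol:
        raise ValueError("covariance matrix is not positive semidefinite")
    keep = vals > tol
    root = vecs[:, keep] * np.sqrt(vals[keep])
    z = rng.standard_normal((size, int(keep.sum())))
    return mean + z @ root.T
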