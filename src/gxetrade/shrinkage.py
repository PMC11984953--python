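"""Empirical-Bayes shrinkage of two-context effect estimates ("mash-lite").

The model follows the multivariate adaptive shrinkage (mash) idea: the
true effect pair (beta_A, beta_B) of variant j is drawn from a mixture of
zero-centered bivariate normals,

    beta_j ~ sum_k pi_k * Normal(0, U_k),

over a fixed grid of covariance components U_k that encode canonical
modes of cross-context sharing (null, equal effects, context-specific,
independent, amplification), and the observed estimates are
beta_hat_j ~ Normal(beta_j, S_j) with known S_j = diag(se_j^2).  The
mixture weights pi are fit by maximum likelihood with EM on the marginal
likelihood; the fitted mixture then acts as a prior, giving per-variant
posterior means that regress estimates toward the commonly observed
patterns of covariance.

Only the weights are estimated — the components are a fixed grid — so
the fit is deterministic given the data.  A univariate variant of the
same machinery (:func:`shrink_univariate`) serves for shrinking a single
column of effect estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CovarianceGrid",
    "MixtureFit",
    "PosteriorPanel",
    "build_canonical_grid",
    "CovarianceMixtureModel",
    "CovarianceMixtureResults",
    "fit_mixture_em",
    "posterior_means",
    "shrink_univariate",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class CovarianceGrid:
    """Labelled 2x2 PSD prior-covariance components, always incl. the null."""

    components: np.ndarray  # (K, 2, 2)
    labels: tuple[str, ...]

    def __post_init__(self):
        comps = np.asarray(self.components, dtype=float)
        if comps.ndim != 3 or comps.shape[1:] != (2, 2):
            raise ValueError("components must be a (K, 2, 2) array")
        if len(self.labels) != comps.shape[0]:
            raise ValueError("one label per component required")
        for k, u in enumerate(comps):
            if not np.allclose(u, u.T):
                raise ValueError(f"component {self.labels[k]!r} is not symmetric")
            if np.linalg.eigvalsh(u).min() < -1e-10:
                raise ValueError(f"component {self.labels[k]!r} is not PSD")
        if not any(np.all(u == 0) for u in comps):
            raise ValueError("grid must include the zero (null) matrix")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self):
        return self.components.shape[0]


def build_canonical_grid(
    scales=(1.0,),
    amplification_factors=(1.5, 2.0, 1 / 1.5, 0.5),
) -> CovarianceGrid:
    """Canonical grid: null + sharing patterns at each prior scale.

    Per scale s: equal effects [[s,s],[s,s]]; A-specific; B-specific;
    independent s*I; and rank-1 amplification [[s*a^2, s*a], [s*a, s]]
    for each factor a (perfect correlation, sd ratio a).  The null
    matrix appears once.
    """
    scales = tuple(float(s) for s in scales)
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    comps = [np.zeros((2, 2))]
    labels = ["null"]
    for s in scales:
        tag = f"@{s:g}" if len(scales) > 1 else ""
        comps.append(np.full((2, 2), s))
        labels.append(f"equal{tag}")
        comps.append(np.array([[s, 0.0], [0.0, 0.0]]))
        labels.append(f"A_specific{tag}")
        comps.append(np.array([[0.0, 0.0], [0.0, s]]))
        labels.append(f"B_specific{tag}")
        comps.append(s * np.eye(2))
        labels.append(f"independent{tag}")
        for a in amplification_factors:
            comps.append(s * np.array([[a * a, a], [a, 1.0]]))
            labels.append(f"amp_{a:g}x{tag}")
    return CovarianceGrid(np.array(comps), tuple(labels))


@dataclass(frozen=True)
class MixtureFit:
    """Fitted mixture weights with the EM log-likelihood trace."""

    weights: np.ndarray
    log_likelihood_trace: np.ndarray
    converged: bool

    @property
    def n_iter(self) -> int:
        return len(self.log_likelihood_trace)


@dataclass(frozen=True)
class PosteriorPanel:
    """Per-variant posterior summaries under the fitted mixture prior."""

    posterior_means: np.ndarray  # (J, 2)
    posterior_sds: np.ndarray  # (J, 2)
    responsibilities: np.ndarray  # (J, K)

    def top_component(self, grid: CovarianceGrid) -> np.ndarray:
        """Label of the most responsible component per variant."""
        idx = np.argmax(self.responsibilities, axis=1)
        return np.asarray(grid.labels)[idx]


def _validate_panel(estimates, ses):
    b = np.atleast_2d(np.asarray(estimates, dtype=float))
    s = np.atleast_2d(np.asarray(ses, dtype=float))
    if b.shape != s.shape or b.shape[1] != 2:
        raise ValueError("estimates and ses must both be (J, 2)")
    if not np.isfinite(b).all():
        raise ValueError("estimates must be finite")
    if not ((s > 0) & np.isfinite(s)).all():
        raise ValueError("standard errors must be positive and finite")
    return b, s


def _log_lik_matrix(b: np.ndarray, s: np.ndarray, comps: np.ndarray) -> np.ndarray:
    """log Normal(b_j; 0, U_k + diag(s_j^2)) for all j, k — closed-form 2x2."""
    J = b.shape[0]
    K = comps.shape[0]
    s2 = s**2
    out = np.empty((J, K))
    for k in range(K):
        u = comps[k]
        a00 = u[0, 0] + s2[:, 0]
        a11 = u[1, 1] + s2[:, 1]
        a01 = np.full(J, u[0, 1])
        det = a00 * a11 - a01**2
        # quadratic form b' Sigma^{-1} b via the 2x2 adjugate
        quad = (a11 * b[:, 0] ** 2 - 2.0 * a01 * b[:, 0] * b[:, 1] + a00 * b[:, 1] ** 2) / det
        out[:, k] = -_LOG2PI - 0.5 * np.log(det) - 0.5 * quad
    if not np.isfinite(out).all():
        bad = int(np.argwhere(~np.isfinite(out).all(axis=1))[0, 0])
        raise FloatingPointError(f"non-finite marginal likelihood at variant row {bad}")
    return out


def _em(log_lik: np.ndarray, tol: float, max_iter: int):
    """EM over mixture weights given a fixed (J, K) log-likelihood matrix."""
    J, K = log_lik.shape
    log_pi = np.full(K, -np.log(K))
    trace = []
    gamma = None
    converged = False
    for _ in range(max_iter):
        z = log_lik + log_pi
        zmax = z.max(axis=1, keepdims=True)
        w = np.exp(z - zmax)
        norm = w.sum(axis=1, keepdims=True)
        gamma = w / norm
        ll = float(np.sum(zmax.ravel() + np.log(norm.ravel())))
        if trace and ll - trace[-1] < tol * (abs(trace[-1]) + 1.0):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        pi = gamma.mean(axis=0)
        with np.errstate(divide="ignore"):
            log_pi = np.log(pi)
    pi = np.exp(log_pi)
    pi = pi / pi.sum()
    return pi, np.asarray(trace), gamma, converged


def fit_mixture_em(
    estimates, ses, grid: CovarianceGrid, tol: float = 1e-6, max_iter: int = 1000
) -> MixtureFit:
    """Maximum-likelihood mixture weights over the covariance grid.

    EM from uniform starting weights; the M-step sets each weight to the
    mean responsibility.  Stops when the relative log-likelihood gain
    drops below ``tol``.
    """
    b, s = _validate_panel(estimates, ses)
    log_lik = _log_lik_matrix(b, s, grid.components)
    pi, trace, _, converged = _em(log_lik, tol, max_iter)
    return MixtureFit(weights=pi, log_likelihood_trace=trace, converged=converged)


def posterior_means(estimates, ses, grid: CovarianceGrid, fit: MixtureFit) -> PosteriorPanel:
    """Posterior means/sds of the true effects under the fitted prior.

    Per variant j and component k the posterior is normal with mean
    U_k (U_k + S_j)^{-1} beta_hat_j and covariance
    U_k - U_k (U_k + S_j)^{-1} U_k; the mixture posterior combines them
    with the responsibilities gamma_jk ∝ pi_k L_jk.
    """
    b, s = _validate_panel(estimates, ses)
    comps = grid.components
    log_lik = _log_lik_matrix(b, s, comps)
    with np.errstate(divide="ignore"):
        z = log_lik + np.log(fit.weights)
    z -= z.max(axis=1, keepdims=True)
    gamma = np.exp(z)
    gamma /= gamma.sum(axis=1, keepdims=True)

    J = b.shape[0]
    s2 = s**2
    mean = np.zeros((J, 2))
    second = np.zeros((J, 2))  # E[beta^2] accumulator, per coordinate
    for k in range(comps.shape[0]):
        u = comps[k]
        a00 = u[0, 0] + s2[:, 0]
        a11 = u[1, 1] + s2[:, 1]
        a01 = u[0, 1]
        det = a00 * a11 - a01**2
        # rows of U (U + S)^{-1}:  inv = adj / det
        i00, i01, i11 = a11 / det, -a01 / det, a00 / det
        t00 = u[0, 0] * i00 + u[0, 1] * i01
        t01 = u[0, 0] * i01 + u[0, 1] * i11
        t10 = u[1, 0] * i00 + u[1, 1] * i01
        t11 = u[1, 0] * i01 + u[1, 1] * i11
        mu0 = t00 * b[:, 0] + t01 * b[:, 1]
        mu1 = t10 * b[:, 0] + t11 * b[:, 1]
        # posterior covariance diagonal: U - U (U+S)^{-1} U
        c0 = u[0, 0] - (t00 * u[0, 0] + t01 * u[1, 0])
        c1 = u[1, 1] - (t10 * u[0, 1] + t11 * u[1, 1])
        g = gamma[:, k]
        mean[:, 0] += g * mu0
        mean[:, 1] += g * mu1
        second[:, 0] += g * (c0 + mu0**2)
        second[:, 1] += g * (c1 + mu1**2)
    var = np.maximum(second - mean**2, 0.0)
    return PosteriorPanel(
        posterior_means=mean, posterior_sds=np.sqrt(var), responsibilities=gamma
    )


def pseudo_pvalues(panel: PosteriorPanel) -> np.ndarray:
    """Two-sided tail probabilities 2*Phi(-|mean|/sd) from the posteriors.

    An interpretive device for ranking variants by posterior evidence of
    a non-zero effect, mirroring p-value-based ascertainment; where the
    posterior sd is zero the value is 1 for a zero mean and 0 otherwise.
    """
    from scipy.stats import norm

    m = panel.posterior_means
    sd = panel.posterior_sds
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(m) / sd
    z[(sd == 0) & (m == 0)] = 0.0
    z[(sd == 0) & (m != 0)] = np.inf
    return 2.0 * norm.sf(z)


class CovarianceMixtureModel:
    """Empirical-Bayes mixture model for a J x 2 panel of effect estimates.

    Parameters
    ----------
    estimates, ses : (J, 2) arrays
        Per-context effect estimates and their standard errors.
    grid : CovarianceGrid, optional
        Prior covariance components; defaults to the canonical grid
        scaled by the data (median squared z-broadened estimate).
    """

    def __init__(self, estimates, ses, grid: CovarianceGrid | None = None):
        self.estimates, self.ses = _validate_panel(estimates, ses)
        if grid is None:
            grid = build_canonical_grid(scales=self._default_scales())
        self.grid = grid

    def _default_scales(self) -> tuple[float, ...]:
        # geometric ladder bracketing the apparent signal variance
        excess = np.maximum(self.estimates**2 - self.ses**2, 0.0).mean()
        base = max(float(excess), float(np.median(self.ses**2)))
        return tuple(base * 4.0**e for e in (-2, -1, 0, 1))

    @classmethod
    def from_dataframe(cls, data, grid: CovarianceGrid | None = None):
        """Build from a summary-stat table with beta_a/se_a/beta_b/se_b columns."""
        est = data[["beta_a", "beta_b"]].to_numpy(float)
        ses = data[["se_a", "se_b"]].to_numpy(float)
        return cls(est, ses, grid)

    def fit(self, tol: float = 1e-6, max_iter: int = 1000) -> "CovarianceMixtureResults":
        mix = fit_mixture_em(self.estimates, self.ses, self.grid, tol, max_iter)
        panel = posterior_means(self.estimates, self.ses, self.grid, mix)
        return CovarianceMixtureResults(self, mix, panel)


class CovarianceMixtureResults:
    """Fitted mixture weights and per-variant posterior effects."""

    def __init__(self, model: CovarianceMixtureModel, mixture: MixtureFit, panel: PosteriorPanel):
        self.model = model
        self.mixture = mixture
        self.panel = panel

    @property
    def weights(self) -> np.ndarray:
        return self.mixture.weights

    @property
    def posterior_means(self) -> np.ndarray:
        return self.panel.posterior_means

    @property
    def posterior_sds(self) -> np.ndarray:
        return self.panel.posterior_sds

    @property
    def log_likelihood(self) -> float:
        return float(self.mixture.log_likelihood_trace[-1])

    def pseudo_pvalues(self) -> np.ndarray:
        return pseudo_pvalues(self.panel)

    def summary(self) -> str:
        lines = [
            "Covariance-mixture shrinkage fit",
            "=" * 46,
            f"variants: {self.model.estimates.shape[0]}   components: {len(self.model.grid)}",
            f"log-likelihood: {self.log_likelihood:.2f}   EM iters: {self.mixture.n_iter}"
            f"   converged: {self.mixture.converged}",
            "-" * 46,
            f"{'component':<22s}{'weight':>10s}",
        ]
        order = np.argsort(self.weights)[::-1]
        for k in order:
            if self.weights[k] < 1e-4:
                continue
            lines.append(f"{self.model.grid.labels[k]:<22s}{self.weights[k]:>10.4f}")
        return "\n".join(lines)

    def __repr__(self):
        top = self.model.grid.labels[int(np.argmax(self.weights))]
        return f"<CovarianceMixtureResults loglik={self.log_likelihood:.1f} top={top!r}>"


def shrink_univariate(
    estimates,
    ses,
    scale_grid=None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    return_sd: bool = False,
):
    """Shrink one column of estimates with a univariate normal mixture prior.

    Components are zero-centered normals with variances ``scale_grid``
    plus a point mass at zero; weights are fit by the same EM as the
    bivariate model, and the returned values are mixture posterior
    means.  With only a diffuse component the map is the identity; with
    the two-component grid {0, s} it is a strict contraction.  With
    ``return_sd=True`` the mixture posterior standard deviations are
    returned as well (so mean**2 + sd**2 is the posterior second
    moment, the natural estimate of the squared true effect).
    """
    b = np.asarray(estimates, dtype=float).ravel()
    s = np.asarray(ses, dtype=float).ravel()
    if b.shape != s.shape:
        raise ValueError("estimates and ses must have equal length")
    if not ((s > 0) & np.isfinite(s)).all() or not np.isfinite(b).all():
        raise ValueError("inputs must be finite with positive ses")
    if scale_grid is None:
        excess = max(float(np.mean(np.maximum(b**2 - s**2, 0.0))), float(np.median(s**2)))
        scale_grid = [excess * 4.0**e for e in (-2, -1, 0, 1)]
    v = np.concatenate([[0.0], np.asarray(scale_grid, dtype=float)])
    if (v < 0).any():
        raise ValueError("scale grid must be non-negative")
    tot = v[None, :] + (s**2)[:, None]
    log_lik = -0.5 * (_LOG2PI + np.log(tot) + (b**2)[:, None] / tot)
    pi, _, _, _ = _em(log_lik, tol, max_iter)
    with np.errstate(divide="ignore"):
        z = log_lik + np.log(pi)
    z -= z.max(axis=1, keepdims=True)
    gamma = np.exp(z)
    gamma /= gamma.sum(axis=1, keepdims=True)
    shrink_factor = v[None, :] / tot
    comp_mean = shrink_factor * b[:, None]
    mean = (gamma * comp_mean).sum(axis=1)
    if not return_sd:
        return mean
    comp_var = shrink_factor * (s**2)[:, None]  # v - v^2/(v+s^2) = v s^2/(v+s^2)
    second = (gamma * (comp_var + comp_mean**2)).sum(axis=1)
    return mean, np.sqrt(np.maximum(second - mean**2, 0.0))
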