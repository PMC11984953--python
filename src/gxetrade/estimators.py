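"""Single-locus OLS estimation of allelic effects in two contexts.

The generative model is a biallelic, autosomal variant with genotype
g in {0, 1, 2} and a continuous trait observed in one of two contexts,
A and B::

    y_i ~ Normal(alpha_A + beta_A * g_i, sigma2_A)   for i in context A
    y_i ~ Normal(alpha_B + beta_B * g_i, sigma2_B)   for i in context B

Two competing estimators of the context-specific effects are provided:

* the **GxE (stratified) estimator** — separate OLS within each context;
  unbiased for beta_A and beta_B, with sampling variances
  V_A = sigma2_A / S_A and V_B = sigma2_B / S_B, where
  S = sum((g - gbar)^2) within context;
* the **additive (pooled) estimator** — a single OLS over all n + m
  individuals, ignoring context; for within-context mean-centered traits
  it is exactly the omega-weighted combination of the stratified slopes,

      beta_pooled = omega_A * beta_A_hat + omega_B * beta_B_hat,

  with omega_A = S_A / S_pooled and omega_B = S_B / S_pooled, so that
  omega_A : omega_B = n * H_A : m * H_B, with H the per-context sample
  heterozygosity (genotypic variance sum((g - gbar)^2) / count).

`StratifiedEffectModel` is the statsmodels-style entry point: construct
it from individual-level data (or a tidy DataFrame via
:meth:`StratifiedEffectModel.from_dataframe`) and call :meth:`fit`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "MonomorphicError",
    "StratifiedSample",
    "EffectEstimate",
    "PooledWeights",
    "StratifiedEffectModel",
    "StratifiedEffectResults",
    "center_within_context",
    "ols_stratified",
    "ols_additive",
    "combination_weights",
]


class MonomorphicError(ValueError):
    """Raised when OLS is requested at a locus with no genotypic variance.

    Carries ``context``: "A", "B" or "pooled".
    """

    def __init__(self, context: str):
        self.context = context
        super().__init__(
            f"genotypes are monomorphic in context {context!r}; "
            "the slope is not identifiable"
        )


@dataclass(frozen=True)
class StratifiedSample:
    """Genotypes, traits and context labels at one biallelic locus.

    Parameters
    ----------
    genotypes : array of int
        Reference-allele counts in {0, 1, 2}, one per individual.
    traits : array of float
        Continuous trait values (trait units).
    context : array
        Label "A" or "B" per individual.
    """

    genotypes: np.ndarray
    traits: np.ndarray
    context: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.genotypes)
        y = np.asarray(self.traits, dtype=float)
        c = np.asarray(self.context)
        if not (g.shape == y.shape == c.shape) or g.ndim != 1:
            raise ValueError("genotypes, traits and context must be equal-length 1-d arrays")
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError("genotypes must be allele counts in {0, 1, 2}")
        if not np.isin(c, ("A", "B")).all():
            raise ValueError("context labels must be 'A' or 'B'")
        if not np.isfinite(y).all():
            raise ValueError("traits must be finite")
        object.__setattr__(self, "genotypes", g.astype(np.int64))
        object.__setattr__(self, "traits", y)
        object.__setattr__(self, "context", c.astype("U1"))

    @property
    def mask_a(self) -> np.ndarray:
        return self.context == "A"

    @property
    def n(self) -> int:
        """Number of individuals in context A."""
        return int(self.mask_a.sum())

    @property
    def m(self) -> int:
        """Number of individuals in context B."""
        return int(self.genotypes.size - self.n)

    def split(self) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
        """Return ((g_A, y_A), (g_B, y_B))."""
        a = self.mask_a
        return (self.genotypes[a], self.traits[a]), (self.genotypes[~a], self.traits[~a])


@dataclass(frozen=True)
class EffectEstimate:
    """An OLS slope with its sampling uncertainty.

    ``sampling_variance`` is V = residual_variance / sum((g - gbar)^2),
    the exact OLS sampling variance of the slope under the within-context
    normal model.
    """

    slope: float
    intercept: float
    sampling_variance: float
    residual_variance: float
    n_used: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.sampling_variance))


@dataclass(frozen=True)
class PooledWeights:
    """Weights relating the pooled slope to the stratified slopes.

    omega_a = S_A / S_pooled and omega_b = S_B / S_pooled where S is the
    centered genotype sum of squares; omega_a/omega_b = (n H_A)/(m H_B)
    holds exactly, and omega_a + omega_b <= 1 with equality iff the
    context genotype means coincide.
    """

    omega_a: float
    omega_b: float
    het_a: float
    het_b: float
    freq_a: float
    freq_b: float


def _context_arrays(sample: StratifiedSample):
    (ga, ya), (gb, yb) = sample.split()
    if ga.size == 0 or gb.size == 0:
        raise ValueError("both contexts must be non-empty")
    return ga, ya, gb, yb


def center_within_context(sample: StratifiedSample) -> StratifiedSample:
    """Subtract the per-context trait mean; genotypes are untouched.

    Mean-centering within context is inconsequential for the stratified
    slopes but is the precondition for the exact omega-weighted
    combination identity of the pooled slope.
    """
    ga, ya, gb, yb = _context_arrays(sample)
    y = sample.traits.copy()
    a = sample.mask_a
    y[a] = ya - ya.mean()
    y[~a] = yb - yb.mean()
    return replace(sample, traits=y)


def _ols_1d(g: np.ndarray, y: np.ndarray, context: str) -> EffectEstimate:
    g = np.asarray(g, dtype=float)
    gbar = g.mean()
    sxx = float(np.sum((g - gbar) ** 2))
    if sxx == 0.0:
        raise MonomorphicError(context)
    slope = float(np.sum((g - gbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * gbar)
    resid = y - intercept - slope * g
    dof = max(g.size - 2, 1)
    sigma2 = float(np.sum(resid**2) / dof)
    return EffectEstimate(
        slope=slope,
        intercept=intercept,
        sampling_variance=sigma2 / sxx,
        residual_variance=sigma2,
        n_used=int(g.size),
    )


def ols_stratified(sample: StratifiedSample) -> tuple[EffectEstimate, EffectEstimate]:
    """Per-context OLS slopes (the GxE estimator).

    Raises
    ------
    MonomorphicError
        If either context has no genotypic variance; ``.context`` names
        the offending context.
    """
    ga, ya, gb, yb = _context_arrays(sample)
    if ga.size < 2 or gb.size < 2:
        raise ValueError("need at least 2 individuals per context for stratified OLS")
    return _ols_1d(ga, ya, "A"), _ols_1d(gb, yb, "B")


def ols_additive(sample: StratifiedSample) -> EffectEstimate:
    """Pooled OLS slope over all individuals (the additive estimator)."""
    g = sample.genotypes.astype(float)
    if np.ptp(g) == 0:
        raise MonomorphicError("pooled")
    return _ols_1d(g, sample.traits, "pooled")


def combination_weights(sample: StratifiedSample) -> PooledWeights:
    """omega-weights expressing the pooled slope in the stratified slopes.

    omega_A = sum_A (g - gbar_A)^2 / sum_all (g - gbar_pooled)^2 and
    analogously for B.
    """
    ga, _, gb, _ = _context_arrays(sample)
    g = sample.genotypes.astype(float)
    s_pool = float(np.sum((g - g.mean()) ** 2))
    if s_pool == 0.0:
        raise MonomorphicError("pooled")
    s_a = float(np.sum((ga - ga.mean()) ** 2))
    s_b = float(np.sum((gb - gb.mean()) ** 2))
    return PooledWeights(
        omega_a=s_a / s_pool,
        omega_b=s_b / s_pool,
        het_a=s_a / ga.size,
        het_b=s_b / gb.size,
        freq_a=float(ga.mean() / 2.0),
        freq_b=float(gb.mean() / 2.0),
    )


class StratifiedEffectModel:
    """Two-context allelic-effect model at a single locus.

    Fits, by OLS, both the stratified (GxE) and the pooled (additive)
    estimators of the allelic effect, after mean-centering the trait
    within context. The returned results object carries the estimates,
    their sampling variances, the omega-weights, and the bias-variance
    decision diagnostics.

    Parameters
    ----------
    genotypes, traits, context : array-like
        Individual-level data; see :class:`StratifiedSample`.

    Examples
    --------
    >>> model = StratifiedEffectModel([0, 1, 2, 0, 1, 2],
    ...                               [0.0, 0.5, 1.0, 0.1, 0.8, 1.9],
    ...                               ["A", "A", "A", "B", "B", "B"])
    >>> res = model.fit()
    >>> res.beta_a  # doctest: +ELLIPSIS
    0.5...
    """

    def __init__(self, genotypes: Iterable, traits: Iterable, context: Iterable):
        raw = StratifiedSample(
            np.asarray(list(genotypes) if not isinstance(genotypes, np.ndarray) else genotypes),
            np.asarray(list(traits) if not isinstance(traits, np.ndarray) else traits, dtype=float),
            np.asarray(list(context) if not isinstance(context, np.ndarray) else context),
        )
        self.sample = center_within_context(raw)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        genotype: str = "genotype",
        trait: str = "trait",
        context: str = "context",
    ) -> "StratifiedEffectModel":
        """Build the model from a tidy table with one row per individual."""
        return cls(data[genotype].to_numpy(), data[trait].to_numpy(), data[context].to_numpy())

    def fit(self) -> "StratifiedEffectResults":
        est_a, est_b = ols_stratified(self.sample)
        est_pooled = ols_additive(self.sample)
        weights = combination_weights(self.sample)
        return StratifiedEffectResults(self, est_a, est_b, est_pooled, weights)


class StratifiedEffectResults:
    """Fitted stratified and pooled estimates at one locus."""

    def __init__(self, model, est_a, est_b, est_pooled, weights):
        self.model = model
        self.stratified_a = est_a
        self.stratified_b = est_b
        self.pooled = est_pooled
        self.weights = weights

    # convenience accessors -------------------------------------------------
    @property
    def beta_a(self) -> float:
        return self.stratified_a.slope

    @property
    def beta_b(self) -> float:
        return self.stratified_b.slope

    @property
    def beta_pooled(self) -> float:
        return self.pooled.slope

    @property
    def var_a(self) -> float:
        return self.stratified_a.sampling_variance

    @property
    def var_b(self) -> float:
        return self.stratified_b.sampling_variance

    def decision(self, focal: str = "A"):
        """Plug-in bias-variance verdict for the focal context.

        Uses the stratified point estimates as plug-ins for the true
        effects; see :func:`gxetrade.decision.mse_pair` for the rule.
        """
        from .decision import DecisionInput, mse_pair

        if focal not in ("A", "B"):
            raise ValueError("focal must be 'A' or 'B'")
        w = self.weights
        if focal == "A":
            inp = DecisionInput(self.beta_a, self.beta_b, self.var_a, self.var_b,
                                w.omega_a, w.omega_b)
        else:
            inp = DecisionInput(self.beta_b, self.beta_a, self.var_b, self.var_a,
                                w.omega_b, w.omega_a)
        return mse_pair(inp)

    def summary(self) -> str:
        w = self.weights
        dec = self.decision("A")
        lines = [
            "Two-context allelic effect estimates (trait units per allele)",
            "=" * 62,
            f"{'':14s}{'slope':>12s}{'se':>12s}{'resid var':>12s}{'n':>8s}",
            f"{'GxE (A)':14s}{self.beta_a:12.4g}{self.stratified_a.se:12.4g}"
            f"{self.stratified_a.residual_variance:12.4g}{self.stratified_a.n_used:8d}",
            f"{'GxE (B)':14s}{self.beta_b:12.4g}{self.stratified_b.se:12.4g}"
            f"{self.stratified_b.residual_variance:12.4g}{self.stratified_b.n_used:8d}",
            f"{'additive':14s}{self.beta_pooled:12.4g}{self.pooled.se:12.4g}"
            f"{self.pooled.residual_variance:12.4g}{self.pooled.n_used:8d}",
            "-" * 62,
            f"omega_A = {w.omega_a:.4f}  omega_B = {w.omega_b:.4f}  "
            f"(H_A = {w.het_a:.4f}, H_B = {w.het_b:.4f})",
            f"plug-in MSE (focal A): additive = {dec.mse_additive:.4g}, "
            f"GxE = {dec.mse_gxe:.4g} -> prefer {dec.preferred}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<StratifiedEffectResults beta_A={self.beta_a:.4g} "
                f"beta_B={self.beta_b:.4g} beta_pooled={self.beta_pooled:.4g}>")
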