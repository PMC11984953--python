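"""Polygenic-score simulation under partial amplification across contexts.

True per-variant effects in two equally sized contexts A and B are drawn
from the mixture

    (beta_A, beta_B) ~ pi0 * delta_0
                       + (1 - pi0) * [ alpha * Normal(0, [[1,1],[1,1]])
                                     + (1-alpha) * Normal(0, [[a, 1],[1, 1/a]]) ]

so a fraction ``alpha`` of causal variants have identical effects in
both contexts and the rest are perfectly correlated with an ``a``-fold
larger standard deviation in context A (default a = 1.5).  Allele
frequencies are f ~ (1/2) Beta(s1, s2), genotypes Binomial(2, f), and
environmental noise is set so the narrow-sense heritability is ``h2``
in each context.

Four polygenic-score strategies are compared out of sample, differing in
how score variants are ascertained and how their weights are estimated:
additive throughout; additive ascertainment with context-specific
weights; context-specific throughout; and empirical-Bayes
(covariance-mixture) posterior means with pseudo-p ascertainment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from ._util import mvn_draw
from .shrinkage import CovarianceMixtureModel, shrink_univariate

__all__ = [
    "PGSSimConfig",
    "TrueArchitecture",
    "CohortData",
    "amplification_cov",
    "draw_architecture",
    "expected_heterozygosity",
    "simulate_cohort",
    "realized_heritability",
    "marginal_gwas",
    "ascertain",
    "build_and_evaluate_scores",
    "run_experiment",
    "summarize_experiment",
    "METHODS",
]

METHODS = ("additive", "additive_asc_gxe_est", "gxe", "mash")


def amplification_cov(factor: float) -> np.ndarray:
    """Rank-1 covariance with correlation 1 and sd ratio ``factor`` (A:B).

    For factor 1.5 this is [[3/2, 1], [1, 2/3]].
    """
    if factor <= 0:
        raise ValueError("amplification factor must be positive")
    return np.array([[factor, 1.0], [1.0, 1.0 / factor]])


@dataclass(frozen=True)
class PGSSimConfig:
    """Study conditions for one simulated GWAS + polygenic-score round."""

    n_variants: int = 5000
    null_fraction: float = 0.5
    equal_share: float = 0.5  # alpha: share of causal variants with equal effects
    amplification: float = 1.5
    maf_beta_params: tuple[float, float] = (1.0, 5.0)
    heritability: float = 0.4
    n_train: int = 1000  # per context
    n_test: int = 3000  # per context
    n_ascertain: int = 833
    shrink: bool = True  # univariate EB shrinkage of additive/GxE weights
    equal_cov: np.ndarray = field(default_factory=lambda: np.ones((2, 2)))
    amp_cov: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.null_fraction <= 1.0 or not 0.0 <= self.equal_share <= 1.0:
            raise ValueError("null_fraction and equal_share must lie in [0, 1]")
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must lie in (0, 1)")
        if self.amp_cov is None:
            object.__setattr__(self, "amp_cov", amplification_cov(self.amplification))
        for name in ("equal_cov", "amp_cov"):
            c = np.asarray(getattr(self, name), dtype=float)
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError(f"{name} must be positive semidefinite")
            object.__setattr__(self, name, c)


@dataclass(frozen=True)
class TrueArchitecture:
    """True two-context effects, allele frequencies and component labels."""

    effects: np.ndarray  # (p, 2): columns A, B
    allele_freqs: np.ndarray  # (p,), in (0, 0.5]
    labels: np.ndarray  # (p,) in {"null", "equal", "amplified"}

    @property
    def n_causal(self) -> int:
        return int((self.labels != "null").sum())


@dataclass(frozen=True)
class CohortData:
    """Genotypes and traits for one context."""

    genotypes: np.ndarray  # (n, p) allele counts
    traits: np.ndarray  # (n,)
    env_variance: float
    context: str


def draw_architecture(config: PGSSimConfig, rng: np.random.Generator) -> TrueArchitecture:
    """Draw true effects and allele frequencies from the stated mixture."""
    p = config.n_variants
    u = rng.random(p)
    labels = np.where(
        u < config.null_fraction,
        "null",
        np.where(
            u < config.null_fraction + (1 - config.null_fraction) * config.equal_share,
            "equal",
            "amplified",
        ),
    )
    effects = np.zeros((p, 2))
    for name, cov in (("equal", config.equal_cov), ("amplified", config.amp_cov)):
        mask = labels == name
        k = int(mask.sum())
        if k:
            effects[mask] = mvn_draw(np.zeros(2), cov, k, rng)
    s1, s2 = config.maf_beta_params
    freqs = 0.5 * rng.beta(s1, s2, size=p)
    return TrueArchitecture(effects=effects, allele_freqs=freqs, labels=labels)


def expected_heterozygosity(freqs: np.ndarray) -> np.ndarray:
    """Expected genotypic variance 2 f (1 - f) of Binomial(2, f) counts."""
    return 2.0 * freqs * (1.0 - freqs)


def _env_variance(arch: TrueArchitecture, context_col: int, h2: float) -> float:
    beta = arch.effects[:, context_col]
    var_g = float(np.sum(expected_heterozygosity(arch.allele_freqs) * beta**2))
    if var_g == 0.0:
        return 1.0  # all-null architecture: unit noise, heritability undefined
    return var_g * (1.0 - h2) / h2


def simulate_cohort(
    arch: TrueArchitecture,
    config: PGSSimConfig,
    context: str,
    n: int,
    rng: np.random.Generator,
) -> CohortData:
    """Simulate genotypes and traits for ``n`` individuals in one context.

    Environmental variance is set from the *expected* genetic variance
    sum_j 2 f_j (1 - f_j) beta_j^2 so that the narrow-sense heritability
    equals ``config.heritability`` in expectation.
    """
    if context not in ("A", "B"):
        raise ValueError("context must be 'A' or 'B'")
    if n < 1:
        raise ValueError("n must be at least 1")
    col = 0 if context == "A" else 1
    geno = rng.binomial(2, arch.allele_freqs, size=(n, arch.allele_freqs.size)).astype(
        np.float64
    )
    sigma2 = _env_variance(arch, col, config.heritability)
    traits = geno @ arch.effects[:, col] + rng.normal(0.0, np.sqrt(sigma2), size=n)
    return CohortData(genotypes=geno, traits=traits, env_variance=sigma2, context=context)


def realized_heritability(
    arch: TrueArchitecture,
    config: PGSSimConfig,
    context: str,
    n: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> float:
    """Var(G beta) / Var(y) of a freshly simulated cohort, streamed in chunks.

    Equivalent to simulating the full cohort but keeps memory flat, so
    very large n (e.g. 50,000 x 5,000 genotypes) is cheap.
    """
    col = 0 if context == "A" else 1
    beta = arch.effects[:, col]
    sigma = np.sqrt(_env_variance(arch, col, config.heritability))
    gvals = np.empty(n)
    done = 0
    while done < n:
        size = min(chunk, n - done)
        g = rng.binomial(2, arch.allele_freqs, size=(size, beta.size))
        gvals[done : done + size] = g @ beta
        done += size
    y = gvals + rng.normal(0.0, sigma, size=n)
    return float(np.var(gvals) / np.var(y))


def _per_variant_ols(geno: np.ndarray, y: np.ndarray):
    """Vectorized simple OLS of y on each genotype column.

    Returns (slope, se, pval); monomorphic columns yield NaN.
    """
    n = y.size
    yc = y - y.mean()
    gc = geno - geno.mean(axis=0)
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        rss = np.maximum(syy - slope * sxy, 0.0)
        sigma2 = rss / max(n - 2, 1)
        se = np.sqrt(sigma2 / sxx)
        z = slope / se
    pval = 2.0 * norm.sf(np.abs(z))
    bad = sxx == 0
    slope[bad] = np.nan
    se[bad] = np.nan
    pval[bad] = np.nan
    return slope, se, pval


def marginal_gwas(cohort_a: CohortData, cohort_b: CohortData) -> pd.DataFrame:
    """Per-variant stratified and additive OLS over two cohorts.

    Variants are simulated without linkage, so single-variant regressions
    are the correctly specified marginal model.  The additive fit pools
    the two cohorts after centering traits within context, making the
    pooled slope exactly the omega-weighted combination of the
    stratified slopes.
    """
    if cohort_a.genotypes.shape[1] != cohort_b.genotypes.shape[1]:
        raise ValueError("cohorts must share the variant panel")
    beta_a, se_a, pval_a = _per_variant_ols(cohort_a.genotypes, cohort_a.traits)
    beta_b, se_b, pval_b = _per_variant_ols(cohort_b.genotypes, cohort_b.traits)
    pooled_g = np.vstack([cohort_a.genotypes, cohort_b.genotypes])
    pooled_y = np.concatenate(
        [
            cohort_a.traits - cohort_a.traits.mean(),
            cohort_b.traits - cohort_b.traits.mean(),
        ]
    )
    beta_add, se_add, pval_add = _per_variant_ols(pooled_g, pooled_y)
    return pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(beta_a.size)],
            "beta_a": beta_a,
            "se_a": se_a,
            "pval_a": pval_a,
            "beta_b": beta_b,
            "se_b": se_b,
            "pval_b": pval_b,
            "beta_add": beta_add,
            "se_add": se_add,
            "pval_add": pval_add,
        }
    )


def ascertain(values, k: int, tiebreak_z=None) -> np.ndarray:
    """Indices of the k smallest values (NaNs excluded).

    Ties are broken by larger ``|tiebreak_z|`` when given, then by lower
    index; the result is sorted ascending by index.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if k > int(finite.sum()):
        raise ValueError(f"k={k} exceeds the {int(finite.sum())} finite entries")
    idx = np.arange(v.size)[finite]
    vv = v[finite]
    if tiebreak_z is not None:
        tz = -np.abs(np.asarray(tiebreak_z, dtype=float))[finite]
        tz = np.nan_to_num(tz, nan=0.0)
        order = np.lexsort((idx, tz, vv))
    else:
        order = np.lexsort((idx, vv))
    return np.sort(idx[order[:k]])


def _safe_corr(score: np.ndarray, y: np.ndarray) -> float:
    if np.std(score) == 0.0 or np.std(y) == 0.0:
        warnings.warn("constant polygenic score; correlation recorded as 0", stacklevel=2)
        return 0.0
    return float(pearsonr(score, y)[0])


def build_and_evaluate_scores(
    gwas: pd.DataFrame,
    test_a: CohortData,
    test_b: CohortData,
    config: PGSSimConfig,
) -> pd.DataFrame:
    """Score the four ascertainment/estimation strategies out of sample.

    Returns a tidy frame with columns method, context, correlation.
    """
    k = config.n_ascertain
    beta_a = gwas["beta_a"].to_numpy()
    beta_b = gwas["beta_b"].to_numpy()
    se_a = gwas["se_a"].to_numpy()
    se_b = gwas["se_b"].to_numpy()
    beta_add = gwas["beta_add"].to_numpy()
    se_add = gwas["se_add"].to_numpy()

    ok = np.isfinite(beta_a) & np.isfinite(beta_b) & np.isfinite(beta_add)
    if config.shrink:
        w_add = np.where(ok, 0.0, np.nan)
        w_a = w_add.copy()
        w_b = w_add.copy()
        w_add[ok] = shrink_univariate(beta_add[ok], se_add[ok])
        w_a[ok] = shrink_univariate(beta_a[ok], se_a[ok])
        w_b[ok] = shrink_univariate(beta_b[ok], se_b[ok])
    else:
        w_add, w_a, w_b = beta_add, beta_a, beta_b

    mash_model = CovarianceMixtureModel(
        np.column_stack([beta_a[ok], beta_b[ok]]),
        np.column_stack([se_a[ok], se_b[ok]]),
    )
    mash_res = mash_model.fit()
    post_mean = np.full((beta_a.size, 2), np.nan)
    post_mean[ok] = mash_res.posterior_means
    pseudo_p = np.full((beta_a.size, 2), np.nan)
    pseudo_p[ok] = mash_res.pseudo_pvalues()

    z_add = np.abs(beta_add) / se_add
    z_a = np.abs(beta_a) / se_a
    z_b = np.abs(beta_b) / se_b

    omega_add = ascertain(gwas["pval_add"], k, tiebreak_z=z_add)
    omega_a = ascertain(gwas["pval_a"], k, tiebreak_z=z_a)
    omega_b = ascertain(gwas["pval_b"], k, tiebreak_z=z_b)
    omega_mash_a = ascertain(pseudo_p[:, 0], k)
    omega_mash_b = ascertain(pseudo_p[:, 1], k)

    per_context_weights = {
        "additive": {"A": (omega_add, w_add), "B": (omega_add, w_add)},
        "additive_asc_gxe_est": {"A": (omega_add, w_a), "B": (omega_add, w_b)},
        "gxe": {"A": (omega_a, w_a), "B": (omega_b, w_b)},
        "mash": {"A": (omega_mash_a, post_mean[:, 0]), "B": (omega_mash_b, post_mean[:, 1])},
    }
    rows = []
    for method in METHODS:
        for context, cohort in (("A", test_a), ("B", test_b)):
            sel, weights = per_context_weights[method][context]
            score = cohort.genotypes[:, sel] @ np.nan_to_num(weights[sel])
            rows.append(
                {
                    "method": method,
                    "context": context,
                    "correlation": _safe_corr(score, cohort.traits),
                }
            )
    return pd.DataFrame(rows)


def _one_replicate(config: PGSSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    arch = draw_architecture(config, rng)
    train_a = simulate_cohort(arch, config, "A", config.n_train, rng)
    train_b = simulate_cohort(arch, config, "B", config.n_train, rng)
    test_a = simulate_cohort(arch, config, "A", config.n_test, rng)
    test_b = simulate_cohort(arch, config, "B", config.n_test, rng)
    gwas = marginal_gwas(train_a, train_b)
    return build_and_evaluate_scores(gwas, test_a, test_b, config)


def run_experiment(
    config: PGSSimConfig,
    alphas: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_trains: Sequence[int] = (1000, 50000),
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid of score comparisons; tidy per-replicate results.

    Each replicate gets its own RNG stream keyed on (seed, alpha,
    n_train, rep), so any single grid cell reruns identically whether it
    is computed alone or as part of the full grid.
    """
    rows = []
    for alpha in alphas:
        for n_train in n_trains:
            cfg = replace(config, equal_share=float(alpha), n_train=int(n_train))
            cell = np.random.SeedSequence([int(seed), int(round(alpha * 10000)), int(n_train)])
            for rep, ss in enumerate(cell.spawn(n_reps)):
                res = _one_replicate(cfg, np.random.default_rng(ss))
                res["alpha"] = alpha
                res["n_train"] = n_train
                res["rep"] = rep
                rows.append(res)
    out = pd.concat(rows, ignore_index=True)
    return out[["alpha", "n_train", "method", "context", "rep", "correlation"]]


def summarize_experiment(results: pd.DataFrame) -> pd.DataFrame:
    """Mean out-of-sample correlation per cell with its Monte-Carlo SE."""
    g = results.groupby(["alpha", "n_train", "method", "context"])["correlation"]
    out = g.agg(mean_correlation="mean", sd="std", n_reps="count").reset_index()
    out["mc_se"] = out["sd"] / np.sqrt(out["n_reps"])
    return out.drop(columns="sd")
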