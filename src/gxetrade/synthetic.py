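"""Synthetic stand-ins for the external inputs of the genome-wide analyses.

Two generators:

* :func:`generate_summary_stats` emulates sex-stratified GWAS summary
  statistics (two-context effects, SEs, LD-block labels) with a known
  generative truth table, so decision-rule screens can be scored
  against the effects that actually produced the data;
* :func:`generate_se_surrogate` produces donor-paired standard errors
  on the log-normal scale, standing in for an empirical fly-study SE
  table in the diet-amplification simulator.

Per-variant estimation noise in the summary-stat generator follows the
approximation that, when each variant explains a tiny share of trait
variance, V = trait_variance / (n * 2 f (1 - f)) — noise is a matter of
trait variance and heterozygosity alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import mvn_draw
from .gxdiet import SEResource
from .pgs import amplification_cov

__all__ = [
    "SummaryStatGeneratorConfig",
    "SESurrogateConfig",
    "generate_summary_stats",
    "generate_se_surrogate",
]


@dataclass(frozen=True)
class SummaryStatGeneratorConfig:
    """Conditions for a synthetic two-context summary-statistic panel.

    Defaults sketch a biobank-scale sex-stratified GWAS: ~150K
    individuals per context, unit trait variance in the focal context,
    and the same null/equal/amplified effect mixture as the
    polygenic-score simulator.  ``heritability`` fixes the scale of
    causal effects (so the mixture explains that share of focal-context
    trait variance in expectation).
    """

    n_variants: int = 10_000
    n_blocks: int = 1700
    null_fraction: float = 0.5
    equal_share: float = 0.5
    amplification: float = 1.5
    heritability: float = 0.4
    n_a: int = 150_000
    n_b: int = 150_000
    trait_var_a: float = 1.0
    trait_var_b: float = 1.0
    maf_beta_params: tuple[float, float] = (1.0, 5.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1 or self.n_variants < self.n_blocks:
            raise ValueError("need at least one variant per block")
        if min(self.n_a, self.n_b) < 1 or min(self.trait_var_a, self.trait_var_b) <= 0:
            raise ValueError("sample sizes and trait variances must be positive")
        if not (0 <= self.null_fraction <= 1 and 0 <= self.equal_share <= 1):
            raise ValueError("mixture proportions must lie in [0, 1]")


def _beta_maf_moments(s1: float, s2: float) -> float:
    """E[2 f (1 - f)] for f = (1/2) Beta(s1, s2)."""
    ef = s1 / (2.0 * (s1 + s2))
    ef2 = s1 * (s1 + 1.0) / (4.0 * (s1 + s2) * (s1 + s2 + 1.0))
    return 2.0 * (ef - ef2)


def generate_summary_stats(
    config: SummaryStatGeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary-statistic table plus its generative truth table.

    Returns ``(stats, truth)``: ``stats`` has the standard columns
    variant_id, beta_a, se_a, beta_b, se_b, pval_a, block_id with
    estimates beta_hat ~ Normal(beta, V) and
    V = trait_var / (n * 2 f (1 - f)); ``truth`` carries the true
    effects, allele frequency and mixture component per variant.
    """
    from scipy.stats import norm

    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.n_variants
    s1, s2 = config.maf_beta_params
    freqs = 0.5 * rng.beta(s1, s2, size=p)
    het = 2.0 * freqs * (1.0 - freqs)

    u = rng.random(p)
    causal_cut = config.null_fraction + (1 - config.null_fraction) * config.equal_share
    labels = np.where(u < config.null_fraction, "null", np.where(u < causal_cut, "equal", "amplified"))
    # effect scale: causal mixture explains `heritability` of focal trait variance
    n_causal_exp = p * (1.0 - config.null_fraction)
    base_var = (
        config.heritability * config.trait_var_a / (n_causal_exp * _beta_maf_moments(s1, s2))
        if n_causal_exp
        else 0.0
    )
    effects = np.zeros((p, 2))
    for name, cov in (("equal", np.ones((2, 2))), ("amplified", amplification_cov(config.amplification))):
        mask = labels == name
        k = int(mask.sum())
        if k:
            effects[mask] = mvn_draw(np.zeros(2), base_var * cov, k, rng)

    var_a = config.trait_var_a / (config.n_a * het)
    var_b = config.trait_var_b / (config.n_b * het)
    se_a, se_b = np.sqrt(var_a), np.sqrt(var_b)
    beta_a_hat = rng.normal(effects[:, 0], se_a)
    beta_b_hat = rng.normal(effects[:, 1], se_b)
    pval_a = 2.0 * norm.sf(np.abs(beta_a_hat / se_a))
    block_id = (np.arange(p) * config.n_blocks) // p

    variant_id = np.array([f"v{j}" for j in range(p)])
    stats = pd.DataFrame(
        {
            "variant_id": variant_id,
            "beta_a": beta_a_hat,
            "se_a": se_a,
            "beta_b": beta_b_hat,
            "se_b": se_b,
            "pval_a": np.maximum(pval_a, np.finfo(float).tiny),
            "block_id": block_id,
        }
    )
    truth = pd.DataFrame(
        {
            "variant_id": variant_id,
            "beta_a": effects[:, 0],
            "beta_b": effects[:, 1],
            "freq": freqs,
            "component": labels,
            "block_id": block_id,
        }
    )
    return stats, truth


@dataclass(frozen=True)
class SESurrogateConfig:
    """Parametric donor-paired SE surrogate (log-normal pairs).

    Defaults put SE magnitudes around 0.05-0.3, the scale of the fly
    study's effect-estimate uncertainty.  Per-variant SE variation in
    such a design is driven mostly by allele frequency, which both
    diets share, so paired log-SEs are nearly perfectly correlated;
    the residual decoupling covers diet-specific death counts.
    """

    log_loc: tuple[float, float] = (-2.0, -2.0)  # (control, sugar)
    log_scale: tuple[float, float] = (0.4, 0.4)
    log_corr: float = 0.95
    n_records: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if min(self.log_scale) <= 0:
            raise ValueError("log-scale sds must be positive")
        if not -1.0 <= self.log_corr <= 1.0:
            raise ValueError("log correlation must lie in [-1, 1]")
        if self.n_records < 1:
            raise ValueError("need at least one SE record")


def generate_se_surrogate(
    config: SESurrogateConfig, rng: np.random.Generator | None = None
) -> SEResource:
    """Correlated log-normal SE pairs, one record per donor."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    loc = np.asarray(config.log_loc, float)
    sd = np.asarray(config.log_scale, float)
    cov = np.array(
        [
            [sd[0] ** 2, config.log_corr * sd[0] * sd[1]],
            [config.log_corr * sd[0] * sd[1], sd[1] ** 2],
        ]
    )
    logs = mvn_draw(loc, cov, config.n_records, rng)
    return SEResource(s_control=np.exp(logs[:, 0]), s_sugar=np.exp(logs[:, 1]))
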