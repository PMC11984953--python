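"""Pervasive-amplification simulator for diet-dependent effects on longevity.

Emulates a two-diet (control vs high-sugar) association study in which
*every* non-null variant is amplified under the high-sugar diet, then
applies the standard significance-based four-way classification of top
hits.  The demonstrative point of the module: although no variant has a
diet-specific effect by construction, realistic estimation noise makes
the classification scheme label a substantial share of significant
variants "sugar-specific" — amplification masquerades as cryptic
genetic variation when variants are tested one at a time.

True effects are drawn as a 60/40 mixture of exact zeros and a
bivariate normal with mean (-0.125, -0.15) and covariance
0.01 * [[1, 1.4], [1.4, 1.96]] (control, high-sugar): correlation
exactly 1 and a 1.4-fold larger sd under high sugar, i.e. the affine
map beta_sugar = 1.4 * beta_control + 0.025.  Estimates add normal
noise with standard errors resampled jointly (control and sugar from
the same donor record) from an empirical SE table or a parametric
surrogate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._util import mvn_draw
from .qvalues import compute_qvalues

__all__ = [
    "CATEGORIES",
    "DietSimConfig",
    "DietEffects",
    "SEResource",
    "draw_true_effects",
    "simulate_estimates",
    "ztest_pvalues",
    "classify_variants",
    "summarize_categories",
    "run_gxdiet",
]

CATEGORIES = ("no_effect", "sugar_specific", "control_specific", "shared", "ambiguous")


@dataclass(frozen=True)
class DietSimConfig:
    """Study conditions of the two-diet amplification simulation."""

    n_variants: int = 50_000
    null_fraction: float = 0.60
    effect_mean: tuple[float, float] = (-0.125, -0.15)  # (control, high-sugar)
    effect_cov: np.ndarray = field(
        default_factory=lambda: 0.01 * np.array([[1.0, 1.4], [1.4, 1.96]])
    )
    q_threshold: float = 0.01
    p_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self):
        cov = np.asarray(self.effect_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("effect_cov must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError("effect_cov must be positive semidefinite")
        if not (0.0 < self.q_threshold < 1.0 and 0.0 < self.p_threshold < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        if not 0.0 <= self.null_fraction <= 1.0:
            raise ValueError("null_fraction must lie in [0, 1]")
        object.__setattr__(self, "effect_cov", cov)


@dataclass(frozen=True)
class DietEffects:
    """True per-variant effects under each diet; nulls are exact zeros."""

    beta_control: np.ndarray
    beta_sugar: np.ndarray
    is_null: np.ndarray


@dataclass(frozen=True)
class SEResource:
    """Paired per-donor standard errors, resampled jointly with replacement."""

    s_control: np.ndarray
    s_sugar: np.ndarray

    def __post_init__(self):
        sc = np.asarray(self.s_control, dtype=float)
        sh = np.asarray(self.s_sugar, dtype=float)
        if sc.shape != sh.shape or sc.ndim != 1 or sc.size == 0:
            raise ValueError("SE resource needs two equal-length non-empty vectors")
        if (sc <= 0).any() or (sh <= 0).any():
            raise ValueError("standard errors must be positive")
        object.__setattr__(self, "s_control", sc)
        object.__setattr__(self, "s_sugar", sh)

    @classmethod
    def from_table(cls, path) -> "SEResource":
        """Load a two-column TSV with headers s_control, s_sugar."""
        df = pd.read_csv(path, sep="\t")
        for col in ("s_control", "s_sugar"):
            if col not in df.columns:
                raise ValueError(f"{path}: SE table must have a {col!r} column")
        return cls(df["s_control"].to_numpy(float), df["s_sugar"].to_numpy(float))

    def __len__(self):
        return self.s_control.size


def draw_true_effects(config: DietSimConfig, rng: np.random.Generator) -> DietEffects:
    """Mixture draw: Bernoulli nulls plus the amplified bivariate normal."""
    p = config.n_variants
    is_null = rng.random(p) < config.null_fraction
    effects = np.zeros((p, 2))
    k = int((~is_null).sum())
    if k:
        effects[~is_null] = mvn_draw(
            np.asarray(config.effect_mean, float), config.effect_cov, k, rng
        )
    return DietEffects(
        beta_control=effects[:, 0], beta_sugar=effects[:, 1], is_null=is_null
    )


def simulate_estimates(
    effects: DietEffects, se_resource: SEResource, rng: np.random.Generator
) -> pd.DataFrame:
    """Noisy effect estimation with donor-paired standard errors.

    For each variant one donor record k is drawn with replacement; the
    control and high-sugar estimates are then independent normals
    centered on the true effects with sds (s_control_k, s_sugar_k).
    """
    p = effects.beta_control.size
    donor = rng.integers(len(se_resource), size=p)
    se_c = se_resource.s_control[donor]
    se_h = se_resource.s_sugar[donor]
    est_c = rng.normal(effects.beta_control, se_c)
    est_h = rng.normal(effects.beta_sugar, se_h)
    return pd.DataFrame(
        {
            "beta_control": effects.beta_control,
            "beta_sugar": effects.beta_sugar,
            "is_null": effects.is_null,
            "est_control": est_c,
            "est_sugar": est_h,
            "se_control": se_c,
            "se_sugar": se_h,
        }
    )


def ztest_pvalues(estimates, ses) -> np.ndarray:
    """Two-sided Z-test p-values 2*Phi(-|estimate/se|).

    Values are floored at the smallest positive float so extreme z-scores
    stay in (0, 1] for downstream q-value computation.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if (se < 0).any():
        raise ValueError("standard errors must be non-negative")
    if (se == 0).any():
        warnings.warn("zero standard error: p-value set to 0 (1 for zero estimate)",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(est / se)
    z[(se == 0) & (est == 0)] = 0.0
    p = 2.0 * norm.sf(z)
    keep_zero = (se == 0) & (est != 0)
    p = np.maximum(p, np.finfo(float).tiny)
    p[keep_zero] = 0.0
    return p


def classify_variants(
    q_sugar, q_control, p_sugar, p_control, config: DietSimConfig
) -> np.ndarray:
    """Four-way top-hit classification (first matching rule wins).

    1. q_sugar >= qt and q_control >= qt -> no_effect
    2. q_sugar <  qt and p_control >= pt -> sugar_specific
    3. q_control < qt and p_sugar  >= pt -> control_specific
    4. q_control < qt and q_sugar  < qt  -> shared

    The four published rules do not partition the outcome space (e.g.
    q_control < qt with q_sugar >= qt and p_sugar < pt matches none),
    so unmatched variants get the explicit label "ambiguous".
    """
    arrs = [np.asarray(a, dtype=float) for a in (q_sugar, q_control, p_sugar, p_control)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("q/p vectors must have identical length")
    qh, qc, ph, pc = arrs
    qt, pt = config.q_threshold, config.p_threshold
    out = np.full(qh.shape, "ambiguous", dtype="U16")
    rules = [
        ("no_effect", (qh >= qt) & (qc >= qt)),
        ("sugar_specific", (qh < qt) & (pc >= pt)),
        ("control_specific", (qc < qt) & (ph >= pt)),
        ("shared", (qc < qt) & (qh < qt)),
    ]
    unassigned = np.ones(qh.shape, dtype=bool)
    for label, mask in rules:
        take = mask & unassigned
        out[take] = label
        unassigned &= ~take
    return out


def summarize_categories(categories) -> pd.DataFrame:
    """Counts and shares per category.

    ``share_of_significant`` uses as denominator all variants outside
    no_effect/ambiguous (i.e. those confidently assigned an effect);
    zero when that set is empty.
    """
    cats = np.asarray(categories)
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    sig_total = sum(counts[c] for c in ("sugar_specific", "control_specific", "shared"))
    rows = []
    for c in CATEGORIES:
        share = (
            counts[c] / sig_total
            if sig_total and c in ("sugar_specific", "control_specific", "shared")
            else 0.0
        )
        rows.append({"category": c, "count": counts[c], "share_of_significant": share})
    return pd.DataFrame(rows)


def run_gxdiet(
    config: DietSimConfig, se_resource: SEResource, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: truths -> noisy estimates -> Z-tests -> q-values -> labels.

    Returns the per-variant table and the category summary.  q-values
    are computed separately within each diet.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    effects = draw_true_effects(config, rng)
    table = simulate_estimates(effects, se_resource, rng)
    table["p_control"] = ztest_pvalues(table["est_control"], table["se_control"])
    table["p_sugar"] = ztest_pvalues(table["est_sugar"], table["se_sugar"])
    table["q_control"] = compute_qvalues(table["p_control"].to_numpy()).qvalues
    table["q_sugar"] = compute_qvalues(table["p_sugar"].to_numpy()).qvalues
    table["category"] = classify_variants(
        table["q_sugar"], table["q_control"], table["p_sugar"], table["p_control"], config
    )
    return table, summarize_categories(table["category"])
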