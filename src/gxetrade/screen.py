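"""Genome-wide application of the decision rule to summary statistics.

Given two-context GWAS summary statistics (per-variant effects and
standard errors in a focal context A and a second context B), each
variant receives a verdict — is its focal-context effect better
estimated by the additive (pooled) or the context-specific (GxE)
estimator? — by comparing the plug-in signal-to-noise ratio
(beta_a - beta_b)^2 / se_a^2 with the threshold
(1 + omega_A)/(1 - omega_A) - V_B/V_A.

Because per-variant standard errors for a pooled fit are unavailable
from stratified summary stats, the ratio of estimation noises
r = V_A/V_B is supplied as a per-trait proxy (e.g. the ratio of
context-specific trait variances), constant across variants, and
heterozygosity is assumed equal across contexts (autosomal variants).

Two genome-wide summaries are provided: the percentage of variants
preferring GxE via one-variant-per-LD-block resampling, and a
train/holdout validation of the predicted per-variant MSE difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision import snr_threshold

__all__ = [
    "ScreenConfig",
    "classify_loci",
    "fraction_gxe_preferred",
    "split_validate",
    "SplitValidation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Settings for a genome-wide decision-rule screen.

    ``noise_ratio_proxy`` is the assumed r = V_A/V_B; ``omega_a``
    defaults to 1/2 (equal per-context sample sizes and
    heterozygosity); ``sig_threshold`` is the focal-context marginal
    p-value cutoff used when restricting to significant variants.
    """

    focal_context: str = "A"
    noise_ratio_proxy: float = 1.0
    omega_a: float = 0.5
    sig_threshold: float = 5e-8
    n_block_draws: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.focal_context not in ("A", "B"):
            raise ValueError("focal_context must be 'A' or 'B'")
        if self.noise_ratio_proxy <= 0:
            raise ValueError("noise_ratio_proxy must be positive")
        if not 0.0 < self.sig_threshold < 1.0:
            raise ValueError("sig_threshold must lie in (0, 1)")
        if not 0.0 < self.omega_a < 1.0:
            raise ValueError("omega_a must lie strictly in (0, 1)")


def _oriented(records: pd.DataFrame, config: ScreenConfig):
    """Return (beta_f, se_f, beta_o, se_o) with the focal context first."""
    if config.focal_context == "A":
        return (
            records["beta_a"].to_numpy(float),
            records["se_a"].to_numpy(float),
            records["beta_b"].to_numpy(float),
            records["se_b"].to_numpy(float),
        )
    return (
        records["beta_b"].to_numpy(float),
        records["se_b"].to_numpy(float),
        records["beta_a"].to_numpy(float),
        records["se_a"].to_numpy(float),
    )


SIGNAL_MODES = ("plugin", "corrected", "shrunk")


def _snr(records, config, signal: str):
    """Squared context-difference signal over focal noise, three flavours.

    "plugin": raw (beta_f - beta_o)^2 — what boundary plots show, but
    inflated by estimation noise (2 V_f under the null at equal SEs).
    "corrected": subtracts se_f^2 + se_o^2, unbiased for the squared true
    difference per variant, but its chi-square noise still misclassifies
    a fixed fraction of nulls (P(chi2_1 > 2) ~ 16% at r = 1).
    "shrunk": empirical-Bayes posterior second moment of the difference,
    pooling information across the genome; nulls collapse to ~0 while
    pervasive real differences survive, so genome-wide *fractions*
    track the truth.
    """
    if signal not in SIGNAL_MODES:
        raise ValueError(f"signal must be one of {SIGNAL_MODES}")
    beta_f, se_f, beta_o, se_o = _oriented(records, config)
    if signal == "shrunk":
        from .shrinkage import shrink_univariate

        mean, sd = shrink_univariate(
            beta_f - beta_o, np.sqrt(se_f**2 + se_o**2), return_sd=True
        )
        delta2 = mean**2 + sd**2
    else:
        delta2 = (beta_f - beta_o) ** 2
        if signal == "corrected":
            delta2 = delta2 - se_f**2 - se_o**2
    with np.errstate(invalid="ignore", divide="ignore"):
        return delta2 / se_f**2


def classify_loci(
    records: pd.DataFrame,
    config: ScreenConfig,
    signal: str = "plugin",
    significant_only: bool = False,
) -> pd.DataFrame:
    """Per-variant decision-rule verdicts.

    Adds columns ``snr``, ``snr_threshold`` and ``preferred``
    ("additive"/"gxe").  The verdict itself does not depend on the
    significance threshold; ``significant_only`` merely restricts the
    returned rows (focal-context p-value below ``sig_threshold``).
    Records with non-finite effects or SEs are dropped with a warning.
    """
    thr = snr_threshold(config.omega_a, 1.0 / config.noise_ratio_proxy)
    beta_f, se_f, beta_o, se_o = _oriented(records, config)
    valid = np.isfinite(beta_f) & np.isfinite(beta_o) & np.isfinite(se_f) & np.isfinite(se_o)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("dropping %d record(s) with missing effects or SEs", n_bad)
    out = records.loc[valid].copy()
    snr = _snr(out, config, signal)
    out["snr"] = snr
    out["snr_threshold"] = thr
    out["preferred"] = np.where(snr > thr, "gxe", "additive")
    if significant_only:
        pcol = "pval_a" if config.focal_context == "A" else "pval_b"
        if pcol not in out.columns:
            raise ValueError(f"significant_only requires a {pcol!r} column")
        out = out[out[pcol] < config.sig_threshold]
    return out


def fraction_gxe_preferred(
    records: pd.DataFrame,
    config: ScreenConfig,
    signal: str = "shrunk",
    significant_only: bool = False,
) -> tuple[float, np.ndarray]:
    """Percent of effects better estimated under GxE, block-resampled.

    One variant is sampled uniformly from each LD block
    (``block_id`` column), the percent of sampled variants preferring
    GxE is recorded, and the procedure repeats ``n_block_draws`` times;
    the mean percentage and the per-draw values are returned.

    The default signal pools information across the genome: per-variant
    context differences are shrunk with a univariate empirical-Bayes
    mixture before the rule is applied.  The raw plug-in difference is
    inflated by estimation noise, and even the per-variant unbiased
    correction misclassifies a fixed ~16% of null variants (its
    chi-square noise exceeds the threshold that often at r = 1), so
    neither tracks the fraction of *true* effects better estimated
    under GxE in null-dominated panels; both remain available via
    ``signal``.
    """
    if "block_id" not in records.columns:
        raise ValueError("block-resampled fraction requires a block_id column")
    labelled = classify_loci(
        records, config, signal=signal, significant_only=significant_only
    )
    if labelled.empty:
        raise ValueError("no variants left after filtering")
    rng = np.random.default_rng(config.seed)
    grouped = labelled.groupby("block_id").indices
    if not grouped:
        raise ValueError("no non-empty blocks")
    draws = np.empty(config.n_block_draws)
    prefers = (labelled["preferred"] == "gxe").to_numpy()
    for d in range(config.n_block_draws):
        picks = [idx[rng.integers(len(idx))] for idx in grouped.values()]
        draws[d] = 100.0 * prefers[picks].mean()
    return float(draws.mean()), draws


@dataclass(frozen=True)
class SplitValidation:
    """Per-variant predicted vs realized MSE differences and their binning."""

    per_variant: pd.DataFrame
    calibration: pd.DataFrame


def split_validate(
    train_records: pd.DataFrame,
    holdout_records: pd.DataFrame,
    config: ScreenConfig,
    n_bins: int = 10,
) -> SplitValidation:
    """Validate predicted MSE differences on an independent holdout split.

    The training half predicts, per variant, MSE(additive) - MSE(GxE)
    for the focal context, using the noise-corrected squared bias
    ((omega_A - 1) beta_f + omega_B beta_o)^2 - (1-omega_A)^2 se_f^2
    - omega_B^2 se_o^2 (the naive plug-in is inflated by estimation
    noise).  The holdout half realizes the same difference as

        (beta_additive_train - beta_f_holdout)^2
        - (beta_f_train - beta_f_holdout)^2,

    whose expectation equals the true MSE difference because the
    holdout estimate's own noise cancels in the difference.
    Calibration bins are predicted-value quantiles; each carries the
    mean predicted and mean realized difference with a Monte-Carlo SE.
    """
    t = train_records.set_index("variant_id")
    h = holdout_records.set_index("variant_id")
    unmatched = t.index.symmetric_difference(h.index)
    if len(unmatched):
        raise ValueError(f"variant ids not present in both splits: {list(unmatched[:10])}")
    h = h.loc[t.index]

    wa = config.omega_a
    wb = 1.0 - wa
    beta_f, se_f, beta_o, se_o = _oriented(t.reset_index(), config)
    hf, _, _, _ = _oriented(h.reset_index(), config)

    bias_plugin = (wa - 1.0) * beta_f + wb * beta_o
    bias2 = bias_plugin**2 - (1.0 - wa) ** 2 * se_f**2 - wb**2 * se_o**2
    var_f = se_f**2
    var_o = se_o**2
    predicted = bias2 + wa**2 * var_f + wb**2 * var_o - var_f

    beta_additive_train = wa * beta_f + wb * beta_o
    realized = (beta_additive_train - hf) ** 2 - (beta_f - hf) ** 2

    per_variant = pd.DataFrame(
        {"variant_id": t.index, "predicted": predicted, "realized": realized}
    )
    try:
        bins = pd.qcut(predicted, n_bins, duplicates="drop")
    except ValueError:
        bins = pd.Series(0, index=per_variant.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        cal = (
            per_variant.assign(bin=np.asarray(bins))
            .groupby("bin", observed=True)
            .agg(
                mean_predicted=("predicted", "mean"),
                mean_realized=("realized", "mean"),
                sd_realized=("realized", "std"),
                n=("realized", "count"),
            )
            .reset_index()
        )
    cal["se_realized"] = cal["sd_realized"] / np.sqrt(cal["n"])
    return SplitValidation(per_variant=per_variant, calibration=cal.drop(columns="sd_realized"))
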