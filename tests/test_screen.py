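"""Genome-wide decision-rule screens on summary statistics."""

import numpy as np
import pandas as pd
import pytest

from gxetrade.decision import DecisionInput, critical_noise_ratio, mse_pair
from gxetrade.screen import (
    ScreenConfig,
    classify_loci,
    fraction_gxe_preferred,
    split_validate,
)
from gxetrade.synthetic import SummaryStatGeneratorConfig, generate_summary_stats


def _records(beta_a, beta_b, se_a, se_b, **extra):
    n = len(beta_a)
    base = {
        "variant_id": [f"v{i}" for i in range(n)],
        "beta_a": beta_a,
        "se_a": se_a,
        "beta_b": beta_b,
        "se_b": se_b,
    }
    base.update(extra)
    return pd.DataFrame(base)


class TestClassifyLoci:
    def test_zero_difference_prefers_additive(self):
        rec = _records([0.3, -0.1], [0.3, -0.1], [0.05, 0.05], [0.05, 0.05])
        out = classify_loci(rec, ScreenConfig())
        assert (out["preferred"] == "additive").all()

    def test_noiseless_limit_prefers_gxe(self):
        rec = _records([0.3], [0.0], [1e-9], [1e-9])
        out = classify_loci(rec, ScreenConfig())
        assert out["preferred"].iloc[0] == "gxe"

    def test_agrees_with_mse_pair_on_every_record(self, rng):
        n = 300
        rec = _records(
            rng.normal(size=n), rng.normal(size=n),
            rng.uniform(0.05, 0.5, n), rng.uniform(0.05, 0.5, n),
        )
        cfg = ScreenConfig(noise_ratio_proxy=0.8, omega_a=0.4)
        out = classify_loci(rec, cfg)
        for _, row in out.iterrows():
            # the screen assumes V_A = se_a^2 and V_B = V_A / r
            var_a = row["se_a"] ** 2
            d = mse_pair(DecisionInput(
                row["beta_a"], row["beta_b"], var_a,
                var_a / cfg.noise_ratio_proxy, cfg.omega_a, 1 - cfg.omega_a,
            ))
            assert d.preferred == row["preferred"]

    def test_missing_values_dropped_with_warning(self, caplog):
        rec = _records([0.3, np.nan], [0.0, 0.1], [0.1, 0.1], [0.1, 0.1])
        with caplog.at_level("WARNING"):
            out = classify_loci(rec, ScreenConfig())
        assert len(out) == 1
        assert "dropping" in caplog.text

    def test_significance_filter_composition_only(self, rng):
        n = 200
        rec = _records(
            rng.normal(size=n), rng.normal(size=n),
            np.full(n, 0.2), np.full(n, 0.2),
            pval_a=rng.uniform(size=n) ** 6,
        )
        cfg = ScreenConfig(sig_threshold=1e-3)
        full = classify_loci(rec, cfg).set_index("variant_id")
        sig = classify_loci(rec, cfg, significant_only=True).set_index("variant_id")
        # per-variant verdicts are unchanged by the filter; only the rows differ
        assert sig.index.isin(full.index).all()
        assert (full.loc[sig.index, "preferred"] == sig["preferred"]).all()


class TestFractionGxePreferred:
    def test_zero_differences_give_zero_percent(self):
        n = 100
        rec = _records([0.2] * n, [0.2] * n, [0.1] * n, [0.1] * n,
                       block_id=np.arange(n) % 10)
        pct, draws = fraction_gxe_preferred(rec, ScreenConfig(n_block_draws=5))
        assert pct == 0.0
        assert len(draws) == 5

    def test_extreme_amplification_tiny_ses_give_hundred_percent(self):
        n = 100
        rec = _records([1.0] * n, [3.0] * n, [1e-6] * n, [1e-6] * n,
                       block_id=np.arange(n) % 10)
        pct, _ = fraction_gxe_preferred(rec, ScreenConfig())
        assert pct == 100.0

    def test_below_critical_noise_ratio_everything_prefers_gxe(self, rng):
        n = 400
        rec = _records(
            rng.normal(size=n), rng.normal(size=n),
            rng.uniform(0.01, 0.3, n), rng.uniform(0.01, 0.3, n),
            block_id=np.arange(n) % 40,
        )
        r = 0.9 * critical_noise_ratio(0.5)
        pct, _ = fraction_gxe_preferred(
            rec, ScreenConfig(noise_ratio_proxy=r), signal="plugin"
        )
        assert pct == 100.0

    def test_matches_oracle_on_generated_truths(self):
        """Shrunk-signal fraction tracks the rule applied to noiseless truths."""
        cfg = SummaryStatGeneratorConfig(
            n_variants=8_000, n_blocks=800, equal_share=0.0, seed=11,
            n_a=400_000, n_b=400_000,
        )
        stats, truth = generate_summary_stats(cfg)
        scfg = ScreenConfig(n_block_draws=10, seed=1)
        pct, draws = fraction_gxe_preferred(stats, scfg, signal="shrunk")
        # oracle: decision rule on the true effects with the known SEs
        thr = (1 + scfg.omega_a) / (1 - scfg.omega_a) - 1.0 / scfg.noise_ratio_proxy
        snr_true = (truth["beta_a"] - truth["beta_b"]) ** 2 / stats["se_a"] ** 2
        oracle_pct = 100.0 * (snr_true > thr).mean()
        assert abs(pct - oracle_pct) < 5.0  # Monte-Carlo + shrinkage slack

    def test_corrected_signal_null_rate_matches_closed_form(self, rng):
        """Pure nulls: corrected SNR is 2(chi2_1 - 1) vs threshold 2 at r=1,
        so the expected false-GxE fraction is P(chi2_1 > 2) ~ 15.7%."""
        from scipy.stats import chi2

        n = 40_000
        se = np.full(n, 0.1)
        noise = rng.normal(0, 0.1, size=(2, n))
        rec = _records(noise[0], noise[1], se, se, block_id=np.arange(n) % 1000)
        pct, _ = fraction_gxe_preferred(rec, ScreenConfig(), signal="corrected")
        expected = 100.0 * chi2.sf(2.0, df=1)
        assert pct == pytest.approx(expected, abs=2.0)

    def test_requires_blocks(self):
        rec = _records([0.1], [0.2], [0.1], [0.1])
        with pytest.raises(ValueError, match="block_id"):
            fraction_gxe_preferred(rec, ScreenConfig())


class TestSplitValidate:
    def test_zero_noise_identical_splits_realize_analytic_margin(self):
        # noiseless: additive = omega-average, holdout equals truth
        beta_a, beta_b = np.array([0.4]), np.array([0.1])
        se = np.array([1e-8])
        train = _records(beta_a, beta_b, se, se)
        hold = _records(beta_a, beta_b, se, se)
        sv = split_validate(train, hold, ScreenConfig())
        expected = (0.5 * 0.4 + 0.5 * 0.1 - 0.4) ** 2
        assert sv.per_variant["realized"].iloc[0] == pytest.approx(expected, rel=1e-6)
        assert sv.per_variant["predicted"].iloc[0] == pytest.approx(expected, rel=1e-4)

    def test_pure_null_predicted_difference_is_variance_penalty(self, rng):
        """beta_A = beta_B = 0: E[predicted] = (w_A^2+w_B^2-1) V_A + w_B^2 V_B... == closed form."""
        n = 50_000
        se_a = np.full(n, 0.2)
        se_b = np.full(n, 0.2)
        train = _records(rng.normal(0, 0.2, n), rng.normal(0, 0.2, n), se_a, se_b)
        hold = _records(rng.normal(0, 0.2, n), rng.normal(0, 0.2, n), se_a, se_b)
        sv = split_validate(train, hold, ScreenConfig())
        # noise-corrected bias^2 has expectation 0 under the null, so the
        # mean predicted difference is the pure variance penalty
        # omega_A^2 V_A + omega_B^2 V_B - V_A with V_A = V_B = 0.04
        penalty = (0.25 - 1.0) * 0.04 + 0.25 * 0.04
        assert sv.per_variant["predicted"].mean() == pytest.approx(penalty, rel=0.05)
        assert sv.per_variant["realized"].mean() == pytest.approx(penalty, rel=0.10)

    def test_calibration_on_synthetic_two_split_panel(self):
        """Binned mean realized and predicted MSE differences agree.

        Bins are formed on the *true* margin (known in simulation):
        conditional on truth both the training prediction and the
        holdout realization are unbiased, so their bin means must agree
        within Monte-Carlo error.  (Binning on the noisy prediction
        itself would instead select on shared training noise and show
        ordinary regression to the mean in the extreme bins.)
        """
        cfg = SummaryStatGeneratorConfig(n_variants=50_000, n_blocks=1000, seed=5)
        train, truth = generate_summary_stats(cfg, np.random.default_rng(101))
        # same truths in both splits, independent estimation noise
        hold = train.copy()
        g = np.random.default_rng(303)
        hold["beta_a"] = truth["beta_a"] + g.normal(0, train["se_a"])
        hold["beta_b"] = truth["beta_b"] + g.normal(0, train["se_b"])
        sv = split_validate(train, hold, ScreenConfig())
        pv = sv.per_variant
        wa = 0.5
        bias = (wa - 1) * truth["beta_a"] + (1 - wa) * truth["beta_b"]
        margin_true = (
            bias**2
            + (wa**2 - 1) * train["se_a"] ** 2
            + (1 - wa) ** 2 * train["se_b"] ** 2
        )
        binned = pv.assign(
            bin=pd.qcut(margin_true.to_numpy(), 8, duplicates="drop")
        ).groupby("bin", observed=True)
        for _, grp in binned:
            se = np.sqrt(
                grp["realized"].var() / len(grp) + grp["predicted"].var() / len(grp)
            )
            assert abs(grp["realized"].mean() - grp["predicted"].mean()) < 3 * se

    def test_unmatched_ids_listed(self):
        train = _records([0.1], [0.2], [0.1], [0.1])
        hold = train.copy()
        hold["variant_id"] = ["other"]
        with pytest.raises(ValueError, match="other"):
            split_validate(train, hold, ScreenConfig())
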