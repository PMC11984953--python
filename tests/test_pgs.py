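"""Polygenic-score simulation: architecture, cohorts, GWAS, scoring."""

import numpy as np
import pandas as pd
import pytest

from gxetrade.pgs import (
    PGSSimConfig,
    amplification_cov,
    ascertain,
    build_and_evaluate_scores,
    draw_architecture,
    marginal_gwas,
    realized_heritability,
    run_experiment,
    simulate_cohort,
    summarize_experiment,
)


@pytest.fixture
def small_cfg():
    return PGSSimConfig(n_variants=300, n_train=400, n_test=200, n_ascertain=50)


class TestArchitecture:
    def test_amplification_matrix_geometry(self):
        cov = amplification_cov(1.5)
        np.testing.assert_allclose(cov, [[1.5, 1.0], [1.0, 2 / 3]])
        assert np.sqrt(cov[0, 0] / cov[1, 1]) == pytest.approx(1.5)
        assert cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]) == pytest.approx(1.0)

    def test_alpha_one_gives_identical_context_effects(self, rng):
        cfg = PGSSimConfig(n_variants=500, equal_share=1.0)
        arch = draw_architecture(cfg, rng)
        causal = arch.labels != "null"
        np.testing.assert_allclose(
            arch.effects[causal, 0], arch.effects[causal, 1], atol=1e-12
        )

    def test_all_null_when_pi0_one(self, rng):
        arch = draw_architecture(PGSSimConfig(n_variants=200, null_fraction=1.0), rng)
        assert (arch.effects == 0).all()

    def test_amplified_sd_ratio_approaches_factor(self, rng):
        cfg = PGSSimConfig(n_variants=40_000, null_fraction=0.0, equal_share=0.0)
        arch = draw_architecture(cfg, rng)
        ratio = arch.effects[:, 0].std() / arch.effects[:, 1].std()
        assert ratio == pytest.approx(1.5, rel=0.03)
        # perfect correlation within the amplified component
        r = np.corrcoef(arch.effects[:, 0], arch.effects[:, 1])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_freqs_in_range(self, rng):
        arch = draw_architecture(PGSSimConfig(n_variants=1000), rng)
        assert ((arch.allele_freqs > 0) & (arch.allele_freqs <= 0.5)).all()


class TestCohort:
    def test_near_unit_heritability_means_traits_track_genetic_values(self, rng):
        cfg = PGSSimConfig(n_variants=100, heritability=1 - 1e-9)
        arch = draw_architecture(cfg, rng)
        cohort = simulate_cohort(arch, cfg, "A", 50, rng)
        gv = cohort.genotypes @ arch.effects[:, 0]
        np.testing.assert_allclose(cohort.traits, gv, atol=1e-3)

    def test_genotype_mean_matches_binomial(self, rng):
        cfg = PGSSimConfig(n_variants=30)
        arch = draw_architecture(cfg, rng)
        n = 8000
        cohort = simulate_cohort(arch, cfg, "B", n, rng)
        for j in range(30):
            f = arch.allele_freqs[j]
            se = np.sqrt(2 * f * (1 - f) / n)
            assert abs(cohort.genotypes[:, j].mean() - 2 * f) < 4 * se + 1e-9

    def test_realized_heritability_streamed_matches_config(self):
        cfg = PGSSimConfig(n_variants=800)
        rng = np.random.default_rng(42)
        arch = draw_architecture(cfg, rng)
        h2 = realized_heritability(arch, cfg, "A", 20_000, rng)
        assert h2 == pytest.approx(0.4, abs=0.03)


class TestMarginalGwas:
    def test_noiseless_single_variant_recovers_truth(self, rng):
        cfg = PGSSimConfig(n_variants=1, null_fraction=0.0, equal_share=1.0,
                           heritability=1 - 1e-12)
        arch = draw_architecture(cfg, rng)
        a = simulate_cohort(arch, cfg, "A", 200, rng)
        b = simulate_cohort(arch, cfg, "B", 200, rng)
        g = marginal_gwas(a, b)
        assert g["beta_a"].iloc[0] == pytest.approx(arch.effects[0, 0], abs=1e-5)

    def test_estimates_unbiased_over_replicates(self):
        cfg = PGSSimConfig(n_variants=60, n_train=300)
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            arch = draw_architecture(cfg, rng)
            a = simulate_cohort(arch, cfg, "A", cfg.n_train, rng)
            b = simulate_cohort(arch, cfg, "B", cfg.n_train, rng)
            g = marginal_gwas(a, b)
            errs.append(np.nanmean(g["beta_a"].to_numpy() - arch.effects[:, 0]))
        errs = np.array(errs)
        assert abs(errs.mean()) < 3 * errs.std(ddof=1) / np.sqrt(len(errs))

    def test_additive_slope_is_omega_weighted_combination(self, rng):
        """Per-variant identity against the single-locus estimator module."""
        from gxetrade.estimators import (
            StratifiedSample, center_within_context, combination_weights,
            ols_additive, ols_stratified,
        )

        cfg = PGSSimConfig(n_variants=12, n_train=150)
        arch = draw_architecture(cfg, rng)
        a = simulate_cohort(arch, cfg, "A", cfg.n_train, rng)
        b = simulate_cohort(arch, cfg, "B", cfg.n_train, rng)
        g = marginal_gwas(a, b)
        for j in range(cfg.n_variants):
            geno = np.concatenate([a.genotypes[:, j], b.genotypes[:, j]]).astype(int)
            if np.ptp(geno) == 0:
                continue
            s = center_within_context(StratifiedSample(
                geno,
                np.concatenate([a.traits, b.traits]),
                np.array(["A"] * cfg.n_train + ["B"] * cfg.n_train),
            ))
            w = combination_weights(s)
            est_a, est_b = ols_stratified(s)
            assert g["beta_add"].iloc[j] == pytest.approx(
                w.omega_a * est_a.slope + w.omega_b * est_b.slope, rel=1e-8
            )
            assert g["beta_a"].iloc[j] == pytest.approx(est_a.slope, rel=1e-8)


class TestAscertain:
    def test_full_selection_is_identity(self):
        assert list(ascertain([0.3, 0.1, 0.5], 3)) == [0, 1, 2]

    def test_matches_independent_sort(self, rng):
        p = rng.uniform(size=500)
        got = ascertain(p, 100)
        expected = np.sort(np.argsort(p)[:100])
        np.testing.assert_array_equal(got, expected)

    def test_one_third_of_default_causal_panel(self):
        # 5000 variants, half causal: a third of 2500 causal variants is 833
        assert PGSSimConfig().n_ascertain == 2500 // 3 == 833

    def test_ties_prefer_larger_z_then_lower_index(self):
        p = np.array([0.5, 0.1, 0.1, 0.1])
        z = np.array([0.0, 1.0, 3.0, 2.0])
        np.testing.assert_array_equal(ascertain(p, 2, tiebreak_z=z), [2, 3])

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            ascertain([0.1, np.nan], 2)


class TestScores:
    def test_perfect_information_hits_heritability_ceiling(self, rng):
        """True weights on all causal variants give corr ~ sqrt(h2)."""
        cfg = PGSSimConfig(n_variants=400, heritability=0.4)
        arch = draw_architecture(cfg, rng)
        test = simulate_cohort(arch, cfg, "A", 4000, rng)
        score = test.genotypes @ arch.effects[:, 0]
        r = np.corrcoef(score, test.traits)[0, 1]
        assert r == pytest.approx(np.sqrt(0.4), abs=0.05)

    def test_all_null_architecture_scores_nothing(self, small_cfg):
        rng = np.random.default_rng(3)
        cfg = PGSSimConfig(**{**small_cfg.__dict__, "null_fraction": 1.0,
                              "equal_cov": small_cfg.equal_cov,
                              "amp_cov": small_cfg.amp_cov})
        arch = draw_architecture(cfg, rng)
        a = simulate_cohort(arch, cfg, "A", cfg.n_train, rng)
        b = simulate_cohort(arch, cfg, "B", cfg.n_train, rng)
        ta = simulate_cohort(arch, cfg, "A", cfg.n_test, rng)
        tb = simulate_cohort(arch, cfg, "B", cfg.n_test, rng)
        rep = build_and_evaluate_scores(marginal_gwas(a, b), ta, tb, cfg)
        assert (rep["correlation"].abs() < 0.2).all()

    def test_smoke_run_emits_all_methods_and_cells(self, small_cfg):
        res = run_experiment(small_cfg, alphas=(0.0, 1.0), n_trains=(400,),
                             n_reps=1, seed=9)
        summary = summarize_experiment(res)
        assert set(res["method"]) == {"additive", "additive_asc_gxe_est", "gxe", "mash"}
        assert len(summary) == 2 * 1 * 4 * 2  # alphas x n_train x methods x contexts
        assert res["correlation"].between(-1, 1).all()

    def test_experiment_reproducible_per_cell(self, small_cfg):
        full = run_experiment(small_cfg, alphas=(0.0, 1.0), n_trains=(400,),
                              n_reps=2, seed=5)
        partial = run_experiment(small_cfg, alphas=(1.0,), n_trains=(400,),
                                 n_reps=2, seed=5)
        a = full[full["alpha"] == 1.0].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, partial.reset_index(drop=True))
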