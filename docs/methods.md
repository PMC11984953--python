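# Methods

This note documents the models implemented in `gxetrade`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions that matter for reproducing results.

## Single-locus model and estimators (`estimators`, `decision`)

The generative model is a biallelic autosomal variant with allele count
g ∈ {0, 1, 2} and a continuous trait observed in one of two contexts:

    y ~ Normal(α_A + β_A g, σ²_A)   in context A (n individuals)
    y ~ Normal(α_B + β_B g, σ²_B)   in context B (m individuals)

`ols_stratified` fits OLS within each context; by standard OLS theory the
slope is unbiased with sampling variance V = σ²/Σ(g − ḡ)², which we estimate
with the residual variance (denominator n − 2). `ols_additive` fits a single
OLS over all n + m individuals. Traits are mean-centered *within context*
before any pooled/stratified comparison (`StratifiedEffectModel` does this on
construction): centering leaves all slopes unchanged but makes the identity

    β̂_pooled = ω_A β̂_A + ω_B β̂_B,
    ω_A = Σ_A (g − ḡ_A)² / Σ_all (g − ḡ_pooled)²   (and analogously ω_B)

exact, which the test suite asserts at 1e-10 relative tolerance. Sample
heterozygosity is defined as the genotypic variance Σ(g − ḡ)²/count, so
ω_A : ω_B = n H_A : m H_B holds by construction. The weights need not sum
to 1; they do exactly when the context genotype means coincide, and
approximately at equal allele frequencies.

The decision rule compares MSE(additive) = bias² + ω_A²V_A + ω_B²V_B, with
bias = (ω_A − 1)β_A + ω_B β_B, against MSE(GxE) = V_A. Numerical decisions:

* ties (zero margin) resolve to **additive**, on parsimony grounds;
* monomorphic designs raise a typed `MonomorphicError` naming the offending
  context rather than returning infinite variance;
* the equal-heterozygosity boundary is implemented on the **variance scale**,
  V_A = (m/2n)·Δβ², verified by re-derivation from the MSE equality with
  ω_A = n/(n+m) (the test suite checks the margin vanishes there to 1e-12);
  the sd-scale form is its square root and is intended only for plotting
  against |Δβ|;
* the noise ratio is defined as r = V_A/V_B throughout the API; the
  dimensionless threshold takes V_B/V_A and the conversion happens at the
  boundary of `screen`.

## Genome-wide screening (`screen`)

`classify_loci` applies the dimensionless rule to summary statistics with a
per-trait noise-ratio proxy r (e.g. the ratio of context-specific trait
variances) held constant across variants, and ω_A defaulting to 1/2 (equal
per-context sample sizes and heterozygosity — appropriate for autosomal
variants in sex-stratified designs). Verdicts are threshold-free; the
significance filter (default 5e-8 in the focal context) only restricts which
rows are reported.

Three signal definitions are exposed, because they answer different
questions:

* **plugin** (default for per-variant verdicts and boundary plots): the raw
  squared difference Δβ̂². Inflated by estimation noise — under a pure null
  with equal SEs its mean is 2V_A.
* **corrected**: Δβ̂² − se_A² − se_B², per-variant unbiased for Δβ². Its
  chi-square sampling noise still exceeds the r = 1 threshold with
  probability P(χ²₁ > 2) ≈ 15.7% under the null, so the *fraction* of
  variants labeled GxE-preferred does not approach the truth-level fraction
  in null-dominated panels.
* **shrunk** (default for `fraction_gxe_preferred`): the posterior second
  moment of Δβ under a univariate empirical-Bayes mixture fit to all
  differences jointly. Pure-noise differences collapse toward zero while
  pervasive real differences survive, so the genome-wide fraction tracks the
  rule applied to the (unobserved) true effects; this is the package's
  polygenic answer to a polygenic question.

`fraction_gxe_preferred` samples one variant per LD block (user-supplied
`block_id`), computes the percent preferring GxE, and averages over
`n_block_draws` repetitions (default 10; blocks default to whatever the
table contains — the synthetic generator uses 1700).

`split_validate` predicts the per-variant MSE difference from a training
split (noise-corrected squared bias plus the exact variance terms) and
realizes it on a holdout as (β̂_add,train − β̂_A,holdout)² −
(β̂_A,train − β̂_A,holdout)², whose expectation equals the true MSE
difference because the holdout estimate's own noise cancels in the
difference. Caveat documented deliberately: the calibration table bins on
the *predicted* value, which shares noise with the realization; in
noise-dominated regimes the extreme bins therefore show ordinary regression
to the mean. In simulation, calibration should be judged in bins of the true
margin (as the test suite does); on real data, aggregate (unbinned) means
are the robust comparison.

## Storey q-values (`qvalues`)

π̂₀(λ) = #{p > λ}/(N(1 − λ)) on the grid λ = 0.05, 0.10, …, 0.95, smoothed
with a cubic spline and evaluated at λ = 0.95, clamped to [1e-8, 1] (the
floor avoids zero q-values in extreme-alternative inputs). Below 100
p-values the spline is unstable and the estimator falls back to the single
point λ = 0.5 with a warning. q-values are the step-down minima
q_(i) = min_{j≥i} π̂₀ p_(j) N/j; forcing π₀ = 1 reproduces
Benjamini–Hochberg exactly (asserted against an independent implementation).

## Two-diet amplification study (`gxdiet`, `synthetic.generate_se_surrogate`)

True effects: a fraction (default 0.60) of variants are exactly null in both
diets; the rest are bivariate normal with mean (−0.125, −0.15)
(control, high-sugar) and covariance 0.01·[[1, 1.4], [1.4, 1.96]] — sd
ratio exactly 1.4, correlation exactly 1, equivalent to the affine map
β_sugar = 1.4 β_control + 0.025. There is deliberately **no diet-specific
class** in the generative model. Estimates add normal noise with standard
errors resampled jointly (both diets from the same donor record) from an
empirical SE table or the parametric surrogate.

Classification follows the published four-rule scheme (q < 0.01 / p ≥ 0.1),
evaluated in order with first match winning: no-effect, sugar-specific,
control-specific, shared. The four rules do not partition the outcome
space, so unmatched variants get an explicit fifth label, `ambiguous`
(e.g. q_control < 0.01 with q_sugar ≥ 0.01 and p_sugar < 0.1). Category
shares are reported among the "significant" variants — those assigned
sugar-specific, control-specific or shared; whether ambiguous variants
belong in that denominator is a judgment call, and the counts are always
reported so any denominator can be reconstructed.

The SE surrogate draws correlated log-normal pairs with median ≈ 0.135 and
log-sd 0.4 (SE magnitudes ≈ 0.05–0.3, the scale of the fly-study effect
uncertainties). The between-diet log-SE correlation defaults to 0.95: in
designs of this kind per-variant SE variation is driven mostly by allele
frequency, which both diets share. With these defaults the simulation
reproduces the qualitative phenomenon — a large sugar-specific share among
significant variants and a near-zero (few percent) control-specific share —
despite amplification being the only mode of GxE present. The
control-specific share is not exactly zero at surrogate noise levels: a
variant with a moderate shared effect can fluctuate to significance under
control while fluctuating below p = 0.1 under sugar. Supplying the real
per-variant SE table (`SEResource.from_table`, CLI `--se-table`) is
supported for full-fidelity reproduction.

A known conflict in the source material: the narrative text says 40% null /
60% causal while the procedure specification says 60% null / 40% causal.
The procedural value (60% null) is the default, and `null_fraction` is a
config knob.

## Empirical-Bayes covariance mixture ("mash-lite", `shrinkage`)

Model: true effect pairs β_j ~ Σ_k π_k N(0, U_k) over a fixed grid of 2×2
PSD components; observations β̂_j ~ N(β_j, S_j) with known
S_j = diag(se²). The canonical grid per scale s contains equal-effects,
A-specific, B-specific, independent, and rank-1 amplification components
[[s a², s a], [s a, s]] for a ∈ {1.5, 2, 1/1.5, 1/2}, plus the zero matrix
(once) for additional shrinkage. Default scales are a geometric ladder
(factor 4) bracketing the data's apparent signal variance. Data-driven
(PCA-derived) components are intentionally out of scope.

Only the weights π are estimated: EM on the marginal likelihood
L_jk = N(β̂_j; 0, U_k + S_j) from uniform initialization, relative
log-likelihood tolerance 1e-6, max 1000 iterations. The fit is
deterministic given the data; the log-likelihood trace is retained and its
monotonicity asserted. All 2×2 operations use closed-form determinants and
adjugates, vectorized over variants. Posteriors per component are normal
with mean U_k(U_k + S_j)⁻¹β̂_j and covariance U_k − U_k(U_k + S_j)⁻¹U_k;
the mixture posterior combines them with responsibilities γ_jk ∝ π_k L_jk.
"Pseudo p-values", used only for ranking variants in score ascertainment,
are 2Φ(−|posterior mean|/posterior sd).

`shrink_univariate` is the same machinery with scalar components plus a
point mass at zero; it supplies both the "with shrinkage" score weights
(the method behind those weights was an open choice — univariate EB was
selected, and `shrink=False` disables it) and the shrunk signal of the
screen module (via the posterior second moment).

## Polygenic-score experiment (`pgs`)

Per variant, true effects follow

    (β_A, β_B) ~ π₀ δ₀ + (1 − π₀)[ α N(0, [[1,1],[1,1]])
                                  + (1 − α) N(0, [[3/2,1],[1,2/3]]) ]

with π₀ = 0.5: causal effects are either identical across contexts or
perfectly correlated with 1.5× the standard deviation in context A. The
amplified covariance is reconstructed as [[3/2, 1], [1, 2/3]] — singular,
rank 1, correlation exactly 1, sd ratio exactly 1.5; the
amplification factor is a config knob (a caption-level description of the
same study says 1.4×; the matrix is taken as authoritative). Allele
frequencies f ~ (1/2)Beta(1, 5); genotypes Binomial(2, f), independent
across variants (no LD). Environmental variance is set from the *expected*
genetic variance, σ² = Σ 2f(1−f)β² · (1 − h²)/h² with h² = 0.4 per context,
each context using its own effect vector; broad- and narrow-sense
heritability coincide because the model is purely additive. Singular
mixture components are sampled through an eigendecomposition that drops
zero modes, so perfect cross-context correlation holds to machine precision.

Each replicate simulates training cohorts (n per context), runs vectorized
per-variant marginal OLS (stratified, and pooled on within-context-centered
traits — correct here because variants are independent), and builds four
scores of 833 variants (= ⌊2500 causal / 3⌋ at full scale):

1. additive ascertainment + additive weights;
2. additive ascertainment + per-context GxE weights;
3. per-context GxE ascertainment + GxE weights;
4. mash-lite: pseudo-p ascertainment + posterior-mean weights.

Strategies 1–3 use univariate-EB-shrunk weights by default. Performance is
the out-of-sample Pearson correlation with the trait per context (3000 test
individuals per context at full scale); a constant score is recorded as
correlation 0 with a warning. Replicate RNG streams are keyed on
(seed, α, n_train, rep) so any grid cell reruns identically alone or within
the full grid.

Default experiment sizes: the full-scale design (p = 5000,
n_train ∈ {1000, 50000}) is available through the config; the package's
default *tested* experiment is a reduced replica — p = 600, 300 causal
expected, 100 scored, n_test = 500, n_train ∈ {120, 6000}, 200 replicates —
chosen so the per-variant non-centrality n h²/p_causal matches the
low-power (0.4) and high-power (20) regimes of the full design while a full
ordering comparison completes in minutes. Strategy orderings are asserted
as differences of means with paired Monte-Carlo standard errors, never per
replicate: at low power the additive strategy is on top (the mash-lite
strategy is statistically indistinguishable from it there, since with
little signal the fitted mixture collapses toward the equal-effects and
null components and mimics pooling); at high power with pervasive
amplification mash-lite matches or beats additive; with identical effects
in both contexts (α = 1) additive beats GxE-throughout decisively.

## Synthetic summary statistics (`synthetic.generate_summary_stats`)

Emulates a sex-stratified biobank GWAS: the same effect mixture as the PGS
experiment, per-context sample sizes (default 150,000), and per-variant
estimation noise V = trait_variance/(n · 2f(1 − f)) — the approximation
that, when each variant explains a negligible share of trait variance,
noise is a matter of trait variance and heterozygosity alone. Estimates are
β̂ ~ N(β, V) with SE = √V exactly; block ids are assigned contiguously
(default 1700 blocks). The generator returns the truth table alongside the
stats so downstream estimates can be scored against the generating effects.
It does not emulate LD within blocks, SE estimation error, sample overlap
between contexts, or annotation structure — so tests built on it validate
the estimators' statistical behavior, not robustness to those features of
real data.

## Known limitations

* Two contexts only; no covariates, relatedness, mixed models, or
  multi-allelic sites.
* The constant-r proxy in the screen is an approximation; it is exact in the
  synthetic generator and approximately right for autosomal variants in
  sex-stratified human GWAS, but not in general.
* mash-lite uses canonical components only and a modest grid; it is a
  faithful small implementation of the model family, not a replacement for
  the full method (no data-driven covariances, no R > 2 contexts).
* The calibration display of `split_validate` bins on a noisy predictor;
  see the caveat above.
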