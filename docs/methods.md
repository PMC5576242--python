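# Methods

This note documents the models, priors, numerical choices and limitations
behind `polyrisk`, in the order data flows through the package.

## Synthetic cohorts (`polyrisk.simulate`)

The generator produces the statistical structure the analysis assumes,
not sequence-level realism.

**Genotypes.** Biallelic dosages `x ~ Binomial(2, p)` with ancestral A1
frequencies uniform on `maf_range` (default 0.05–0.5). With two
subpopulations, subpopulation frequencies are Balding–Nichols draws
`Beta(p(1−F)/F, (1−p)(1−F)/F)` around the ancestral value at
differentiation `fst`. A configurable fraction of SNPs (default 5%)
receives palindromic A/T or G/C allele pairs so the QC filters have work
to do; imputation INFO scores are `Beta(8, 2)` draws (mean 0.8, a plausible
post-imputation profile); genotypes go missing independently at
`missing_rate`.

**Effects and phenotypes.** Per-SNP effects on the standardized-genotype
scale follow the four-component mixture with variance multipliers
`(0, 1e−4, 1e−3, 1e−2)` of the genetic variance and mixture proportions
defaulting to `(0.95, 0.03, 0.015, 0.005)` — a sparse architecture in
which the largest component dominates the genetic variance. The drawn
effect vector is rescaled so the realized variance of `g = Zβ` over the
simulated pool equals the target h² *exactly*; liability is `g + N(0, 1−h²)`
and a case is `liability > Φ⁻¹(1−K)`. Standardized-scale effects match the
GRM/BayesR conventions and make the h² rescaling exact.

**Ascertainment.** Rejection sampling from a finite pool: exactly
`n_cases`/`n_controls` are drawn from the pool's cases/controls. The pool
prevalence defaults to `K = 0.1`; simulating at the clinical prevalences
(0.005, 0.002) would need pools of millions, and nothing downstream
requires it — the clinical-utility math is analytic in K. With
`confounding_delta > 0` and two subpopulations, the target subpopulation-2
share is `0.5 + δ/2` among cases and `0.5 − δ/2` among controls, a generic
stand-in for the unknown ascertainment scheme of a real multi-centre
cohort. `eligible_ids` restricts ascertainment to a subset of the pool so
one pool can supply disjoint discovery and external-validation cohorts
plus a reference panel with identical SNP metadata.

**Clinical covariates.** Cases receive three categorical covariates
(onset age group, bowel surgery, disease location) through an
ordered-logit construction: a latent `direction · effect_per_sd · z` plus
logistic noise cut at the logistic quantiles of base category
probabilities, where `z` is the standardized true genetic score among
cases. `effect_per_sd = 0` reproduces the base distribution exactly;
positive values shift high-score cases toward earlier onset, surgery and
ileal location. Controls get missing values.

**Batch artifacts and LD.** `genotype_with_batch_errors` re-renders the
same samples with symmetric genotype errors at a given rate (two noisy
genotypings of identical individuals, the cross-array design).
SNPs are otherwise simulated in linkage equilibrium;
`replicate_snps_with_ld` appends one correlated duplicate per SNP (keep
with probability ρ, else redraw), enough to probe redundancy-invariance of
the effective marker number without coalescent machinery.

**What passing tests do not show.** No LD beyond block copies, no MAF
spectrum from demography, no genotyping error structure beyond symmetric
flips, no covariate measurement error. Conclusions about *relative* method
behaviour under sparse architectures transfer to real data; absolute AUC
values do not.

## Quality control (`polyrisk.qc`)

SNP filters run in the fixed order INFO → MAF → HWE → palindromic
(removal counts depend on order, so it is part of the contract); MAF and
HWE are recomputed from the non-missing genotypes of the current sample
set. Defaults: INFO > 0.6, MAF ≥ 0.01 (0.001 is the convention for dense
immune-locus arrays), HWE exact p ≥ 1e−6, sample missingness ≤ 2%,
relatedness cutoff 0.2. The Hardy–Weinberg test is the exact conditional
test on heterozygote counts, computed with log-gamma weights and no mid-p
correction; it is verified against an exact-rational enumeration oracle to
1e−12 for totals up to 500. Relatedness pruning visits pairs above the
cutoff in ascending index order and removes one member uniformly at random
(seeded), so results are reproducible and the surviving set provably
contains no pair above the cutoff.

## Structure (`polyrisk.structure`)

The GRM is `G = ZZ'/m` with in-sample (or supplied) frequencies,
missing dosages mean-imputed to `2p`, monomorphic SNPs skipped with `m`
adjusted. The effective marker number is `Me = 1/Var(G_jk)` over j<k with
the unbiased variance — meaningful only for unrelated, homogeneous
samples, and invariant to duplicating SNP columns (tested).

Reference PCA takes the SVD `Z_ref = USV'` of the reference panel
standardized by its own frequencies; reference scores are `US` and a study
sample standardized *by the reference frequencies* projects as `zV`, so
self-projection reproduces the reference scores exactly — that
self-consistency is the projection contract (the scaling convention is
otherwise arbitrary). Allele orientation is reconciled by id + allele
match with dosage flips for swapped labels; at least 80% of loading SNPs
must be usable (configurable).

Ancestry adjustment is the OLS residual of the 0–1 status on an intercept
plus the top-k projected eigenvectors (k = 10 by default). A linear rather
than logistic adjustment keeps the "adjusted" phenotype a continuous trait
that the downstream linear machinery (GBLUP, BayesR, linear scans)
consumes directly; the operation is idempotent and the residuals are
orthogonal to the coordinates by construction.

## Predictors (`polyrisk.predictors`)

All four methods emit a `SnpEffectSet` (dosage-scale per-SNP effects +
intercept + training-fold frequencies) consumed by one scorer that
reconciles alleles, flips swapped orientations and imputes missing
dosages from training frequencies. Anything fitted on a training fold
therefore scores any other dataset identically across methods.

**Association scans.** Per-SNP univariate logistic regression (status) or
linear regression (adjusted), with the logistic scan implemented as
Newton–Raphson vectorized over SNP blocks: each SNP has a 2×2 Hessian in
closed form, so genome-wide scans cost a few matrix products per
iteration. Quasi-separated fits (|log-odds| > 30 or non-finite) and
constant-dosage SNPs return NaN and are excluded downstream. Verified
against `statsmodels` to 1e−6.

**GPRS.** Effects are the scan betas for SNPs with `p < cutoff`, zero
otherwise; cutoff 1 (all SNPs) is the default, with a grid helper for
cutoff curves. No LD clumping — the simulator's default independence makes
it moot, and thresholding-only matches the method being benchmarked.

**Elastic net.** Candidate set = `top_m` smallest-p SNPs from the
training-fold scan (default 8000, capped at the available count);
features standardized; penalty chosen by inner 10-fold cross-validated
deviance over a decreasing λ path at fixed mixing `α = 0.5`
(configurable). scikit-learn's saga/coordinate-descent solvers stand
behind this surface; coefficients are mapped back to the dosage scale.

**GBLUP.** REML is computed exactly by profiling the restricted
log-likelihood down to one dimension: with eigendecomposition
`G_tt = UDU'`, for each heritability ratio h the GLS intercept and total
variance have closed forms, and a bounded Brent search (xatol 1e−9)
maximizes the profiled restricted likelihood. This replaces iterative
AI-REML: at package scale the eigendecomposition is cheap, the optimum is
the same, and there are no convergence failures to handle — `h → 0`
boundary fits are flagged and yield constant predictions. Binary status is
used directly as a linear trait. The SNP-BLUP equivalent
(`b = Z'α/m`, ridge with penalty `m·σ²_e/σ²_g`) converts a fit into the
shared effect-set pathway; the two prediction routes agree to ~1e−14 and
are tested against an independent ridge solve.

**BayesR.** Single-site Gibbs sampler in a numba kernel (one sweep is
O(n·m)): per-SNP component indicator from the conjugate marginal
likelihoods, effect from the normal–normal full conditional with residual
updating, mixture proportions from the Dirichlet posterior, variance
components from scaled inverse chi-squares. Priors, chosen as the
package's defaults since the method's literature leaves room:

- `σ²_e ~ SSR/χ²_{n−2}` (Jeffreys-like);
- `σ²_g ~ scaled-inv-χ²(ν = 4, S = Var(y)/4)` — weakly informative, prior
  mean half the phenotypic variance;
- mixture proportions `Dirichlet(1, 0.01, 0.01, 0.01)` by default. The
  small non-null concentrations matter: at desk-scale n the `1e−4 σ²_g`
  component is statistically indistinguishable from the null, and with a
  symmetric Dirichlet(1,1,1,1) the label proportions then random-walk back
  to the prior (a Polya urn) instead of emptying — long-chain emulation
  shows the non-null fraction wandering between 0.3 and 0.95 on pure-noise
  data. The sparse prior follows overfitted-mixture asymptotics
  (components without likelihood support empty; SNPs with real support
  overwhelm prior odds of e⁻⁴·⁶) and restores the intended behaviour:
  non-null proportion < 0.05 on null data with no measurable cost to
  predictive accuracy on sparse architectures. Pass
  `dirichlet_alpha=(1, 1, 1, 1)` for the classical symmetric prior.

Defaults 10,000 iterations / 5,000 burn-in / thin 10, single seeded chain;
the chain trace (σ²_g, σ²_e, π, model size) is returned for diagnostics.
Posterior-mean standardized effects are rescaled to the dosage scale for
scoring. The conditional effect update is verified against the closed-form
normal–normal posterior, and with a single shared non-null variance and a
disfavoured null component the sampler's predictions correlate > 0.98 with
GBLUP, the corresponding ridge limit.

## Evaluation (`polyrisk.evaluation` and `polyrisk.liability`)

**Cross-validation.** Stratified 5-fold by default; every method's scan,
selection and tuning run inside the training fold (the leakage guard in
the test suite holds all methods to CV AUC 0.5 ± 0.05 on pure noise).
External validation scores the held-out cohort with each of the K
fold-models and reports the mean of the K AUCs — fold-model averaging, not
an ensemble score.

**AUC** is the Mann–Whitney estimator (ties half credit), identical to the
trapezoidal ROC area and exactly antisymmetric under score negation.

**Decile odds ratios.** Samples ranked ascending (stable ties), cut into
10 near-equal groups with remainders assigned to the top groups;
`OR_d = (cases_d/controls_d)/(cases_1/controls_1)` with decile 1 ≡ 1.
Zero-control deciles are flagged infinite, not fatal. Across CV models the
table reports `mean ± 1.96·SD/√K` over folds where the OR is defined — a
documented convention, since "±" intervals over CV folds have no canonical
definition.

**Liability conversions.** `auc_to_liability_v` inverts the closed-form
AUC(v, K) relation by bracketed Brent root-finding (the relation is
monotone in v); `expected_decile_or` integrates the disease probability
`Φ((√v·z − t)/√(1−v))` over standard-normal deciles by adaptive quadrature
(epsrel 1e−10), using within-decile integration rather than the
decile-mean plug-in, which materially overstates tail ORs. A vectorized
Monte-Carlo mode evaluates the same decile expectations from sampled
scores and agrees with the quadrature within 2% at 10⁷ draws across the
(AUC, K) grid in the tests; an independent generative oracle (simulate
score and liability jointly, classify, count) was used to fix the expected
values during development.

**Calibration and covariate association.** Calibration slope is the
regression of observed phenotype on predicted score (1 = calibrated).
`score_factor_association` regresses the standardized score on factor
dummies and reports the overall F-test p-value and per-level means.

## Problem sizes and determinism

All randomness flows through a seed-plus-stage-name hierarchy
(`numpy.random.SeedSequence` spawn keys), so every pipeline artifact is
reproducible from config + seed; the pipeline manifest stamps seed, config
hash and package version. Test-suite simulations are sized for a single
CPU: heritability recovery uses 20 replicates at n = 2000 × m = 1000;
the method-ranking comparison 10 replicates at n = 3000 × m = 2000 with
1200-iteration chains (the sparse signal is strong enough that longer
chains change nothing); the leakage and confounding suites run at
n ≈ 800–1200 × m = 400–500. Null/power checks on the covariate generator
use 30–50 replicates with the corresponding binomial pass margins.

## Known limitations

- The simulator's independence default means the effective-marker-number
  and SNP-density analyses only see LD through the block-copy mode.
- GBLUP/BayesR treat 0–1 status as a linear trait (by design, matching
  the benchmarked methods); predicted scores are on the liability-ish
  0–1 scale, not calibrated probabilities.
- The elastic net's inner CV re-standardizes once on the training fold,
  not per inner split; at the package's candidate-set sizes the
  difference is negligible.
- The exact expected-OR values depend on the liability-model assumptions
  (normal liability, bivariate-normal score/liability); real scores with
  heavy-tailed effect distributions can deviate in the extreme deciles.
- `prune_related` is greedy per pair, not a maximum independent set; with
  the 0.2 cutoff and realistic relatedness this matches common tooling
  behaviour but can remove slightly more samples than optimal.
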