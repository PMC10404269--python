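# Methods

`multipgs` implements a three-step framework for polygenic prediction that
combines many polygenic scores (PGS) instead of one: (1) build an *agnostic
library* of PGS from heterogeneous GWAS summary-statistics files, with no
per-score validation data; (2) stack the standardized scores together with
covariates into a single predictor by penalized regression or boosted trees;
(3) evaluate out-of-sample with liability-scale statistics and benchmark
against single-GWAS, individual-level (BLUP) and summary-statistics-index
predictors. Everything runs end-to-end on simulated cohorts, so the package
is also a laboratory for studying when multi-PGS stacking helps.

## The model behind the score library

Each GWAS file contributes marginal effect estimates. On the
standardized-genotype scale, with per-variant sample size n and block LD
matrix R,

    beta_hat = R beta + e,      e ~ N(0, R / n),

and the prior on true effects is spike-and-slab:

    beta_j ~ p * N(0, h2 / (M p)) + (1 - p) * delta_0,

where M is the number of modeled variants, h2 the SNP-heritability and p the
proportion of causal variants. A Gibbs sampler draws each beta_j from its
full conditional: with residual r_j = beta_hat_j - (R beta)_j + beta_j, the
slab posterior has mean r_j / (1 + M p/(n h2)) and variance
(1/n) / (1 + M p/(n h2)); the inclusion probability is the two-component
Gaussian likelihood ratio between N(0, 1/n + h2/(Mp)) and N(0, 1/n). The
hyperparameters are resampled inside the chain — p from
Beta(1 + #causal, 1 + M - #causal) and h2 as the realized genetic variance
beta' R beta (a quadratic form per block, not a sum of squares, so LD is
accounted for) — which is what removes the need for tuning data.

Chains start from a log-spaced grid of p in [1e-4, 0.9]; h2 starts at the
LD-score-regression estimate. The full-scale run configuration is 30 chains,
800 burn-in and 400 kept iterations; the desk-scale default is 10/200/100,
which at m = 2,000 reproduces hyperparameters well (see the acceptance run).
A chain whose h2 trace exceeds `dead_chain_factor` (3) times
max(h2_init, 0.05) is discarded as divergent; surviving chains are filtered
by predictive scale (keep chains whose effect-vector SD is at least 0.95 of
the 95th-percentile scale) and averaged. Two test hooks — fixed (p, h2) and
a deterministic mode that replaces each draw by its conditional posterior
mean — make the sampler exactly checkable: against the closed-form
infinitesimal shrinkage beta_hat/(1 + M/(n h2)) when p = 1 with identity LD,
and against brute-force enumeration of all causal configurations at M = 3.

### LD-score regression

h2 is initialized from an unweighted LD-score regression of chi-square on
l_j = sum_k r2_jk. The intercept is constrained to 1 by default: simulated
(and well-controlled real) summary statistics have no confounding inflation,
and at desk scale the LD-score range (roughly 1–1.7 for AR(1) blocks with
rho = 0.5) is far too narrow to identify a free intercept — free-intercept
estimates swing over the whole [0, 1] clamp range while the constrained
estimator recovers h2 = 0.5 to within ±0.03 at m = 2,000, n = 50,000. A
`intercept="free"` option restores the conventional estimator for data where
confounding is a concern. The same identifiability argument applies to the
cross-trait (genetic-correlation) regression, which runs through the origin.

### Summary-statistics QC

Files are parsed through a column-alias library (editable YAML), odds ratios
converted by ln(OR), Z-only files by z·se, and case-control sample sizes to
n_eff = 4/(1/N_cases + 1/N_controls). Harmonization aligns alleles to the
reference panel (flips negate beta, strand flips are resolved by complement,
A/T and C/G variants are dropped as ambiguous) and is involution-safe. The
SD filter compares sd_ss = 1/(se sqrt(n_eff)) with the genotype-derived
sd_ref = sqrt(2 maf (1-maf)); defaults t_low = 0.5, t_high = 1.1,
t_abs = t_ref = 0.05 follow common LDpred2 QC practice (the thresholds are
config-exposed since published practice varies). sd_ref uses the panel's
genotype MAF, with the file's reported frequency only as a fallback —
the filter is defined as a genotype-vs-summary-statistics discrepancy check,
and reported frequencies at low MAF are too noisy to anchor it. A file
passes to derivation only if strictly more than `min_snps` variants survive
(200,000 at genome scale; scaled down in desk configs).

## Stacking

The score library is standardized (mean 0, variance 1). The lasso stack
minimizes the penalized deviance over [covariates + scores] with per-feature
penalty factors: 0 for covariates (never shrunk) and 1 for scores; the
penalty level is chosen by internal 10-fold cross-validation (minimum
deviance, no 1-SE rule). The solver is a glmnet-style coordinate descent
(IRLS-wrapped for logistic loss) written for this package because the
penalty-factor contract is not available in scikit-learn; it is
cross-checked against R's glmnet in the test suite. L1 is the default
(sparse weights are integral to the simplified stack and the weight
reports); the elastic-net mixing parameter is exposed.

The boosted-tree stack uses XGBoost with eta = 0.01 and nrounds = 10
(logistic objective for binary outcomes, squared error for continuous) —
deliberately the documented full-scale configuration even though it is a
weak learner budget; both knobs are config-exposed. The mixed stack first
boosts covariates only, then feeds that risk score unpenalized into the
lasso over scores — this isolates non-linear covariate structure (e.g. a
sex-by-age interaction, which the simulator can generate) without giving
trees access to the scores. The simplified stack refits on scores with
|weight| > 0.01.

Leakage control: within each evaluation fold, score standardization
parameters, the covariate base model, penalty selection and tree fitting all
use the training split only. Whole-sample standardization is available as a
config option (`standardize="full_sample"`) because the original workflow's
choice is not documented; the default is the leakage-safe variant, and a
sanity property checks the two differ by < 0.01 R2 at n = 10,000.

## Evaluation

Five-fold cross-validation, stratified by case status. For each model the
pooled out-of-sample risk score is evaluated as:

* observed-scale R2 from a *linear* regression of the 0/1 outcome on the
  score (required by the liability conversion, regardless of training loss);
* adjusted R2 = (R2_full - R2_cov) / (1 - R2_cov), the variance explained
  beyond a covariates-only GLM;
* liability-scale R2 via the ascertainment-corrected transformation with
  population prevalence K and sample case proportion P: with
  t = Phi^-1(1-K), z = phi(t), m = z/K, C = K^2(1-K)^2/(z^2 P(1-P)),
  theta = m(P-K)/(1-K) (m(P-K)/(1-K) - t),
  r2_liab = C r2 / (1 + C theta r2). The conversion is applied to R2_full
  and R2_cov separately and then adjusted (transform-then-adjust; the
  reverse order is config-selectable);
* Mann–Whitney AUC;
* quintile odds ratios from a logistic regression of the outcome on
  quintile indicators (middle quintile as reference) plus covariates;
* 95% percentile bootstrap CIs over individuals (B = 10,000 at full scale,
  2,000 in the desk config).

The liability machinery is validated against a liability-threshold
simulation oracle over K in {0.01, 0.05, 0.2} and P in {K, 0.5}, and the
quintile OR against numeric integration of the liability model. A case-case
recoding (exclude comorbid individuals, label A-only 1 and B-only 0) is
provided for disorder-pair prediction. No multiple-testing adjustment is
applied across outcomes; results carry CIs only.

## Benchmarks

*Single PGS*: the target trait's own library score plus the covariate model.

*BLUP PGS*: ridge regression on standardized dosages with
lambda = M(1-h2)/h2, the infinitesimal-model penalty, solved in dual (n x n)
or primal (M x M) form, with out-of-fold scores. This is an exact linear
solve rather than an iterative mixed-model approximation, affordable at desk
scale.

*Selection index over scores* (wMT-SBLUP-style): weights over standardized
library scores from genetic parameters only. The expected phenotype variance
explained by score i is r2_i = h2_i / (1 + M_e/(n_i h2_i)) with M_e the
effective number of independent markers (config default: M / mean LD score
for simulated panels; 60,000 is a literature-typical genome-scale value).
Writing each standardized score as sqrt(r2_i/h2_i) times the standardized
genetic value plus independent noise, the index solves V w = c with
V_ij = r_g(i,j) sqrt(r2_i r2_j/(h2_i h2_j)) (unit diagonal) and
c_i = r_g(i,t) sqrt(r2_i/h2_i) sqrt(h2_t). All intermediates (r2, V, c) are
recorded for audit. The pipeline uses plug-in parameters estimated from the
summary statistics themselves (LDSC h2, through-origin cross-trait slope,
PSD-projected correlation matrix), matching how such an index is used in
practice; an oracle mode with the true simulation parameters exists for
diagnostics.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **LD panel**: AR(1) blocks, rho^|i-j| within blocks of 50 (rho = 0.5),
  independent across blocks; MAF uniform on [0.05, 0.5] in the demo profile.
* **Architecture**: causal indicators coupled across traits through a shared
  per-variant uniform (nested causal sets), causal effects jointly normal
  with correlation r_g, each trait rescaled so beta' R beta = h2 exactly.
  Realized genetic correlations land within ±0.05 of target at m = 10,000.
* **Summary statistics**: the fast *direct* mode samples
  beta_hat = R beta + MVN(0, R/n) per block; the slow *cohort* mode actually
  regresses a simulated external cohort and serves as the oracle for the
  direct mode. Output is on the allele-count scale
  (beta_std / sd, se = 1/(sd sqrt(n))) so emitted files look like real GWAS
  files and exercise the QC path end-to-end.
* **Cohort genotypes**: Gaussian-copula haplotypes — latent MVN per block
  thresholded at the 1-MAF quantile, two haplotypes summed. The latent
  correlations are tetrachorically inverted (Owen's-T bivariate normal CDF,
  vectorized bisection, PSD re-projection) so the realized *genotype*
  correlations match the panel's analytic R; without this correction
  thresholding attenuates LD and the direct/cohort modes diverge. Known
  limitation: binary correlations have an attainability ceiling, so target
  correlations between variants with very unequal MAF are clamped slightly
  low.
* **Phenotypes**: liability = genetic value + optional covariate effects
  (sex, age, sex-by-age interaction on standardized covariates) + Gaussian
  residual scaled to unit variance; case iff liability > Phi^-1(1-K).
  Case-cohort ascertainment keeps all cases and subsamples controls to a
  target case proportion P > K (a generic stand-in; no real register's
  sampling is modeled).
* **Seeds**: one master seed; every operation derives a 31-bit child seed
  from (master, operation tag) via CRC32, recorded in output metadata.
  Fixed seed implies bit-identical outputs.

What passing tests on these simulations do *not* show: robustness to real
allele-frequency/LD spectra, population structure, relatedness, imputation
error, cross-ancestry transfer, or sample overlap between GWAS and target
cohort — all deliberately out of the generator's scope.

## Desk-scale run configuration

The bundled demo (and the acceptance script) uses m = 2,000 variants, a
20-trait library in which the target's own GWAS is small (n = 1,000) and the
19 auxiliaries are large (n = 80,000) with r_g(target, aux) = 0.5 and
r_g(aux, aux) = 0.3, h2 = 0.5, polygenicity 0.05, a cohort of n = 4,000 with
K = 0.2, and B = 2,000 bootstrap resamples. This is the regime the framework
targets — a phenotype whose own GWAS is underpowered but which is genetically
correlated with many well-powered ones — and the full pipeline completes in
a few minutes on one CPU. The genome-scale defaults (200,000-SNP gate,
30/800/400 sampler, B = 10,000) remain the documented full-scale profile.

## Numerical notes

* Coordinate descent converges on max weighted-coordinate update < 1e-7;
  IRLS working weights are floored at 1e-5; logistic linear predictors are
  clipped at ±30 for stability.
* Separation in the unregularized covariate GLM (non-finite or |log-odds|
  > 30 coefficients) triggers a tiny-ridge refit, flagged in the model.
* Quintile boundaries use ordinal ranks (stable tie-breaking); a quintile
  with an empty case or control cell is flagged degenerate and its OR left
  infinite with undefined CI.
* Duplicate variant ids keep the smallest-SE record; near-constant library
  columns (SD < 1e-8) are dropped with a logged reason.
* Non-PSD genetic-correlation inputs are rejected for the simulator but
  plug-in *estimates* are projected to the nearest correlation matrix
  (eigenvalue clipping) for the selection index.
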