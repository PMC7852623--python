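# Methods

`cytogxe` implements an integrative imaging-genetics analysis that asks
whether the genetic variants of candidate cytokine/chemokine genes moderate
the association between a prenatal environmental exposure (maternal
depressive symptoms) and neonatal brain morphology, restricting attention to
genes that are demonstrably active in the corresponding brain region during
gestation. This note records the models, the numerical choices, what the
synthetic generators do and do not emulate, and the open design decisions we
resolved.

## 1. Developmental expression screen

For each gene *g* and fetal brain region *r*, expression is modeled as a
linear function of post-conceptional age (pcw),

    expr = b0 + b1 * age + e,

fit with a Huber M-estimator so that a few aberrant specimens cannot flip a
trend. The estimator is IRLS with tuning constant c = 1.345 (95% Gaussian
efficiency), scale re-estimated each iteration as MAD(resid)/0.6745,
iterated to a relative parameter tolerance of 1e-8 (at most 200
iterations). The slope variance uses the standard Huber sandwich with the
MASS-style small-sample correction factor; when every standardized residual
stays below c the fit and its covariance collapse exactly onto OLS. Two-
sided p-values use a t reference with n - 2 df. The robust estimator and
its tuning are configurable; Huber/1.345 is the field's default for trend
fits and is cross-checked in the tests against an independent IRLS
implementation (statsmodels RLM).

Multiplicity is handled by one Benjamini-Hochberg pass jointly across the
full gene x region grid (a per-region option exists but is off by default);
cells with adjusted p below q = 0.01 enter the region -> gene map that
restricts the downstream interaction scan. Trend direction is the sign of
the robust slope.

**Small-sample calibration.** The robust t-approximation is known to be
anti-conservative deep in the tail at small n; we measured the null tail
P(p < 1e-4) at 5.0e-4 (n = 14), 2.0e-4 (n = 30), 1.45e-4 (n = 50), 
approaching nominal as n grows. Two consequences: (i) the per-test null
rejection check is run at n = 40, where the 5% level holds to within
[0.03, 0.07]; (ii) the FDR-control experiment (five planted trends among
208 x 12 cells, 400 replicates) is designed at n = 100 specimens per
region, where per-test miscalibration is secondary to the BH property under
test. The expression generator's *default* stays at 14 specimens per
region, mirroring the size of real fetal post-mortem expression resources,
and users should read screen p-values at that n as approximate in the far
tail.

## 2. The MixGE gene-set interaction test

For one brain measure Y, covariates X (sex, age at scan, total brain
volume, maternal education, ethnicity), environment score E (EPDS total)
and the dosage matrix G of one gene's SNPs (minor-allele coded after QC),
the model is

    Y = Z beta + diag(E) G pi + diag(E) G delta,      Z = [X, E, G],

with pi a single fixed "accumulative" interaction coefficient shared by the
gene's SNPs and delta a vector of SNP-specific "heterogeneous" deviations
treated as random effects with Var(delta_j) = tau. Note that the SNP main
effects are part of the null design — the interaction is tested conditional
on all main effects — which distinguishes this construction from plain
SKAT-style kernel tests.

The null hypothesis pi = 0, tau = 0 is addressed in two parts:

* **Burden (accumulative) test.** The single regressor
  b = E_c ∘ rowsum(G_c) (centered environment times the row sum of
  column-centered dosages) is added to the null model and its coefficient
  pi-hat is t-tested on the residual df. With one SNP this is exactly the
  classical E x G interaction t-test. Centering is internal; p-values are
  invariant to it because the main effects absorb the difference.

* **Variance-component (heterogeneous) score test.** With
  M = diag(E_c) G_c and r the null residuals, the score statistic is
  Q = ||M' r||^2 / sigma-hat^2, with kernel weights lambda_k the nonzero
  eigenvalues of M' P0 M (P0 the null residual-forming projection). The
  familiar reference for such statistics is the mixture
  sum_k lambda_k chi2_1 with sigma-hat treated as known; we instead use
  the *finite-sample-exact studentized* null, which accounts for the
  estimated residual variance: under Gaussian errors,

      P(Q > q) = P( sum_k (lambda_k - q/df) chi2_1
                     - (q/df) chi2_{df-m} > 0 ),

  a signed chi-square mixture at threshold zero built from the same
  eigenvalues (df = residual df, m = kernel rank). This is exact at any
  df, converges to the sum-lambda_k-chi2 reference as df grows, and — the
  property that motivated the choice — agrees with residual-permutation
  calibration even when the SNP count is comparable to the residual df,
  where the sigma-fixed mixture is visibly off (we measured a 0.037
  discrepancy from a 20,000-draw permutation p at n = 60 with 16 SNPs,
  versus well inside Monte-Carlo noise for the studentized form). With
  one SNP it reduces exactly to the classical single-term F(1, df-1)
  (equivalently two-sided t) interaction test, so all three tests collapse
  onto the same classical answer in the single-variant limit; the
  squared-score chi2(1) version of that reduction is recovered in the
  large-df regime.

* **Combination.** The default combiner is Fisher's
  T = -2(log p_burden + log p_vc) calibrated by Freedman-Lane permutation:
  null residuals are permuted, re-projected onto the null residual space,
  and both component tests recomputed per draw (each with its own
  re-estimated residual variance); the reported p is the add-one empirical
  tail (1 + #{T* >= T}) / (1 + B), B >= 2000 by default (configurable; the
  bundled end-to-end runs use smaller B for speed). A fast analytic bound,
  2 min(p) capped at 1, is available as `min_p_bonf`. The permutation
  machinery doubles as the package's ground-truth oracle for all three
  tests.

**Mixture-of-chi-square tails.** Both the studentized null and the
classical nonnegative mixture are computed by exact numerical inversion of
the characteristic function (Imhof's integral). Generic adaptive
quadrature is unreliable on the oscillatory, slowly decaying nonnegative-
mixture integrand, so that implementation splits the integral at the zeros
of sin(theta(u)), applies 16-point Gauss-Legendre per half-period, and
accelerates the alternating tail series by iterated averaging; the
studentized (threshold-zero, signed-weight) integrand has bounded phase
and a rapidly decaying envelope and is integrated on a geometric
Gauss-Legendre grid. One-weight and equal-weight cases use closed forms
(scaled chi2, F). Accuracy is ~1e-10 against the equal-weight exponential
closed form and within Monte-Carlo error of large-scale simulations across
weight/df profiles. The Liu four-moment approximation serves only as a
recorded fallback (`method_flags`: "imhof" vs "liu") if an inversion
reports trouble. Inside a permutation loop the eigenvalues and df are
fixed, so batch evaluation interpolates log-SF through 48 exact nodes
(monotone PCHIP), keeping the interpolation error far below permutation
resolution.

**Calibration measured under the generative model** (n = 300, 8 SNPs,
exchangeable LD 0.5, 1000 replicates): rejection at the 5% level 0.059
(burden), 0.055 (VC), 0.052 (combined), all Uniform(0,1) by KS at the 1%
level; analytic VC p within 3 binomial SE of a 20,000-draw permutation p
across a 20-instance sweep spanning n ∈ {60, 200}, 1–16 SNPs, LD ∈
{0, 0.8}.

**SNP weighting** is identity by default (no weights are standard for
candidate-gene sets of common variants); a Beta(maf; 1, 25) option is
exposed for rare-variant-style weighting. Significance in the scan is
reported as raw p per (gene, measure) at alpha = 0.05, matching
candidate-gene reporting practice; a BH column across the scan is available
but off by default. Left/right measures are separate outcomes; no bilateral
averaging.

Degenerate inputs are flagged rather than failed: E identically zero gives
Q = 0, p = 1; a numerically constant burden regressor gives p = 1; rank-
deficient design columns are dropped (logged) before fitting, and n <=
columns raises "insufficient df".

## 3. Cohort handling

EPDS: ten items scored 0-3, items 3 and 5-10 reverse scored (3 - raw),
total in [0, 30]; missing items are never imputed — dyads with incomplete
EPDS are excluded. Internal consistency is Cronbach's alpha on the scored
items. Inclusion applies, in order: genotype availability, EPDS
availability, demographics completeness, gestational age >= 34 weeks,
birth weight >= 2000 g, 5-minute APGAR >= 9; the audit attributes each
dyad to the first failing criterion, so counts always conserve
(kept + removed = input). Maternal education is coded ordinal 0-4 on the
five-level ladder (a categorical option exists); sex and ethnicity are
dummy-coded against the alphabetically first level; constant covariates are
retained with a warning and dropped downstream by the rank check.

## 4. Genotype QC

VCF v4.2 (GT, or DS for fractional dosages) and dosage-TSV readers;
multiallelic records and SNPs without a gene assignment are dropped with
logged counts. QC order: call rate (max missing 0.05), MAF (min 0.01), then
the two-sided exact Hardy-Weinberg test (conditional on allele counts,
summing configurations no more likely than observed) with Bonferroni
correction across all tested SNPs at family alpha 0.05 (BH optional); the
exact test is only applied to hard calls, as fractional dosages carry no
genotype counts. Thresholds are configurable; MAF/call-rate defaults are
the field's conventional values. Survivors are oriented to the minor allele
(dosage flipped and alleles swapped when the alt frequency exceeds 0.5;
ties at exactly 0.5 keep the alt allele; idempotent), then remaining
missing dosages are mean-imputed per SNP and flagged. Allele orientation
provably cannot change the VC p (the kernel is sign-invariant) and cannot
change any p for a single SNP; the multi-SNP burden regressor, like all
burden tests, does depend on the coding — which is exactly why a fixed
minor-allele orientation is applied once, upstream.

## 5. GES post hoc

The genetic expression score sums, over a gene's eQTL-flagged SNPs, the
dosage of the expression-increasing allele (direction -1 contributes
2 - dosage; absent direction annotation falls back to the minor-allele
count), so higher GES means higher predicted expression. eQTL membership is
consumed as a binary flag — the thresholding that defines "an eQTL" is
upstream of this package. "High/low GES at mean +- 1 SD" is ambiguous
between subgroup fits and Aiken-West evaluation points; both are
implemented. The default is the evaluation-point mode (one moderated
regression Y ~ X + E + GES + E:GES, slopes evaluated at mean +- SD with
delta-method SEs) because it uses all subjects and matches simple-slope
terminology; the subgroup mode reproduces two-cloud scatter renderings. In
the evaluation-point mode the high-low slope difference equals
2 sd(GES) beta_int identically. The outcome is z-scored (ddof = 1) before
fitting, matching standardized reporting; the covariates are exactly the
main model's set.

## 6. Synthetic generators: what they emulate, and what they do not

* Expression: specimens evenly spaced over 8-26 pcw (default 14 per
  region, as in real fetal post-mortem resources), one linear trend per
  planted (gene, region) cell, flat unit-variance Gaussian background
  elsewhere, optional symmetric outlier contamination.
* Genotypes: latent Gaussian copula with exchangeable within-gene
  correlation (sufficient to stress the VC eigenstructure; real haplotype
  block structure is not modeled), thresholded to exact HWE margins at the
  drawn MAF; missingness completely at random.
* Cohort: EPDS items from a one-factor thresholded-normal model with
  loading 0.617 and cuts (-0.455, 0.996, 2.030), calibrated once by
  simulation to total mean ~ 8.56, SD ~ 4.50, alpha ~ 0.82; ethnicity
  45.3/41.6/13.0% (Chinese/Malay/Indian), five-level education ladder,
  sex ~ 54% male, age at scan ~ N(1.41, 0.52) weeks, total brain volume
  ~ N(548.7, 43.5) cm^3, and regional volumes/thickness with the cohort's
  descriptive means and SDs, mildly coupled (r = 0.4) to total brain
  volume.
* Outcomes: drawn exactly from the MixGE equation with delta drawn once
  per dataset (random-coefficient reading, the adopted interpretation of
  the per-SNP random effect) and returned as ground truth.

Passing tests on these generators demonstrate the statistical machinery —
calibration, recovery, FDR control, oracle equivalence — under the stated
structure. They do not demonstrate robustness to population stratification,
haplotype LD, non-Gaussian measure distributions, scanner batch effects, or
informative missingness, none of which are modeled.

A deliberate consequence of the design: the 13 anatomical region labels
(AMY, HIP, A1C, ACC, DFC, IPC, ITC, M1C, OFC, S1C, STC, V1C, VFC) form the
canonical reporting order, while the default simulated expression grid uses
the first 12, matching the screen's customary genes x 12 layout.

## 7. Reproducibility

Every generator and every permutation consumes an explicit seed;
per-(gene, measure) scan seeds are derived from the run seed plus stable
CRC32 hashes of the identifiers, so results are independent of iteration
order. The pipeline writes a manifest with a config hash that excludes only
the output directory: hash + seed determine every output byte, and the
end-to-end test asserts bit-identical reruns. Problem sizes in the test
suite (replicate counts, permutation counts, bundle sizes) are chosen so
the default suite demonstrates each property at useful Monte-Carlo
resolution while remaining quick to run; the acceptance script scales the
same computations with its own sizes.
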