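# Methods

## The problem

A genome-wide environment interaction study (GWEIS) asks, for each SNP in
turn, whether the SNP's effect on a quantitative phenotype depends on an
environmental exposure. Compared to an ordinary GWAS this raises three
methodological problems that this package is built around:

1. **Heteroscedasticity.** If the residual variance of the phenotype varies
   with the environment — which is common, and which an interaction model
   cannot distinguish from a mean effect without extra assumptions — the
   classical constant-variance standard error of the interaction coefficient
   is anti-conservative, and the genome-wide scan fills with spurious hits.
2. **Covariate-interaction confounding.** Adjusting for a covariate's main
   effect does not stop a covariate-by-SNP or covariate-by-environment
   interaction from loading onto the SNP-by-environment product term when
   the covariate is correlated with the environment.
3. **Evaluation of aggregate interaction signal.** Single-SNP interaction
   effects are small; their joint predictive value is assessed with
   interaction-based polygenic scores in a hold-out sample, measured strictly
   beyond what gene and environment main effects already explain.

## The regression model

For phenotype `Y`, SNP allele count `G` (0/1/2; 0/2 for male X), environment
`E` (ordinal and count exposures coded as consecutive integers from 0 and
analysed as continuous), and covariate vector `C`:

    Y_i = b0 + G_i bG + E_i bE + G_i E_i bGxE
            + C_i' bC + C_i' G_i bCxG + C_i' E_i bCxE + eps_i

The parameter of interest is `bGxE`. The design has `4 + 3k` columns for `k`
covariates. Fitting is ordinary least squares with per-SNP listwise deletion
of missing values, so the complete-case `n` can differ across SNPs and
environments. Monomorphic SNPs or otherwise rank-deficient designs are
skipped with a logged reason rather than aborting the scan.

Inference on `bGxE` uses the Huber-White sandwich covariance

    (X'X)^-1 X' diag(e_i^2) X (X'X)^-1

with raw squared residuals (HC0; HC1's `n/(n-p)` rescaling is available as an
option and matters only at small `n`). The test statistic is
`t = bGxE / SE_sandwich` against a t distribution with `n - p` degrees of
freedom — indistinguishable from normal at biobank `n`, correct at test
fixture `n`. The main-effect GWAS mode fits `Y ~ 1 + G + C` with model-based
errors, the convention of standard GWAS software.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, at
sizes a desk machine handles, and is itself first-class tested code.

* **Genotypes**: each SNP is the sum of two haplotype alleles obtained by
  thresholding latent standard normals at the `Phi^-1(MAF)` quantile, which
  yields Hardy-Weinberg genotype frequencies exactly. Within an LD block the
  latents share a common factor with loading `sqrt(rho)` and one MAF is drawn
  per block (uniform over `maf_range`, default 0.01-0.5), so `rho = 1` gives
  identical columns and intermediate `rho` gives tunable dosage `r^2` without
  coalescent machinery. Blocks are independent. Positions are laid out on one
  chromosome at a configurable spacing (default 10 kb) so the clumping window
  logic is exercised.
* **Environments** are continuous, ordinal (2-7 levels), or bounded counts;
  the discrete types are equal-frequency rank-binnings of a latent unit
  normal. An environment can be made heritable: a fraction `h2` of its latent
  variance comes from a configured causal SNP set, which lets tests construct
  the situation where an apparent GxE is partly gene-gene interaction.
* **Covariates** mimic a biobank adjustment set: an age analogue
  (N(57, 8^2)), a sex indicator, PC-like standard normals, and
  assessment-centre indicator columns.
* **Phenotype**: built term by term from the model above with configurable
  sparse effect maps; all-zero defaults give a global null. Noise is
  `N(0, sigma^2)` or multiplicatively heteroscedastic
  `sigma_i^2 = sigma^2 exp(theta E_i)` — the standard variance form for
  demonstrating interaction-test inflation; `theta = 0.5` roughly doubles the
  residual variance per 1.4 SD of `E`. The `likert12` option rank-bins the
  linear phenotype into 13 equal-frequency levels, the 0-12 scale of a
  12-item dichotomous questionnaire sum score; equal-frequency binning is the
  least-assumption choice since no generative model for the observed score
  distribution is assumed.
* **Reproducibility**: one master seed spawns independent named substreams
  (genotypes, environments, covariates, phenotype, hold-out split), so every
  stage is independently re-runnable and a rerun is bit-identical.

What the generator does **not** emulate: realistic human LD maps and
recombination, imputation uncertainty (info scores are consumed as metadata
only), relatedness, population structure beyond PC-like noise covariates,
or item-level questionnaire response processes. Passing tests therefore show
that the statistical machinery is correct under its stated assumptions, not
that those assumptions hold in any particular real cohort.

## Post-processing

* **QC filter**: MAF >= 1%, missingness <= 5%, imputation info >= 0.9; SNPs
  without an info score pass that filter trivially (logged). Idempotent.
* **LD clumping**: greedy — repeatedly take the lowest-p unassigned SNP below
  the p threshold as an index SNP and absorb unassigned SNPs on the same
  chromosome within ±250 kb with dosage `r^2 >= 0.2` (score construction) or
  `0.8` (reporting independence). `r^2` is the squared Pearson correlation of
  dosages over pairwise-complete samples — the genotype-correlation
  convention, sufficient at these thresholds — with constant columns flagged
  NaN. Equal p-values tie-break on (chr, bp) then ID, making output invariant
  to input row order.
* **Inflation**: genomic lambda = median chi-square(1)-transformed p over
  0.4549 (the null median), plus QQ tables.
* **Layered Bonferroni**: per-analysis (`alpha / n_tests`), cross-environment
  (further `/ 25`), and `0.05 / 25 / 2` for the two interaction-score
  families.

## Polygenic scores

From clumped index SNPs at each threshold of the grid
`.001, .05, .1, .2, ..., .9, 1`:

    PRS_i          = sum_j G_ij b_j^G
    iPRS_i^G       = PRS_i * E_i
    iPRS_i^GxE     = sum_j G_ij E_i b_j^GxE
    iPRS_i^{G+GxE} = sum_j G_ij (E_i b_j^GxE + b_j^G)

Missing dosages in scoring are imputed with twice the training effect-allele
frequency (the PLINK `--score` convention); mismatched effect alleles are
flipped, unresolvable mismatches are errors. Predictive ability is
`delta = adjR2(full) - adjR2(covariate-only)` in the hold-out sample with a
nested-model F test, `df = (1, n - p_full)`. For the interaction scores the
covariate-only model already contains the environment, the GWAS main-effect
PRS, and their interactions with the base covariates; the GWAS (not the
interaction scan) supplies the main-effect PRS because a SNP set pruned on
interaction p-values underestimates the genome-wide main-effect contribution.
Adjusted R2 is used because the full R2 is biased upward with many
predictors; `delta` can legitimately be negative. The best grid point is the
one maximising `delta` (ties to the sparser score). Score weights carry a
fingerprint of their training samples and evaluation refuses a hold-out that
overlaps it.

## Numerical choices

* Rank deficiency is declared when `lstsq` reports deficient rank or the
  smallest singular value falls below 1e-8 of the largest.
* The sandwich matrix is symmetrised (`(V + V')/2`) against accumulation
  asymmetry.
* Missing genotypes are NaN throughout — never a numeric sentinel.
* Dosages count bim allele A1 by default; the counted allele is recorded in
  every output row. Interaction p-values are invariant to an allele flip
  (the t statistic changes sign); coefficients are not, which is why the
  convention is explicit rather than implicit.
* Environment values enter models raw (uncentered); the interaction test is
  invariant to affine recoding when all covariate-interaction terms are
  present, coefficients are not.

## Test problem sizes

The suite demonstrates each statistical property at the smallest size where
it is decisive: calibration of the robust vs model-based test on 2,000 null
SNPs at n = 5,000 with theta = 0.5; confounding control over 400 replicates
at n = 2,000; estimator unbiasedness over 200 replicates at n = 50,000
(single-SNP fits); score-evaluation null calibration over 20 end-to-end
replicates at n = 4,000, and interaction-variance recovery (a planted common
variant contributing 2% of phenotypic variance) averaged over 3 replicates
with a 10,000-person hold-out, matching the generative share within ±0.5
percentage points. The planted-SNP pipeline-detection fixture fixes its MAF
range to common variants (0.2-0.5) so the planted effect is powered by
design rather than by the luck of a rare-variant draw.

## Known limitations

* Hard-call genotypes only (no BGEN/VCF dosages, no phasing).
* No mixed-model or relatedness correction; samples are assumed unrelated.
* Single-environment models only; no joint multi-environment or 2-df joint
  SNP+interaction tests.
* Gene- and gene-set-level aggregation is out of scope; only the associated
  Bonferroni arithmetic is provided.
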