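# Statistical methods

This note documents the models, estimators, default parameters and known
limitations of `snpcox`. All survival statistics are implemented from first
principles (numpy/scipy only); lifelines appears solely as a test oracle.

## Data model

A cohort is one row per patient: two censored endpoints — overall survival
(time from start of radiotherapy to death, months) and freedom from
loco-regional relapse (ffLRR) — clinical covariates, and one biallelic
genotype call per SNP as a two-character string (e.g. `"GA"`, normalised to
sorted order). Missing values use the token `NA` in CSV. Patients with a
missing genotype at any candidate SNP are excluded from model fitting for
that endpoint; missing p16 status is retained through a dummy variable
(`p16_missing`) so the average effect of the unknown stratum is absorbed
rather than the patients dropped.

### Covariate coding

- `log_gtv` — natural log of the combined gross tumor volume (cm³).
- `p16_pos`, `p16_missing` — indicators against the p16-negative reference.
- `chemo_mmc` — mitomycin-C-based versus cisplatin-based chemotherapy.
- `"<rs>-1"` — homozygote-major indicator; `"<rs>-2"` — homozygote-minor
  indicator. Major/minor status is assigned from the sample allele counts
  (ties broken toward the lexicographically smaller allele), making the
  coding reproducible without external annotation and free of a committed
  dominant/recessive/additive model.

## Population-genetics QC

- **Hardy–Weinberg**: plain 1-df asymptotic χ² goodness-of-fit test without
  continuity correction — allele frequency estimated from the genotype
  counts, expected counts n·(p², 2pq, q²). Monomorphic SNPs are untestable
  and raise.
- **Linkage disequilibrium**: Pearson correlation of the 0/1/2 minor-allele
  dosage scores over patients with complete calls at both loci (numerically
  identical to the correlation computed from the 3×3 cross-table), with a
  Fisher-z 95 % CI (bootstrap optional). Association is tested by a
  Monte-Carlo Freeman–Halton (Fisher) exact test: tables are sampled with
  fixed margins and the p-value is the add-one–smoothed fraction with
  log-probability ≤ the observed table's (default `n_mc = 1e5`, seeded).
  Exhaustive enumeration of 3×3 tables at n ≈ 132 is infeasible.

## Survival machinery

- **Cox partial likelihood**: Breslow tie handling by default (matching the
  convention under which the score test equals the log-rank test), Efron
  available via `ties="efron"`. Newton–Raphson with step-halving (max 10
  halvings), convergence when the relative log-likelihood change is below
  1e-9, max 50 iterations. Fits with |β| > 20 or a Wald SE > 100 are flagged
  non-converged (monotone-likelihood/separation diagnostic). Rank-deficient
  or constant design columns raise with the offending column named.
- **Score test**: U(0)ᵀ I(0)⁻¹ U(0) with the gradient and information of the
  log partial likelihood at β = 0. For a single binary covariate this equals
  the log-rank χ² (verified to 1e-9 in tests).
- **Kaplan–Meier**: product-limit estimate; at tied times events are
  processed before censorings.
- **Two-sample tests**: weighted observed-minus-expected sums with
  hypergeometric variances; weight 1 gives the log-rank test, weight n_t
  (pooled at-risk count) gives the Gehan–Breslow Wilcoxon test, which
  up-weights early differences.
- **Proportional-hazards check**: Kolmogorov-type supremum test on the
  standardized cumulative Schoenfeld-residual (score) process. The null
  distribution is simulated by Gaussian-multiplier resampling including the
  −I(t) I⁻¹ Σ Gᵢ rᵢ correction term; the p-value is the fraction of
  resampled suprema ≥ the observed one (default 1000 realizations, seeded).
  Under exact proportional hazards the rejection rate at the 0.05 level is
  ≈ 0.06 over 200 simulated datasets; against crossing hazards the power is
  near 1 at n = 150.

## Model selection

- **Best k-subset by score χ²**: all C(m, k) subsets are scored at the null
  using batched submatrix solves (a slogdet validity mask plus a stacked
  linear solve), so one fold with C(20, 6) = 38 760 subsets costs
  milliseconds. Candidates are scored in sorted-name order and ties resolve
  to the first maximum, making selection independent of input ordering. An
  enumeration guard (10⁶ subsets) prevents accidental combinatorial blowups.
- **Forward selection**: at each step the candidate with the smallest
  score-test entry p-value (1 df, evaluated at the current MLE with the
  candidate at 0) enters if p < 0.05 (configurable).

## LOO-CV classifier

For each patient i: remove i, select the best k-subset on the remaining
n − 1 patients, fit the Cox model on that training set, compute patient i's
prognostic index PI = xᵢᵀβ̂, and classify i as high risk iff PI strictly
exceeds the training-set median PI. Prevalence of a covariate is the
fraction of the n folds whose selected subset contains it. If fewer than
k_max covariates reach prevalence strictly above 0.60, k is reduced to that
count and the whole LOO pass is re-run once (the published reduction rule).
`always_include` forces covariates into every subset; `allow_fold_failures`
tolerates folds whose fit fails (they contribute no subset). The two
cross-validated risk groups are compared by log-rank and Wilcoxon tests and
Kaplan–Meier curves.

Defaults: `k_max = 6`, prevalence threshold 0.60 (strict), minimum cohort
size 20.

### Known limitation: the naive cross-validated log-rank is anti-conservative

Applying the standard log-rank test to LOO-CV risk groups as if they were a
fixed grouping — which is what the published procedure does — inflates the
type-I error. Measured with this implementation under pure-noise candidates
(n = 150, six binary candidates, k = 2, 200 replicates), the rejection rate
at the 0.05 level is ≈ 0.38–0.44 depending on the censoring pattern, against
a nominal 0.05. Two mechanisms were isolated:

1. the cross-validated labels of different patients are built from almost
   identical training sets (n − 1 overlap), so they are strongly dependent,
   violating the independence behind the log-rank variance; and
2. under the null the sign of the fitted prognostic index is unstable across
   folds, which by construction manufactures group contrast.

The log-rank implementation itself is exactly nominal on fixed random splits
of the same generator, so this is a property of the procedure, not a defect
of the test. The package reproduces the procedure faithfully; cross-validated
p-values from `compare_cv_groups` should therefore be read as descriptive,
not as calibrated significance levels. A permutation reference distribution
would fix the calibration but is out of scope here.

## Synthetic cohort generator

- **Genotypes**: each SNP draws two alleles at its target MAF (HWE by
  construction). A pair of SNPs can be put in LD: four haplotype frequencies
  are solved by moment matching the two MAFs and the target genotype
  correlation r (D = r·√(p₁q₁p₂q₂), with the feasibility bounds on D
  enforced and reported), and each patient draws two haplotypes. Defaults:
  eight DNA-repair SNPs at the observed genotype frequencies of a
  132-patient head-and-neck cohort, with r = 0.68 between the two ERCC2
  coding SNPs. Empirically the MAF error is < 0.01 at n = 10⁴ and the
  genotype correlation is within 0.01 of target at n = 5000.
- **Clinical covariates**: log-normal GTV (median 37.3 cm³, log-SD 0.72,
  clipped to the observed range), p16 positive/missing rates 18/132 and
  8/132, mitomycin-C rate 24/132, plus age, gender, N category and tumor
  site at the observed margins.
- **Event times**: Weibull with shape 1.2 for both endpoints; the linear
  predictor uses published univariate log-hazard-ratios as marginal effect
  targets and is centred at the theoretical covariate means so the baseline
  scale controls the marginal event rate. Censoring is the administrative
  horizon of a uniform(36, 108) month accrual window. The baseline scales
  (OS 102, ffLRR 132) were calibrated once, before any acceptance testing,
  to the published event counts: the defaults yield ≈ 65 deaths and
  ≈ 53 relapses in expectation at n = 132.

Scope: the generator matches marginal distributions, one LD pair and
univariate effect sizes. It does not model inter-site heterogeneity,
competing risks, genotype-by-treatment interaction, or joint (multivariable)
effect structure, and the two endpoints are conditionally independent given
the covariates.

## Numerical choices

- Linear predictors are max-shifted before exponentiation; risk-set sums use
  reverse cumulative sums over the time-sorted data.
- Batched subset scoring validates each submatrix with `slogdet` before the
  stacked solve; singular or non-positive-definite submatrices score NaN and
  are excluded from the argmax.
- All Monte-Carlo procedures (Fisher exact, supremum test, generator) take
  explicit seeds and are deterministic given them.
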