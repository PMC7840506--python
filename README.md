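# snpcox

Prognostic SNP classifiers for censored survival endpoints, built from first
principles: Cox proportional-hazards regression, score-test best-subset
selection, and a leave-one-out cross-validated (LOO-CV) high/low-risk
classifier, together with the population-genetics quality control
(Hardy–Weinberg, linkage disequilibrium) needed for germline genotype
covariates and a synthetic cohort generator for testing the whole pipeline.

The package targets the common design of small oncology biomarker cohorts:
~100–200 patients, two censored endpoints (overall survival and freedom from
loco-regional relapse), a handful of clinical covariates, and biallelic SNPs
recoded into homozygote-major (`<rs>-1`) and homozygote-minor (`<rs>-2`)
indicator contrasts.

## What is implemented

- **`snpcox.survival`** — Cox partial likelihood (Breslow ties by default,
  Efron optional) with Newton–Raphson and step-halving; Wald CIs; score test
  at the null (identical to the log-rank test for a single binary covariate);
  Kaplan–Meier curves; log-rank and Gehan–Breslow Wilcoxon two-sample tests;
  a Kolmogorov-type supremum test of the proportional-hazards assumption via
  Gaussian-multiplier resampling of the cumulative score process.
- **`snpcox.selection`** — exhaustive best-k-subset selection by the score
  χ² statistic (vectorised over all subsets), and forward selection with a
  score-test entry criterion.
- **`snpcox.loocv`** — the LOO-CV classifier: per-fold best-subset selection
  and Cox calibration, classification of each held-out patient as high or low
  risk by their prognostic index relative to the training median, covariate
  prevalence across folds, and the >60 % prevalence reduction rule.
- **`snpcox.popgen`** — Hardy–Weinberg χ² goodness-of-fit test, genotype
  (dosage) Pearson correlation with Fisher-z CI, Monte-Carlo Freeman–Halton
  exact test for 3×3 genotype tables.
- **`snpcox.simulate`** — synthetic cohorts: HWE genotypes with optional
  pairwise LD (haplotype moment matching), clinical margins, and Weibull
  event times for both endpoints under log-linear covariate effects.
- **`snpcox.cohort` / `snpcox.pipeline` / `snpcox.cli`** — CSV schema and
  validation, the end-to-end report bundle, and the `snpcox` command line.

## Worked example

Simulate a 132-patient cohort and run the classifier for overall survival:

```python
from snpcox import (
    read_cohort_csv, simulate_cohort, write_cohort_csv,
    build_survival_data, run_loocv, compare_cv_groups,
)

cohort = simulate_cohort(seed=1)
write_cohort_csv(cohort, "cohort.csv")

data, design = build_survival_data(cohort, endpoint="survival")
res = run_loocv(data, k_max=6, allow_fold_failures=True)
print(res.k_used, res.retained)
cmp_res = compare_cv_groups(res, data)
print(cmp_res["logrank_p"], cmp_res["wilcoxon_p"])
```

With seed 1 this selects six covariates — `chemo_mmc`, `log_gtv`, `p16_pos`,
`rs11615-2`, `rs13181-2`, `rs17655-2` (all with fold prevalence above 73 %) —
and the cross-validated risk groups separate with log-rank p = 0.00036 and
Wilcoxon p = 0.00030.

The same run from the command line:

```sh
snpcox simulate --out cohort.csv --seed 1
snpcox hwe   --cohort cohort.csv
snpcox ld    --cohort cohort.csv --snp-a rs1799793 --snp-b rs13181
snpcox loocv --cohort cohort.csv --endpoint survival
snpcox analyze --cohort cohort.csv --out report/   # full CSV/JSON bundle
```

For seed 1 the LD check reports r = 0.691 (95 % CI 0.590–0.771, Fisher exact
p ≈ 1e-5) for the simulated ERCC2 pair, with per-SNP Hardy–Weinberg
p-values between 0.049 and 0.999.

## Analysis pipeline

The `analysis/` directory contains thin numbered drivers over the package
that write to `results/`:

```sh
python analysis/01_simulate_cohort.py 1   # results/cohort.csv
python analysis/02_genotype_qc.py         # SNP summary, HWE, LD
python analysis/03_loocv_classifier.py    # LOO-CV classifier, both endpoints
python analysis/04_cox_models.py          # univariate + forward Cox, PH check
```

## Reproduction

`scripts/acceptance.py` recomputes the project's main quantities from scratch
(published-table checks, estimator property rates on synthetic data, and an
end-to-end cohort analysis) and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The run takes about 90 seconds on one CPU. One quantity deserves a caveat:
`loocv_crossvalidated_logrank_rejection_rate_under_null` is well above the
nominal 0.05 — the naive log-rank applied to LOO-CV risk groups is known to
be anti-conservative, and the package reproduces the published procedure
faithfully rather than correcting it. See `docs/methods.md` for the analysis.

## Layout

```
src/snpcox/      the package
tests/           pytest suite (tests/test_acceptance.py holds the criterion tests)
scripts/         acceptance.py
analysis/        numbered pipeline drivers
docs/methods.md  statistical methods, parameter choices, limitations
```
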