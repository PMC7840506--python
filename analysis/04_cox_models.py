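#!/usr/bin/env python
"""Step 4: proportional-hazards models and diagnostics.

Univariate Cox fits of the covariates retained by the LOO-CV selection,
a multivariable model built by forward selection (score-test entry at
p < 0.05), and the Kolmogorov-type supremum check of the proportional-
hazards assumption for the forward model.  Writes results/cox/.
"""

from pathlib import Path

import pandas as pd

from snpcox.cohort import read_cohort_csv
from snpcox.loocv import run_loocv
from snpcox.pipeline import build_survival_data
from snpcox.selection import forward_select
from snpcox.survival import cox_fit, ph_supremum_test

RESULTS = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    cohort = read_cohort_csv(RESULTS / "cohort.csv")
    outdir = RESULTS / "cox"
    outdir.mkdir(parents=True, exist_ok=True)

    for endpoint in ("survival", "ffLRR"):
        data, _ = build_survival_data(cohort, endpoint)
        retained = run_loocv(data, k_max=6, allow_fold_failures=True).retained

        uni_rows = []
        for cov in retained:
            fit = cox_fit(data.subset([cov]))
            lo, hi = fit.hr_ci_95[0]
            uni_rows.append(
                {"covariate": cov, "hr": fit.hr[0], "ci_lo": lo, "ci_hi": hi,
                 "wald_p": fit.wald_p[0]}
            )
        uni = pd.DataFrame(uni_rows)
        uni.to_csv(outdir / f"{endpoint}_univariate.csv", index=False)

        fwd = forward_select(data.subset(retained), entry_p=0.05)
        multi_rows = []
        if fwd.fit is not None:
            for j, name in enumerate(fwd.fit.names):
                lo, hi = fwd.fit.hr_ci_95[j]
                multi_rows.append(
                    {"covariate": name, "hr": fwd.fit.hr[j], "ci_lo": lo,
                     "ci_hi": hi, "wald_p": fwd.fit.wald_p[j]}
                )
        multi = pd.DataFrame(multi_rows)
        multi.to_csv(outdir / f"{endpoint}_forward.csv", index=False)

        print(f"== {endpoint} ==")
        print("univariate (LOO-CV-retained covariates):")
        print(uni.round(4).to_string(index=False))
        print(f"forward selection entered: {fwd.entry_order}")
        if fwd.fit is not None and fwd.fit.converged:
            sup = ph_supremum_test(fwd.fit, data.subset(fwd.fit.names), seed=0)
            ph = pd.DataFrame(
                [{"covariate": r.covariate, "sup": r.sup_observed, "p": r.p_value}
                 for r in sup]
            )
            ph.to_csv(outdir / f"{endpoint}_ph_supremum.csv", index=False)
            print("PH supremum test:")
            print(ph.round(4).to_string(index=False))
        print()
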