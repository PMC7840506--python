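#!/usr/bin/env python
"""Step 2: genotype quality control on the simulated cohort.

Per-SNP genotype counts, minor-allele frequencies and Hardy-Weinberg
tests, plus the linkage-disequilibrium check for the ERCC2 SNP pair.
Reads results/cohort.csv (run 01_simulate_cohort.py first) and writes
results/genotype_qc/.
"""

from pathlib import Path

import pandas as pd

from snpcox.cohort import read_cohort_csv
from snpcox.genotypes import summarize_snp
from snpcox.popgen import genotype_correlation, hwe_test

RESULTS = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    cohort = read_cohort_csv(RESULTS / "cohort.csv")
    outdir = RESULTS / "genotype_qc"
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for snp in cohort.snp_ids:
        s = summarize_snp(cohort, snp)
        h = hwe_test(s)
        rows.append(
            {
                "snp_id": snp,
                "major": s.major_allele,
                "minor": s.minor_allele,
                "n_hom_major": s.n_hom_major,
                "n_het": s.n_het,
                "n_hom_minor": s.n_hom_minor,
                "maf": round(s.maf, 4),
                "hwe_chi2": round(h.chi_square, 4),
                "hwe_p": round(h.p_value, 4),
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "snp_summary.csv", index=False)
    print(frame.to_string(index=False))

    ld = genotype_correlation(cohort, "rs1799793", "rs13181", seed=0, n_mc=100_000)
    pd.DataFrame(
        [
            {
                "snp_a": "rs1799793",
                "snp_b": "rs13181",
                "n": ld.n,
                "r_pearson": round(ld.r_pearson, 4),
                "ci_lo": round(ld.ci_95[0], 4),
                "ci_hi": round(ld.ci_95[1], 4),
                "fisher_p": ld.fisher_p,
            }
        ]
    ).to_csv(outdir / "ld.csv", index=False)
    print(
        f"\nLD rs1799793 x rs13181: r={ld.r_pearson:.3f} "
        f"95% CI ({ld.ci_95[0]:.3f}, {ld.ci_95[1]:.3f}), Fisher p={ld.fisher_p:.2g}"
    )
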