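"""Hardy–Weinberg, genotype correlation (LD) and Fisher's exact test.

Hardy–Weinberg equilibrium is tested with the plain 1-df asymptotic
goodness-of-fit chi-square (no continuity correction): allele frequencies
are estimated from the genotype counts, expected class counts are
``n * (p^2, 2pq, q^2)``.

Linkage disequilibrium between two SNPs is summarised by the Pearson
correlation of the minor-allele dosage scores (0/1/2) over subjects with
complete calls at both loci — numerically identical to computing the
correlation from the 3x3 genotype cross-table — and tested by a
Monte-Carlo Freeman–Halton (Fisher) exact test on that table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from snpcox.cohort import Cohort
from snpcox.genotypes import SNPSummary, summarize_snp

__all__ = ["HweResult", "LdResult", "hwe_test", "genotype_correlation", "fisher_exact_3x3"]


@dataclass(frozen=True)
class HweResult:
    snp_id: str
    observed: tuple[int, int, int]  # hom-major, het, hom-minor
    expected: tuple[float, float, float]
    chi_square: float
    df: int
    p_value: float


@dataclass(frozen=True)
class LdResult:
    snp_pair: tuple[str, str]
    table_3x3: np.ndarray  # rows: snp_a dosage 0/1/2; cols: snp_b dosage 0/1/2
    n: int
    r_pearson: float
    ci_95: tuple[float, float]
    fisher_p: float
    fisher_p_mc_se: float


def hwe_test(summary: SNPSummary) -> HweResult:
    """Goodness-of-fit chi-square test of Hardy–Weinberg proportions.

    One degree of freedom (three genotype classes minus one estimated
    allele frequency minus one).  Undefined for a monomorphic SNP.
    """
    n_maj, n_het, n_min = summary.counts
    n = summary.n_total
    if n == 0:
        raise ValueError(f"{summary.snp_id}: no genotype calls")
    q = summary.maf
    p = 1.0 - q
    if q == 0.0 or p == 0.0:
        raise ValueError(f"{summary.snp_id}: monomorphic, HWE test undefined")
    expected = (n * p * p, n * 2 * p * q, n * q * q)
    observed = (n_maj, n_het, n_min)
    chi_square = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_value = float(stats.chi2.sf(chi_square, df=1))
    return HweResult(
        snp_id=summary.snp_id,
        observed=observed,
        expected=expected,
        chi_square=float(chi_square),
        df=1,
        p_value=p_value,
    )


def _dosages(cohort: Cohort, snp_id: str) -> dict[str, int]:
    """Minor-allele dosage (0/1/2) per patient with a non-missing call."""
    summ = summarize_snp(cohort, snp_id)
    out = {}
    for s in cohort.subjects:
        call = s.genotypes.get(snp_id)
        if call is None:
            continue
        out[s.patient_id] = sum(1 for a in call if a == summ.minor_allele)
    return out


def genotype_correlation(
    cohort: Cohort,
    snp_a: str,
    snp_b: str,
    ci_method: str = "fisher_z",
    n_mc: int = 100_000,
    seed: int | None = None,
    n_boot: int = 2000,
) -> LdResult:
    """Pairwise genotype correlation with a 3x3 exact test.

    Pearson r over minor-allele dosages; 95% CI by Fisher z-transform
    (``ci_method="bootstrap"`` for a subject-resampling percentile CI,
    seeded); Freeman–Halton exact p by Monte Carlo (:func:`fisher_exact_3x3`).
    """
    da = _dosages(cohort, snp_a)
    db = _dosages(cohort, snp_b)
    shared = sorted(set(da) & set(db))
    if len(shared) < 3:
        raise ValueError(f"fewer than 3 complete pairs for {snp_a}/{snp_b}")
    xa = np.array([da[i] for i in shared], dtype=float)
    xb = np.array([db[i] for i in shared], dtype=float)
    if xa.std() == 0 or xb.std() == 0:
        raise ValueError(f"zero genotype variance at {snp_a if xa.std() == 0 else snp_b}")
    n = len(shared)
    r = float(np.corrcoef(xa, xb)[0, 1])

    if ci_method == "fisher_z":
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        se = 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - 1.959964 * se)), float(np.tanh(z + 1.959964 * se)))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        rs = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            a, b = xa[idx], xb[idx]
            if a.std() == 0 or b.std() == 0:
                continue
            rs.append(np.corrcoef(a, b)[0, 1])
        lo, hi = np.percentile(rs, [2.5, 97.5])
        ci = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    table = np.zeros((3, 3), dtype=int)
    for i, j in zip(xa.astype(int), xb.astype(int)):
        table[i, j] += 1
    fisher_p, mc_se = fisher_exact_3x3(table, n_mc=n_mc, seed=seed if seed is not None else 0)
    return LdResult(
        snp_pair=(snp_a, snp_b),
        table_3x3=table,
        n=n,
        r_pearson=r,
        ci_95=ci,
        fisher_p=fisher_p,
        fisher_p_mc_se=mc_se,
    )


def _log_table_prob(table: np.ndarray) -> float:
    """Log conditional probability of an r x c table given its margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_exact_3x3(
    table, n_mc: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo Freeman–Halton exact test for an r x c count table.

    Samples tables from the fixed-margins (multivariate hypergeometric)
    null by random pairing of row and column labels; the p-value is the
    null probability of a table at most as probable as the observed one.
    Returns ``(p_estimate, mc_standard_error)``.  The estimate includes
    the observed table itself (add-one correction), so p > 0 always.
    """
    table = np.asarray(table, dtype=int)
    if (table < 0).any():
        raise ValueError("negative counts")
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        nz_r = rows > 0
        nz_c = cols > 0
        sub = table[np.ix_(nz_r, nz_c)]
        if sub.shape[0] < 2 or sub.shape[1] < 2:
            warnings.warn("degenerate margins: only one table possible, p = 1")
            return 1.0, 0.0
        table = sub
        rows, cols = table.sum(axis=1), table.sum(axis=0)

    n = int(table.sum())
    log_p_obs = _log_table_prob(table)
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(len(rows)), rows)
    col_labels = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    tol = 1e-9
    r_, c_ = len(rows), len(cols)
    for _ in range(n_mc):
        perm = rng.permutation(n)
        flat = np.bincount(row_labels * c_ + col_labels[perm], minlength=r_ * c_)
        t = flat.reshape(r_, c_)
        if _log_table_prob(t) <= log_p_obs + tol:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return float(p), se
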