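"""Hardy–Weinberg testing, genotype correlation and the 3x3 exact test."""

import numpy as np
import pytest
from scipy import stats

from snpcox.genotypes import SNPSummary
from snpcox.popgen import fisher_exact_3x3, genotype_correlation, hwe_test
from tests.test_genotypes import cohort_from_calls
from snpcox.cohort import Cohort
from tests.conftest import make_subject


def summ(n_maj, n_het, n_min, snp="rs"):
    return SNPSummary(snp, "A", "C", n_maj, n_het, n_min)


class TestHwe:
    def test_observed_cohort_counts(self):
        # 49/60/23 genotype distribution: p rounds to 0.53
        res = hwe_test(summ(49, 60, 23))
        assert res.df == 1
        assert round(res.p_value, 2) == 0.53
        assert sum(res.expected) == pytest.approx(132, abs=1e-9)

    def test_exact_hwe_proportions_give_p_one(self):
        res = hwe_test(summ(25, 50, 25))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_no_heterozygotes_hand_computation(self):
        # p=q=0.5, expected (25,50,25) -> chi2 = 25+50+25 = 100
        res = hwe_test(summ(50, 0, 50))
        assert res.chi_square == pytest.approx(100.0)
        assert res.p_value < 1e-20

    def test_monomorphic_is_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_test(summ(100, 0, 0))

    def test_invariant_to_major_minor_swap(self):
        a = hwe_test(summ(48, 65, 19))
        b = hwe_test(summ(19, 65, 48))
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-12)

    def test_null_p_values_approximately_uniform(self):
        """Simulating exact HWE genotypes, the p-value is uniform to chi2 asymptotics."""
        rng = np.random.default_rng(77)
        n, reps, q = 500, 2000, 0.3
        dosages = rng.binomial(2, q, size=(reps, n))
        pvals = []
        for row in dosages:
            counts = np.bincount(row, minlength=3)
            pvals.append(hwe_test(summ(*counts)).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.statistic < 0.05  # asymptotic discreteness allowance


class TestCorrelation:
    def _ld_cohort(self, dos_a, dos_b):
        geno = {0: "AA", 1: "AC", 2: "CC"}
        subs = [
            make_subject(i + 1, {"s1": geno[a], "s2": geno[b]})
            for i, (a, b) in enumerate(zip(dos_a, dos_b))
        ]
        return Cohort(subjects=subs, snp_ids=["s1", "s2"])

    def test_perfect_ld(self):
        dos = [0] * 10 + [1] * 10 + [2] * 10
        res = genotype_correlation(self._ld_cohort(dos, dos), "s1", "s2", n_mc=1000)
        assert res.r_pearson == pytest.approx(1.0)

    def test_independence_table_r_zero(self):
        # counts equal to the outer product of the margins
        dos_a, dos_b = [], []
        for i, ra in enumerate([2, 6, 2]):
            for j, cb in enumerate([2, 6, 2]):
                k = ra * cb // 10
                dos_a += [i] * k
                dos_b += [j] * k
        res = genotype_correlation(self._ld_cohort(dos_a, dos_b), "s1", "s2", n_mc=1000)
        assert abs(res.r_pearson) < 1e-12

    def test_matches_per_subject_oracle_on_fixture_table(self):
        table = np.array([[30, 10, 0], [10, 20, 5], [0, 5, 10]])
        dos_a, dos_b = [], []
        for i in range(3):
            for j in range(3):
                dos_a += [i] * table[i, j]
                dos_b += [j] * table[i, j]
        res = genotype_correlation(self._ld_cohort(dos_a, dos_b), "s1", "s2", n_mc=1000)
        oracle = np.corrcoef(dos_a, dos_b)[0, 1]
        assert res.r_pearson == pytest.approx(oracle, abs=1e-12)
        assert (res.table_3x3 == table).all()

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(8)
        dos_a = rng.integers(0, 3, 50)
        dos_b = np.clip(dos_a + rng.integers(-1, 2, 50), 0, 2)
        c = self._ld_cohort(dos_a, dos_b)
        r1 = genotype_correlation(c, "s1", "s2", n_mc=1000).r_pearson
        r2 = genotype_correlation(c, "s2", "s1", n_mc=1000).r_pearson
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_is_error(self):
        dos_b = [0, 1, 2, 1, 0]
        with pytest.raises(ValueError, match="zero genotype variance"):
            genotype_correlation(self._ld_cohort([1] * 5, dos_b), "s1", "s2", n_mc=1000)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(8)
        dos_a = rng.integers(0, 3, 80)
        dos_b = np.clip(dos_a + rng.integers(-1, 2, 80), 0, 2)
        res = genotype_correlation(
            self._ld_cohort(dos_a, dos_b), "s1", "s2", ci_method="bootstrap",
            seed=4, n_mc=1000,
        )
        lo, hi = res.ci_95
        assert lo < res.r_pearson < hi


class TestFisherExact:
    def test_single_nonzero_cell_p_one(self):
        table = np.zeros((3, 3), dtype=int)
        table[1, 1] = 12
        with pytest.warns(UserWarning, match="degenerate"):
            p, se = fisher_exact_3x3(table, n_mc=1000, seed=0)
        assert p == 1.0 and se == 0.0

    def test_embedded_2x2_matches_hypergeometric_oracle(self):
        table = np.array([[8, 2, 0], [3, 7, 0], [0, 0, 0]])
        p_mc, se = fisher_exact_3x3(table, n_mc=50_000, seed=1)
        p_exact = stats.fisher_exact(table[:2, :2])[1]
        assert abs(p_mc - p_exact) < 3 * max(se, 1e-4)

    def test_matches_full_enumeration_on_small_table(self):
        """MC estimate vs exhaustive Freeman–Halton enumeration at n=12."""
        table = np.array([[3, 1, 0], [1, 2, 1], [0, 1, 3]])
        rows, cols = table.sum(1), table.sum(0)

        # enumerate all 3x3 tables with the observed margins
        from scipy.special import gammaln

        def log_prob(t):
            t = np.asarray(t)
            return float(
                gammaln(rows + 1).sum()
                + gammaln(cols + 1).sum()
                - gammaln(t.sum() + 1)
                - gammaln(t + 1).sum()
            )

        obs_lp = log_prob(table)
        total = 0.0
        hit = 0.0
        for a in range(min(rows[0], cols[0]) + 1):
            for b in range(min(rows[0] - a, cols[1]) + 1):
                c = rows[0] - a - b
                if c > cols[2]:
                    continue
                for d in range(min(rows[1], cols[0] - a) + 1):
                    for e in range(min(rows[1] - d, cols[1] - b) + 1):
                        f = rows[1] - d - e
                        if f > cols[2] - c:
                            continue
                        g, h, i = cols[0] - a - d, cols[1] - b - e, cols[2] - c - f
                        if min(g, h, i) < 0 or g + h + i != rows[2]:
                            continue
                        t = [[a, b, c], [d, e, f], [g, h, i]]
                        lp = log_prob(t)
                        total += np.exp(lp)
                        if lp <= obs_lp + 1e-9:
                            hit += np.exp(lp)
        p_exact = hit / total
        p_mc, se = fisher_exact_3x3(table, n_mc=100_000, seed=3)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert abs(p_mc - p_exact) < 3 * max(se, 1e-4)

    def test_strong_diagonal_table_significant(self):
        table = np.diag([70, 70, 60])
        p, _ = fisher_exact_3x3(table, n_mc=10_000, seed=0)
        assert p < 0.001

    def test_reproducible_given_seed(self):
        table = np.array([[10, 5, 1], [4, 8, 3], [2, 2, 6]])
        assert fisher_exact_3x3(table, 5000, seed=9) == fisher_exact_3x3(table, 5000, seed=9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_exact_3x3([[1, -1, 0], [0, 1, 0], [0, 0, 1]], 1000, 0)
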