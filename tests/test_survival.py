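"""Cox fitting, score tests, KM, two-sample tests, PH supremum diagnostic.

Oracles: a naively-written Breslow partial likelihood maximised by scalar
optimisation; finite differences of that likelihood; hand product-limit
computations; hand-tabulated O-E log-rank tables; and lifelines as an
independent established implementation on random fixtures.
"""

import numpy as np
import pytest
from scipy import optimize, stats

from snpcox.survival import (
    SurvivalData,
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    ph_supremum_test,
    wilcoxon_test,
)
from tests.conftest import random_survival_data


def naive_breslow_loglik(beta, time, event, x):
    """Independent risk-set-by-risk-set Breslow log partial likelihood."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += x[i] @ beta - np.log(np.exp(x[risk] @ beta).sum())
    return ll


class TestCoxFit:
    def test_single_covariate_matches_scalar_maximisation(self):
        time = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        x = np.array([[1.0], [0.0], [1.0], [0.0], [1.0], [0.0]])
        fit = cox_fit(SurvivalData(time, event, x, ["g"]))
        oracle = optimize.minimize_scalar(
            lambda b: -naive_breslow_loglik([b], time, event, x),
            bounds=(-10, 10),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.beta[0] == pytest.approx(oracle.x, abs=1e-6)
        assert fit.converged

    def test_constant_covariate_rejected(self):
        d = SurvivalData([1, 2, 3, 4], [1, 1, 0, 1], np.zeros((4, 1)), ["z"])
        with pytest.raises(ValueError, match="constant columns.*'z'"):
            cox_fit(d)

    def test_no_events_rejected(self):
        d = SurvivalData([1, 2, 3], [0, 0, 0], np.eye(3)[:, :1], ["z"])
        with pytest.raises(ValueError, match="no events"):
            cox_fit(d)

    def test_collinear_columns_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 1))
        d = SurvivalData(
            rng.exponential(1, 30) + 0.01,
            np.ones(30, dtype=int),
            np.hstack([x, 2 * x]),
            ["a", "b"],
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            cox_fit(d)

    def test_separation_flags_nonconvergence(self):
        # the covariate perfectly orders events before censorings
        time = np.arange(1.0, 21.0)
        event = (time <= 10).astype(int)
        x = (time <= 10).astype(float)[:, None]
        fit = cox_fit(SurvivalData(time, event, x, ["sep"]))
        assert not fit.converged

    def test_loglik_increases_from_null(self):
        rng = np.random.default_rng(4)
        d = random_survival_data(rng, n=150, p=3, beta=[0.5, -0.4, 0.0])
        fit = cox_fit(d)
        assert fit.loglik >= fit.loglik_null
        assert (fit.hr_ci_95[:, 0] <= fit.hr).all() and (fit.hr <= fit.hr_ci_95[:, 1]).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_lifelines_on_random_fixtures(self, seed):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(seed)
        d = random_survival_data(rng, n=120, p=3, beta=[0.7, -0.5, 0.2])
        df = pd.DataFrame(d.x, columns=d.names)
        df["T"], df["E"] = d.time, d.event
        cph = CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-11})
        fit = cox_fit(d)
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-6)

    def test_efron_and_breslow_agree_without_ties(self):
        rng = np.random.default_rng(11)
        d = random_survival_data(rng, n=80, p=2, beta=[0.6, -0.3])
        np.testing.assert_allclose(
            cox_fit(d, ties="breslow").beta, cox_fit(d, ties="efron").beta, atol=1e-9
        )

    def test_efron_matches_lifelines_with_ties(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(21)
        d = random_survival_data(rng, n=100, p=2, beta=[0.8, -0.4])
        d = SurvivalData(np.ceil(d.time * 4), d.event, d.x, d.names)  # induce ties
        df = pd.DataFrame(d.x, columns=d.names)
        df["T"], df["E"] = d.time, d.event
        cph = CoxPHFitter().fit(df, "T", "E")  # lifelines uses Efron ties
        fit = cox_fit(d, ties="efron")
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-5)


class TestScoreTest:
    @pytest.mark.parametrize("seed", range(20))
    def test_equals_logrank_for_single_binary_covariate(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = random_survival_data(rng, n=60, p=1, binary=True)
        if d.x.std() == 0 or d.n_events == 0:
            pytest.skip("degenerate draw")
        st_res = cox_score_test(d, ["x0"])
        lr_chi2, lr_p = logrank_test(d.time, d.event, d.x[:, 0])
        assert st_res.score_chi2 == pytest.approx(lr_chi2, abs=1e-9)
        assert st_res.p_value == pytest.approx(lr_p, abs=1e-9)

    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(42)
        d = random_survival_data(rng, n=50, p=3, beta=[0.5, 0.0, -0.5])

        def ll(beta):
            return naive_breslow_loglik(beta, d.time, d.event, d.x)

        eps = 1e-5
        p = 3
        grad = np.array(
            [(ll(eps * np.eye(p)[j]) - ll(-eps * np.eye(p)[j])) / (2 * eps) for j in range(p)]
        )
        hess = np.zeros((p, p))
        for j in range(p):
            for k in range(p):
                ej, ek = np.eye(p)[j] * eps, np.eye(p)[k] * eps
                hess[j, k] = (ll(ej + ek) - ll(ej - ek) - ll(-ej + ek) + ll(-ej - ek)) / (
                    4 * eps * eps
                )
        oracle_chi2 = grad @ np.linalg.solve(-hess, grad)
        res = cox_score_test(d)
        assert res.score_chi2 == pytest.approx(oracle_chi2, rel=1e-4)
        assert res.df == 3

    def test_nested_subsets_nonnegative(self):
        rng = np.random.default_rng(1)
        d = random_survival_data(rng, n=80, p=4, beta=[0.5, 0.3, 0, 0])
        a = cox_score_test(d, ["x0"])
        b = cox_score_test(d, ["x0", "x1"])
        assert a.score_chi2 >= 0 and b.score_chi2 >= 0
        assert (a.df, b.df) == (1, 2)

    def test_null_type_i_error_near_nominal(self):
        rng = np.random.default_rng(314)
        rej = 0
        reps = 1000
        for _ in range(reps):
            d = random_survival_data(rng, n=50, p=1)
            rej += cox_score_test(d, ["x0"]).p_value < 0.05
        # binomial 99% bounds around 0.05 at 1000 reps
        assert 0.032 <= rej / reps <= 0.068


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        c = km_estimate([2, 3, 5], [1, 1, 1])
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(c.n_risk, [3, 2, 1])

    def test_all_censored_flat_at_one(self):
        c = km_estimate([2, 3, 5], [0, 0, 0])
        assert len(c.times) == 0
        assert c.at(10.0) == 1.0

    def test_event_censor_tie_event_first(self):
        # times (1,3,3,5), events (1,1,0,1): censored at 3 is still at risk at 3
        c = km_estimate([1, 3, 3, 5], [1, 1, 0, 1])
        np.testing.assert_allclose(c.survival, [0.75, 0.5, 0.0])
        np.testing.assert_array_equal(c.n_risk, [4, 3, 1])

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1.0, 200)
        c = km_estimate(t, np.ones(200, dtype=int))
        for u in [0.2, 0.7, 1.5]:
            assert c.at(u) == pytest.approx((t > u).mean(), abs=1e-12)

    def test_survival_non_increasing_from_one(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(1.0, 100)
        e = rng.integers(0, 2, 100)
        c = km_estimate(t, e)
        s = np.concatenate([[1.0], c.survival])
        assert (np.diff(s) <= 1e-12).all()
        assert (np.diff(c.n_risk) <= 0).all()


class TestTwoSampleTests:
    def test_identical_groups_give_zero(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert logrank_test(t, e, g)[0] == pytest.approx(0.0, abs=1e-12)
        assert wilcoxon_test(t, e, g)[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_tabulated_logrank_and_wilcoxon(self):
        # groups A:(1,3) B:(2,4), all events; O-E and variances tabulated by hand
        t = np.array([1.0, 3.0, 2.0, 4.0])
        e = np.ones(4, dtype=int)
        g = np.array(["A", "A", "B", "B"])
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx((2 / 3) ** 2 / (0.25 + 2 / 9 + 0.25), abs=1e-12)
        wchi2, _ = wilcoxon_test(t, e, g)
        assert wchi2 == pytest.approx(4.0 / 7.0, abs=1e-12)

    def test_single_event_time_wilcoxon_equals_logrank(self):
        t = np.array([5.0, 5.0, 8.0, 9.0])
        e = np.array([1, 1, 0, 0])
        g = np.array([0, 1, 0, 1])
        assert wilcoxon_test(t, e, g)[0] == pytest.approx(logrank_test(t, e, g)[0])

    def test_early_separation_favors_wilcoxon(self):
        # curves separate early and cross late: pooled-at-risk weighting
        # upweights the early difference
        t0 = np.array([1, 1, 2, 2, 3, 8, 9, 10, 11, 12], dtype=float)
        t1 = np.array([4, 5, 6, 7, 7.5, 8.5, 9.5, 10.5, 11.5, 12.5], dtype=float)
        t = np.concatenate([t0, t1])
        e = np.ones(20, dtype=int)
        g = np.repeat([0, 1], 10)
        assert wilcoxon_test(t, e, g)[0] > logrank_test(t, e, g)[0]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two non-empty groups"):
            logrank_test([1, 2], [1, 1], [0, 0])

    def test_matches_lifelines_logrank(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(9)
        t = rng.exponential(1, 80)
        e = rng.integers(0, 2, 80)
        g = rng.integers(0, 2, 80)
        chi2, p = logrank_test(t, e, g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_null_rejection_near_nominal(self):
        rng = np.random.default_rng(2718)
        rej = 0
        reps = 1000
        for _ in range(reps):
            n = 200
            t = rng.exponential(1, n)
            c = rng.uniform(0.2, 3, n)
            tt = np.minimum(t, c)
            e = (t <= c).astype(int)
            g = rng.integers(0, 2, n)
            rej += logrank_test(tt, e, g)[1] < 0.05
        assert 0.032 <= rej / reps <= 0.068


class TestSupremumTest:
    def _ph_data(self, rng, n=200):
        x = rng.normal(size=(n, 1))
        T = rng.exponential(1.0, n) / np.exp(0.5 * x[:, 0])
        c = rng.uniform(0.2, 3.0, n)
        return SurvivalData(
            np.maximum(np.minimum(T, c), 1e-9), (T <= c).astype(int), x, ["x"]
        )

    def test_observed_sup_deterministic_across_realization_counts(self):
        rng = np.random.default_rng(55)
        d = self._ph_data(rng)
        fit = cox_fit(d)
        a = ph_supremum_test(fit, d, n_realizations=400, seed=3)[0]
        b = ph_supremum_test(fit, d, n_realizations=800, seed=3)[0]
        assert a.sup_observed == pytest.approx(b.sup_observed, abs=1e-12)
        assert abs(a.p_value - b.p_value) < 0.08  # MC error only

    def test_requires_converged_fit(self):
        rng = np.random.default_rng(56)
        d = self._ph_data(rng)
        fit = cox_fit(d)
        fit.converged = False
        with pytest.raises(ValueError, match="converged"):
            ph_supremum_test(fit, d, 500, 0)

    def test_detects_crossing_hazards(self):
        """Hazard ratio reversing at the median time is flagged."""
        rng = np.random.default_rng(57)
        hits = 0
        for i in range(10):
            n = 400
            x = rng.integers(0, 2, n).astype(float)
            T = np.where(
                x == 1,
                np.where(
                    (t0 := rng.exponential(1 / 2.5, n)) <= 0.5,
                    t0,
                    0.5 + rng.exponential(1 / 0.3, n),
                ),
                rng.exponential(1.0, n),
            )
            c = rng.uniform(0.5, 3.0, n)
            d = SurvivalData(
                np.maximum(np.minimum(T, c), 1e-9), (T <= c).astype(int), x[:, None], ["x"]
            )
            fit = cox_fit(d)
            hits += ph_supremum_test(fit, d, 500, seed=i)[0].p_value < 0.05
        assert hits >= 8
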