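"""Survival-analysis primitives written from first principles.

Cox proportional-hazards regression is fitted by Newton–Raphson with
step-halving on the Breslow-tie partial likelihood (Efron tie handling is
available behind a flag).  Score tests at the null are the basis of the
best-subset selection criterion; for a single binary covariate the score
chi-square is identical to the log-rank statistic.

Kaplan–Meier estimation, the log-rank and Gehan–Wilcoxon two-sample
tests, and a Kolmogorov-type supremum test of the proportional-hazards
assumption (standardized cumulative score process with Gaussian
multiplier resampling, as in the SAS PHREG ASSESS diagnostic) complete
the toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalData",
    "CoxFit",
    "ScoreTestResult",
    "KMCurve",
    "SupremumTestResult",
    "cox_fit",
    "cox_score_test",
    "score_stats_at_null",
    "km_estimate",
    "logrank_test",
    "wilcoxon_test",
    "ph_supremum_test",
]

Z975 = 1.959963984540054


@dataclass
class SurvivalData:
    """Right-censored outcomes with a covariate matrix.

    ``time`` strictly positive, ``event`` in {0,1}; ``x`` is an (n, p)
    float matrix with column ``names``.
    """

    time: np.ndarray
    event: np.ndarray
    x: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim == 1:
            self.x = self.x[:, None]
        n = self.time.shape[0]
        if self.event.shape[0] != n or self.x.shape[0] != n:
            raise ValueError("time/event/x length mismatch")
        if (self.time <= 0).any():
            raise ValueError("times must be strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event flags must be 0/1")
        if np.isnan(self.x).any():
            raise ValueError("missing covariate values")
        if len(self.names) != self.x.shape[1]:
            raise ValueError("names length != number of covariate columns")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, columns: list[str]) -> "SurvivalData":
        idx = [self.names.index(c) for c in columns]
        return SurvivalData(self.time, self.event, self.x[:, idx], list(columns))

    def drop_subject(self, i: int) -> "SurvivalData":
        keep = np.ones(self.n, dtype=bool)
        keep[i] = False
        return SurvivalData(self.time[keep], self.event[keep], self.x[keep], list(self.names))


@dataclass
class CoxFit:
    names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    converged: bool
    n_iter: int
    ties: str = "breslow"

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def hr_ci_95(self) -> np.ndarray:
        se = self.se
        return np.column_stack(
            [np.exp(self.beta - Z975 * se), np.exp(self.beta + Z975 * se)]
        )

    @property
    def wald_p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def prognostic_index(self, x: np.ndarray) -> np.ndarray:
        """Linear predictor x'beta (higher = higher hazard)."""
        return np.atleast_2d(np.asarray(x, dtype=float)) @ self.beta


@dataclass(frozen=True)
class ScoreTestResult:
    subset: list[str]
    score_chi2: float
    df: int
    p_value: float


@dataclass
class KMCurve:
    """Product-limit survivor estimate with at-risk/event bookkeeping."""

    times: np.ndarray  # distinct event times, ascending
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def at(self, t: float) -> float:
        """S(t); 1 before the first event time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class SupremumTestResult:
    covariate: str
    sup_observed: float  # sup_t of |standardized cumulative score process|
    p_value: float
    n_realizations: int
    seed: int


# ---------------------------------------------------------------------------
# Breslow/Efron partial likelihood machinery


def _sort_struct(data: SurvivalData):
    order = np.argsort(data.time, kind="stable")
    t = data.time[order]
    e = data.event[order]
    x = data.x[order]
    # first index of each tie group (risk set = everybody with time >= t)
    first = np.zeros(len(t), dtype=int)
    for i in range(1, len(t)):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i
    return t, e, x, first


def _loglik_grad_hess(beta, t, e, x, first, ties="breslow"):
    """Breslow (default) or Efron log partial likelihood with U and I."""
    n, p = x.shape
    eta = x @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    wx = w[:, None] * x
    wxx = wx[:, :, None] * x[:, None, :]
    # reverse cumulative sums: risk-set aggregates at each sorted position
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev = np.flatnonzero(e == 1)
    if ties == "breslow" or len(ev) == 0:
        fp = first[ev]
        s0e, s1e, s2e = s0[fp], s1[fp], s2[fp]
    elif ties == "efron":
        # within each tie group of d events, the k-th event's denominator
        # subtracts k/d of the tied events' own contributions
        s0e = np.empty(len(ev))
        s1e = np.empty((len(ev), p))
        s2e = np.empty((len(ev), p, p))
        pos = 0
        while pos < len(ev):
            g = first[ev[pos]]
            grp = [j for j in range(pos, len(ev)) if first[ev[j]] == g]
            idx = ev[grp[0]: grp[-1] + 1]
            d = len(grp)
            w_t, wx_t, wxx_t = w[idx].sum(), wx[idx].sum(0), wxx[idx].sum(0)
            for k, j in enumerate(grp):
                f = k / d
                s0e[j] = s0[g] - f * w_t
                s1e[j] = s1[g] - f * wx_t
                s2e[j] = s2[g] - f * wxx_t
            pos += d
    else:
        raise ValueError(f"unknown tie handling {ties!r}")

    ll = float((eta[ev] - shift).sum() - np.log(s0e).sum())
    xbar = s1e / s0e[:, None]
    grad = x[ev].sum(axis=0) - xbar.sum(axis=0)
    hess = (s2e / s0e[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", xbar, xbar)
    return ll, grad, hess


def _check_rank(data: SurvivalData) -> None:
    x = data.x
    if x.shape[1] == 0:
        raise ValueError("no covariates")
    xc = x - x.mean(axis=0)
    sv = np.linalg.svd(xc, compute_uv=False)
    tol = max(x.shape) * np.finfo(float).eps * (sv[0] if sv[0] > 0 else 1.0)
    if (sv <= tol).any() or sv[0] == 0:
        # name the offending columns: zero variance first, else report all
        degenerate = [n for n, c in zip(data.names, xc.T) if np.allclose(c, 0)]
        raise ValueError(
            "rank-deficient covariate matrix"
            + (f": constant columns {degenerate}" if degenerate else f": {data.names}")
        )


def cox_fit(
    data: SurvivalData,
    ties: str = "breslow",
    tol: float = 1e-9,
    max_iter: int = 50,
    max_halvings: int = 10,
) -> CoxFit:
    """Maximum partial-likelihood Cox fit via Newton–Raphson.

    Step-halving guarantees a monotone log-likelihood path; convergence
    when the relative log-likelihood change falls below ``tol``.
    Monotone-likelihood (separation) shows up as ``converged=False``.
    """
    if data.n_events == 0:
        raise ValueError("no events: partial likelihood undefined")
    _check_rank(data)
    t, e, x, first = _sort_struct(data)
    p = x.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, t, e, x, first, ties)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix at iteration {it}") from exc
        new_beta = beta + step
        new = _loglik_grad_hess(new_beta, t, e, x, first, ties)
        halvings = 0
        while new[0] < ll and halvings < max_halvings:
            step *= 0.5
            halvings += 1
            new_beta = beta + step
            new = _loglik_grad_hess(new_beta, t, e, x, first, ties)
        if new[0] < ll:  # could not improve
            break
        delta = new[0] - ll
        beta, (ll, grad, hess) = new_beta, new
        if delta < tol * (1.0 + abs(ll)):
            converged = True
            break
    cov = np.linalg.inv(hess)
    cov = 0.5 * (cov + cov.T)
    # monotone likelihood (separation) diagnostic: runaway coefficient or
    # exploding standard error means the maximum is at infinity
    if np.abs(beta).max() > 20 or np.sqrt(np.diag(cov)).max() > 100:
        converged = False
    return CoxFit(
        names=list(data.names),
        beta=beta,
        cov=cov,
        loglik=ll,
        loglik_null=ll_null,
        n=data.n,
        n_events=data.n_events,
        converged=converged,
        n_iter=it,
        ties=ties,
    )


def score_stats_at_null(data: SurvivalData, ties: str = "breslow"):
    """Score vector U(0) and observed information I(0) for all columns."""
    t, e, x, first = _sort_struct(data)
    _, grad, hess = _loglik_grad_hess(np.zeros(x.shape[1]), t, e, x, first, ties)
    return grad, hess


def score_chi2_from_null(grad: np.ndarray, hess: np.ndarray, idx) -> float:
    """Score chi-square U_s' I_ss^{-1} U_s for a column subset."""
    idx = list(idx)
    u = grad[idx]
    i_ss = hess[np.ix_(idx, idx)]
    return float(u @ np.linalg.solve(i_ss, u))


def cox_score_test(
    data: SurvivalData, subset: list[str] | None = None, ties: str = "breslow"
) -> ScoreTestResult:
    """Score test of H0: beta = 0 for a subset of covariates.

    For a single binary covariate this equals the (Breslow-consistent)
    log-rank chi-square for the two groups.
    """
    names = list(data.names) if subset is None else list(subset)
    if not names:
        raise ValueError("empty subset")
    grad, hess = score_stats_at_null(data, ties)
    idx = [data.names.index(nm) for nm in names]
    try:
        chi2 = score_chi2_from_null(grad, hess, idx)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular information sub-matrix for {names}") from exc
    df = len(names)
    return ScoreTestResult(
        subset=names, score_chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df))
    )


# ---------------------------------------------------------------------------
# Kaplan–Meier and two-sample tests


def km_estimate(times, events, group=None):
    """Product-limit survivor estimate, optionally per group.

    A censoring tied with an event time is handled after the event
    (the censored subject is in the risk set at that time).  Returns a
    :class:`KMCurve` (or a dict label -> KMCurve when ``group`` given).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if group is not None:
        group = np.asarray(group)
        return {
            g: km_estimate(times[group == g], events[group == g])
            for g in np.unique(group)
        }
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    n = len(t)
    ev_times = np.unique(t[e == 1])
    n_risk = np.array([(t >= u).sum() for u in ev_times], dtype=int)
    n_event = np.array([((t == u) & (e == 1)).sum() for u in ev_times], dtype=int)
    surv = np.cumprod(1.0 - n_event / n_risk) if len(ev_times) else np.array([])
    return KMCurve(times=ev_times, n_risk=n_risk, n_event=n_event, survival=surv)


def _weighted_two_sample(times, events, group, weights: str):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {labels}")
    g1 = group == labels[1]
    ev_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in ev_times:
        at_risk = times >= u
        n_t = at_risk.sum()
        n1_t = (at_risk & g1).sum()
        d_t = ((times == u) & (events == 1)).sum()
        d1_t = ((times == u) & (events == 1) & g1).sum()
        if n_t <= 1:
            continue
        e1 = d_t * n1_t / n_t
        v = d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
        w = float(n_t) if weights == "gehan" else 1.0
        o_minus_e += w * (d1_t - e1)
        var += w * w * v
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def logrank_test(times, events, group):
    """Two-sample log-rank test (1 df chi-square)."""
    return _weighted_two_sample(times, events, group, weights="logrank")


def wilcoxon_test(times, events, group):
    """Gehan–Breslow generalized Wilcoxon test (pooled at-risk weights).

    Weights each event time by the pooled number at risk, so early
    differences between the curves carry more weight than in the
    log-rank test.
    """
    return _weighted_two_sample(times, events, group, weights="gehan")


# ---------------------------------------------------------------------------
# Kolmogorov-type supremum test of proportional hazards


def ph_supremum_test(
    fit: CoxFit,
    data: SurvivalData,
    n_realizations: int = 1000,
    seed: int = 0,
) -> list[SupremumTestResult]:
    """Supremum test of the PH assumption per covariate.

    The observed statistic is the sup over time of the standardized
    cumulative score process (cumulative Schoenfeld residuals,
    standardized by the fitted information).  Its null distribution is
    approximated by Gaussian-multiplier resampling of the score process
    at the fitted beta; the p-value is the fraction of simulated sups at
    or above the observed one.
    """
    if not fit.converged:
        raise ValueError("supremum test requires a converged fit")
    if n_realizations < 100:
        raise ValueError("n_realizations must be at least 100")
    t, e, x, first = _sort_struct(data)
    p = x.shape[1]
    eta = x @ fit.beta
    w = np.exp(eta - eta.max())
    wx = w[:, None] * x
    wxx = wx[:, :, None] * x[:, None, :]
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    ev = np.flatnonzero(e == 1)
    fp = first[ev]
    xbar = s1[fp] / s0[fp][:, None]
    resid = x[ev] - xbar  # Schoenfeld residuals, events in time order
    # partial information I(t): cumulative over events
    info_incr = s2[fp] / s0[fp][:, None, None] - xbar[:, :, None] * xbar[:, None, :]
    info_cum = np.cumsum(info_incr, axis=0)
    info_total = info_cum[-1]
    info_inv = np.linalg.inv(info_total)
    sd = np.sqrt(np.diag(info_total))

    u_obs = np.cumsum(resid, axis=0) / sd  # standardized observed process
    sup_obs = np.abs(u_obs).max(axis=0)

    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_realizations, len(ev)))
    # W*(t_j) = sum_{e<=j} G_e r_e  -  I(t_j) I^{-1} sum_all G_e r_e
    gr_cum = np.einsum("be,ep->bep", g, resid).cumsum(axis=1)
    gr_tot = gr_cum[:, -1, :]  # (B, p)
    correction = np.einsum("epq,bq->bep", info_cum @ info_inv, gr_tot)
    w_star = (gr_cum - correction) / sd
    sup_star = np.abs(w_star).max(axis=1)  # (B, p)

    results = []
    for k, name in enumerate(data.names[:p]):
        p_val = float((sup_star[:, k] >= sup_obs[k]).mean())
        results.append(
            SupremumTestResult(
                covariate=name,
                sup_observed=float(sup_obs[k]),
                p_value=p_val,
                n_realizations=n_realizations,
                seed=seed,
            )
        )
    return results
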