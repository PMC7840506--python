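"""Best-subset selection by score statistic and forward selection.

The subset-selection engine mirrors the "score" option of SAS PHREG: for
a given subset size k it enumerates every size-k subset of the candidate
covariates and keeps the one with the largest score chi-square evaluated
at beta = 0.  Because the score vector U(0) and the observed information
I(0) for the full candidate set determine every subset's statistic via
submatrices, the enumeration costs one O(n p^2) pass plus a k x k solve
per subset.

Forward selection adds, at each step, the candidate with the smallest
score-test entry p-value conditional on the current model (current
coefficients at their MLE, the new coefficient at 0) and stops when no
candidate enters below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from snpcox.survival import (
    CoxFit,
    SurvivalData,
    _loglik_grad_hess,
    _sort_struct,
    cox_fit,
    score_chi2_from_null,
    score_stats_at_null,
)

__all__ = [
    "SubsetSelectionResult",
    "ForwardSelectionResult",
    "best_subset_by_score",
    "forward_select",
]

ENUMERATION_GUARD = 1_000_000


@dataclass
class SubsetSelectionResult:
    k: int
    best_subset: list[str]
    best_score_chi2: float
    ranked: list[tuple[tuple[str, ...], float]]  # top subsets, descending chi2


@dataclass
class ForwardSelectionResult:
    entry_order: list[str]
    entry_chi2: list[float]
    entry_p: list[float]
    fit: CoxFit | None  # final model; None if nothing entered


def _n_subsets(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def subset_index_array(n_candidates: int, k: int) -> np.ndarray:
    """All size-k index subsets of range(n_candidates), lexicographic order."""
    n_sub = _n_subsets(n_candidates, k)
    if n_sub > ENUMERATION_GUARD:
        raise ValueError(
            f"{n_sub} subsets exceed the enumeration guard ({ENUMERATION_GUARD}); "
            "reduce the candidate list or k"
        )
    return np.array(list(combinations(range(n_candidates), k)), dtype=int)


def batch_subset_scores(grad: np.ndarray, hess: np.ndarray, subsets: np.ndarray) -> np.ndarray:
    """Score chi-square for every subset at once (NaN where singular)."""
    u = grad[subsets]  # (m, k)
    i_ss = hess[subsets[:, :, None], subsets[:, None, :]]  # (m, k, k)
    sign, logdet = np.linalg.slogdet(i_ss)
    ok = (sign > 0) & np.isfinite(logdet)
    chi2 = np.full(len(subsets), np.nan)
    if ok.any():
        sol = np.linalg.solve(i_ss[ok], u[ok][..., None])[..., 0]
        chi2[ok] = np.einsum("mk,mk->m", u[ok], sol)
    chi2[~np.isfinite(chi2)] = np.nan
    chi2[chi2 < 0] = np.nan  # numerically indefinite submatrix: skip
    return chi2


def best_subset_by_score(
    data: SurvivalData,
    candidates: list[str] | None = None,
    k: int = 6,
    ties: str = "breslow",
    top: int = 1,
) -> SubsetSelectionResult:
    """Exhaustive best size-k subset by the score chi-square at the null.

    Ties in the statistic are broken towards the lexicographically
    smaller covariate-name tuple, so the result does not depend on
    candidate ordering.  Subsets with a singular information submatrix
    are skipped.
    """
    candidates = sorted(data.names if candidates is None else candidates)
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidates")
    subsets = subset_index_array(len(candidates), k)
    grad, hess = score_stats_at_null(data.subset(candidates), ties)
    chi2 = batch_subset_scores(grad, hess, subsets)
    if np.isnan(chi2).all():
        raise ValueError("every candidate subset was singular")
    # lexicographic enumeration + first-max argmax = documented tie-break
    best_i = int(np.nanargmax(chi2))
    order = np.argsort(-np.where(np.isnan(chi2), -np.inf, chi2), kind="stable")
    ranked = [
        (tuple(candidates[j] for j in subsets[i]), float(chi2[i]))
        for i in order[: max(top, 1)]
        if not np.isnan(chi2[i])
    ]
    return SubsetSelectionResult(
        k=k,
        best_subset=[candidates[j] for j in subsets[best_i]],
        best_score_chi2=float(chi2[best_i]),
        ranked=ranked,
    )


def _entry_score(data: SurvivalData, current: list[str], candidate: str, ties: str):
    """Score chi-square for adding one covariate to a fitted model.

    Current coefficients at their MLE under H0 (candidate coefficient 0);
    the statistic is U' I^{-1} U of the augmented model, which reduces to
    the efficient score for the candidate because U is zero on the
    current components.
    """
    cols = current + [candidate]
    sub = data.subset(cols)
    if current:
        base = cox_fit(data.subset(current), ties=ties)
        beta0 = np.append(base.beta, 0.0)
    else:
        beta0 = np.zeros(1)
    t, e, x, first = _sort_struct(sub)
    _, grad, hess = _loglik_grad_hess(beta0, t, e, x, first, ties)
    chi2 = float(grad @ np.linalg.solve(hess, grad))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def forward_select(
    data: SurvivalData,
    candidates: list[str] | None = None,
    entry_p: float = 0.05,
    ties: str = "breslow",
) -> ForwardSelectionResult:
    """Forward selection by score-test entry p-value (threshold 0.05)."""
    remaining = sorted(data.names if candidates is None else candidates)
    if not remaining:
        raise ValueError("no candidates")
    entered: list[str] = []
    chi2s: list[float] = []
    ps: list[float] = []
    while remaining:
        best = None
        for cand in remaining:
            try:
                chi2, p = _entry_score(data, entered, cand, ties)
            except (np.linalg.LinAlgError, ValueError):
                continue  # collinear with current model
            if best is None or p < best[2] or (p == best[2] and cand < best[0]):
                best = (cand, chi2, p)
        if best is None or best[2] >= entry_p:
            break
        entered.append(best[0])
        chi2s.append(best[1])
        ps.append(best[2])
        remaining.remove(best[0])
    fit = cox_fit(data.subset(entered), ties=ties) if entered else None
    return ForwardSelectionResult(entry_order=entered, entry_chi2=chi2s, entry_p=ps, fit=fit)
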