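"""Leave-one-out cross-validated median-prognostic-index risk classifier.

For each patient i the model is selected and calibrated on the other
N - 1 patients: the best size-k covariate subset by score chi-square is
found on the training fold, a Cox model on that subset is fitted, and
patient i is classified high-risk when its prognostic index x'beta
exceeds the training fold's median prognostic index (ties go to low
risk; the rule is a strict "higher than the median hazard").

Covariate prevalence is the fraction of the N training folds whose best
subset includes the covariate.  If fewer than k_max covariates are
selected in more than 60% of the folds, the subset size is reduced to
that count and the whole LOO pass re-run once (single reduction, not
iterated, unless requested).

The resulting cross-validated risk classes are compared with Kaplan–Meier
curves and the log-rank and Gehan–Wilcoxon tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from snpcox.selection import batch_subset_scores, subset_index_array
from snpcox.survival import (
    KMCurve,
    SurvivalData,
    cox_fit,
    km_estimate,
    logrank_test,
    score_stats_at_null,
    wilcoxon_test,
)

__all__ = ["LoocvResult", "run_loocv", "apply_reduction_rule", "compare_cv_groups"]


@dataclass
class LoocvResult:
    k_max: int
    k_used: int
    prevalence_threshold: float
    prevalence: dict[str, float]  # final-pass prevalence per candidate
    retained: list[str]  # covariates above the threshold in the final pass
    fold_subsets: list[list[str]]  # per patient: best subset of its training fold
    prognostic_index: np.ndarray  # held-out PI per patient
    training_median: np.ndarray  # per-fold training-median PI
    risk_class: np.ndarray  # "high"/"low" per patient
    reduced: bool  # whether the reduction rule triggered a re-run
    first_pass_prevalence: dict[str, float] | None = None
    fold_failures: list[int] = field(default_factory=list)

    def as_frame(self, ids=None) -> pd.DataFrame:
        idx = ids if ids is not None else np.arange(len(self.risk_class))
        return pd.DataFrame(
            {
                "fold_subset": ["+".join(s) for s in self.fold_subsets],
                "prognostic_index": self.prognostic_index,
                "training_median": self.training_median,
                "risk_class": self.risk_class,
            },
            index=pd.Index(idx, name="patient_id"),
        )


def _loo_pass(
    data: SurvivalData,
    candidates: list[str],
    k: int,
    ties: str,
    allow_fold_failures: bool,
    always_include: list[str] | None = None,
):
    n = data.n
    forced = sorted(always_include or [])
    free = [c for c in candidates if c not in forced]
    if len(forced) > k:
        raise ValueError(f"always_include ({len(forced)}) exceeds subset size k={k}")
    cand_order = forced + free
    cand_data = data.subset(cand_order)
    free_subsets = subset_index_array(len(free), k - len(forced))
    forced_idx = np.arange(len(forced))
    subset_idx = np.hstack(
        [np.tile(forced_idx, (len(free_subsets), 1)), free_subsets + len(forced)]
    ).astype(int)
    candidates = cand_order
    fold_subsets: list[list[str]] = []
    pi = np.full(n, np.nan)
    med = np.full(n, np.nan)
    failures: list[int] = []
    counts: dict[str, int] = {c: 0 for c in candidates}
    for i in range(n):
        train = cand_data.drop_subject(i)
        if train.n_events == 0:
            raise ValueError(f"fold {i}: training data has zero events")
        try:
            grad, hess = score_stats_at_null(train, ties)
            chi2 = batch_subset_scores(grad, hess, subset_idx)
            if np.isnan(chi2).all():
                raise ValueError("every candidate subset singular")
            best = [candidates[j] for j in subset_idx[int(np.nanargmax(chi2))]]
            fit = cox_fit(train.subset(best), ties=ties)
        except (ValueError, np.linalg.LinAlgError) as exc:
            if not allow_fold_failures:
                raise ValueError(f"fold {i} failed: {exc}") from exc
            failures.append(i)
            fold_subsets.append([])
            continue
        if not fit.converged and not allow_fold_failures:
            raise ValueError(f"fold {i}: Cox fit did not converge")
        fold_subsets.append(best)
        for c in best:
            counts[c] += 1
        pi_train = fit.prognostic_index(train.subset(best).x)
        med[i] = float(np.median(pi_train))
        cols = [data.names.index(c) for c in best]
        pi[i] = float(data.x[i, cols] @ fit.beta)
    prevalence = {c: counts[c] / n for c in candidates}
    return fold_subsets, pi, med, prevalence, failures


def apply_reduction_rule(
    prevalence: dict[str, float], k_max: int, threshold: float = 0.60
) -> tuple[int, list[str]]:
    """Covariates selected in *more than* ``threshold`` of training folds.

    Returns ``(k_used, retained)`` where ``k_used`` is the count of
    covariates above the (strict) threshold; if ``k_used < k_max`` the
    LOO pass is to be re-run at the reduced size.
    """
    retained = sorted([c for c, f in prevalence.items() if f > threshold])
    k_used = len(retained)
    if k_used == 0:
        best = max(prevalence.values()) if prevalence else 0.0
        raise ValueError(
            f"no covariate exceeds prevalence {threshold:.0%} (max observed {best:.0%})"
        )
    return min(k_used, k_max), retained


def run_loocv(
    data: SurvivalData,
    candidates: list[str] | None = None,
    k_max: int = 6,
    prevalence_threshold: float = 0.60,
    ties: str = "breslow",
    allow_fold_failures: bool = False,
    iterate_reduction: bool = False,
    always_include: list[str] | None = None,
) -> LoocvResult:
    """Full LOO-CV classifier with the prevalence reduction rule.

    ``always_include`` forces covariates into every fold's subset (their
    prevalence is 1 by construction).  The LOO loop itself is
    deterministic; no seed is involved.
    """
    if data.n < 20:
        raise ValueError("need at least 20 subjects for LOO-CV")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    candidates = sorted(data.names if candidates is None else candidates)
    k = min(k_max, len(candidates))

    subsets, pi, med, prevalence, failures = _loo_pass(
        data, candidates, k, ties, allow_fold_failures, always_include
    )
    first_prev = dict(prevalence)
    k_used, retained = apply_reduction_rule(prevalence, k, prevalence_threshold)
    reduced = False
    while k_used < k:
        reduced = True
        k = k_used
        subsets, pi, med, prevalence, failures = _loo_pass(
            data, candidates, k, ties, allow_fold_failures, always_include
        )
        k_used, retained = apply_reduction_rule(prevalence, k, prevalence_threshold)
        if not iterate_reduction:
            break

    ok = ~np.isnan(pi)
    risk = np.where(ok & (pi > med), "high", "low").astype(object)
    return LoocvResult(
        k_max=k_max,
        k_used=k,
        prevalence_threshold=prevalence_threshold,
        prevalence=prevalence,
        retained=retained,
        fold_subsets=subsets,
        prognostic_index=pi,
        training_median=med,
        risk_class=risk,
        reduced=reduced,
        first_pass_prevalence=first_prev,
        fold_failures=failures,
    )


def compare_cv_groups(result: LoocvResult, data: SurvivalData):
    """KM curves and log-rank / Wilcoxon tests for the CV risk classes."""
    labels = result.risk_class
    if len(set(labels)) < 2:
        raise ValueError("cross-validated classifier produced a single risk class")
    lr_chi2, lr_p = logrank_test(data.time, data.event, labels)
    w_chi2, w_p = wilcoxon_test(data.time, data.event, labels)
    curves: dict[str, KMCurve] = km_estimate(data.time, data.event, group=labels)
    return {
        "logrank_chi2": lr_chi2,
        "logrank_p": lr_p,
        "wilcoxon_chi2": w_chi2,
        "wilcoxon_p": w_p,
        "curves": curves,
    }
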