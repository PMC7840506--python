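"""End-to-end analysis assembly: cohort -> report bundle.

Stages, in the order of the study's results: genotype frequency summary
with Hardy–Weinberg tests, pairwise LD of flagged SNP pairs, the LOO-CV
classifier with cross-validated KM comparison, univariate Cox models of
the retained covariates, forward multivariable selection, and the
supremum proportional-hazards diagnostic on the forward model.

Everything is exported as CSV plus a MANIFEST with SHA-256 checksums so
a rerun on identical inputs is verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from snpcox.cohort import Cohort, encode_clinical
from snpcox.genotypes import code_contrasts, contrast_columns, summarize_snp
from snpcox.loocv import compare_cv_groups, run_loocv
from snpcox.popgen import genotype_correlation, hwe_test
from snpcox.selection import forward_select
from snpcox.survival import SurvivalData, cox_fit, ph_supremum_test

__all__ = ["build_survival_data", "default_candidates", "analyze", "AnalysisError"]

log = logging.getLogger("snpcox")

ENDPOINTS = ("survival", "ffLRR")


class AnalysisError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def default_candidates(cohort: Cohort) -> list[str]:
    """Clinical covariates plus both contrasts of every SNP."""
    cands = ["log_gtv", "chemo_mmc", "p16_pos", "p16_missing"]
    for snp in cohort.snp_ids:
        cands.extend(contrast_columns(snp))
    return cands


def build_survival_data(
    cohort: Cohort,
    endpoint: str = "survival",
    candidates: list[str] | None = None,
    lrr_death_as_event: bool = False,
) -> tuple[SurvivalData, Cohort]:
    """Design matrix + outcomes for one endpoint.

    Subjects with a missing genotype at any analysed SNP are excluded
    (logged with counts).  Candidate columns without variance in the
    remaining subjects (e.g. a monomorphic SNP contrast) are dropped.

    For the relapse endpoint, death without a documented relapse censors
    at the death time by default; ``lrr_death_as_event=True`` counts it
    as an event instead.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint {endpoint!r} not in {ENDPOINTS}")
    candidates = candidates or default_candidates(cohort)
    needed_snps = sorted(
        {c.rsplit("-", 1)[0] for c in candidates if c.rsplit("-", 1)[0] in cohort.snp_ids}
    )
    complete = cohort.complete_for_snps(needed_snps)
    n_dropped = len(cohort) - len(complete)
    if n_dropped:
        log.info("excluded %d subject(s) with missing genotype calls", n_dropped)

    clinical = encode_clinical(complete).frame
    summaries = [summarize_snp(complete, s) for s in needed_snps]
    contrasts = code_contrasts(complete, summaries).astype(float)
    design = pd.concat([clinical, contrasts], axis=1)

    usable, dropped_cols = [], []
    for c in candidates:
        if c not in design.columns:
            raise ValueError(f"unknown candidate covariate {c!r}")
        if design[c].nunique() < 2:
            dropped_cols.append(c)
        else:
            usable.append(c)
    if dropped_cols:
        log.info("dropped constant candidate column(s): %s", dropped_cols)

    if endpoint == "survival":
        time = np.array([s.os_time for s in complete.subjects])
        event = np.array([s.os_event for s in complete.subjects])
    else:
        time = np.array([s.lrr_time for s in complete.subjects])
        if lrr_death_as_event:
            event = np.array(
                [max(s.lrr_event, s.os_event) if s.lrr_time <= s.os_time else s.lrr_event
                 for s in complete.subjects]
            )
        else:
            event = np.array([s.lrr_event for s in complete.subjects])
    data = SurvivalData(time, event, design[usable].to_numpy(), usable)
    return data, complete


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze(
    cohort: Cohort,
    outdir,
    endpoints: tuple[str, ...] = ENDPOINTS,
    candidates: list[str] | None = None,
    k_max: int = 6,
    prevalence_threshold: float = 0.60,
    entry_p: float = 0.05,
    ld_pairs: list[tuple[str, str]] | None = None,
    n_mc_fisher: int = 20_000,
    n_sup_realizations: int = 1000,
    seed: int = 0,
) -> dict:
    """Run the full pipeline and write the report bundle to ``outdir``.

    Stochastic steps (Fisher Monte Carlo, supremum resampling) derive
    their streams from ``seed``; the LOO loop is deterministic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"seed": seed, "n_subjects": len(cohort)}

    def emit(name: str, frame: pd.DataFrame):
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)

    def finish(complete: bool):
        manifest = {
            "complete": complete,
            "outputs": {p.name: _sha256(p) for p in written},
        }
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    # --- genotype frequencies + HWE -------------------------------------
    try:
        rows = []
        summaries = {}
        for snp in cohort.snp_ids:
            summ = summarize_snp(cohort, snp)
            summaries[snp] = summ
            row = {
                "snp": snp,
                "major_allele": summ.major_allele,
                "minor_allele": summ.minor_allele,
                "n_hom_major": summ.n_hom_major,
                "n_het": summ.n_het,
                "n_hom_minor": summ.n_hom_minor,
                "n_total": summ.n_total,
                "maf": round(summ.maf, 4),
            }
            if summ.maf in (0.0,):
                row["hwe_p"] = "untestable_monomorphic"
            else:
                row["hwe_p"] = round(hwe_test(summ).p_value, 4)
            rows.append(row)
        emit("snp_summary.csv", pd.DataFrame(rows))
        emit(
            "hwe.csv",
            pd.DataFrame(
                [{"snp": r["snp"], "hwe_p": r["hwe_p"]} for r in rows]
            ),
        )
    except Exception as exc:
        finish(False)
        raise AnalysisError(f"stage snp_summary/hwe failed: {exc}") from exc

    # --- LD --------------------------------------------------------------
    try:
        if ld_pairs is None:
            ld_pairs = [("rs1799793", "rs13181")] if {
                "rs1799793",
                "rs13181",
            } <= set(cohort.snp_ids) else []
        ld_rows = []
        for i, (a, b) in enumerate(ld_pairs):
            res = genotype_correlation(
                cohort, a, b, n_mc=n_mc_fisher, seed=seed + 1000 + i
            )
            ld_rows.append(
                {
                    "snp_a": a,
                    "snp_b": b,
                    "n": res.n,
                    "r_pearson": round(res.r_pearson, 4),
                    "ci_low": round(res.ci_95[0], 4),
                    "ci_high": round(res.ci_95[1], 4),
                    "fisher_p": res.fisher_p,
                    "fisher_p_mc_se": res.fisher_p_mc_se,
                }
            )
        emit("ld.csv", pd.DataFrame(ld_rows, columns=[
            "snp_a", "snp_b", "n", "r_pearson", "ci_low", "ci_high",
            "fisher_p", "fisher_p_mc_se"]))
        if ld_rows:
            summary["ld"] = ld_rows
    except Exception as exc:
        finish(False)
        raise AnalysisError(f"stage ld failed: {exc}") from exc

    # --- per-endpoint modelling ------------------------------------------
    prev_rows, pat_frames, uni_rows, multi_rows, km_rows, sup_rows = [], [], [], [], [], []
    for endpoint in endpoints:
        try:
            data, complete = build_survival_data(cohort, endpoint, candidates)
            loocv = run_loocv(
                data,
                k_max=k_max,
                prevalence_threshold=prevalence_threshold,
                allow_fold_failures=True,
            )
            cmp_res = compare_cv_groups(loocv, data)
            summary[endpoint] = {
                "n_model": data.n,
                "n_events": data.n_events,
                "k_used": loocv.k_used,
                "retained": loocv.retained,
                "cv_logrank_p": cmp_res["logrank_p"],
                "cv_wilcoxon_p": cmp_res["wilcoxon_p"],
            }
            for cov, prev in sorted(loocv.prevalence.items(), key=lambda t: -t[1]):
                prev_rows.append(
                    {"endpoint": endpoint, "covariate": cov, "prevalence": round(prev, 4)}
                )
            pat = loocv.as_frame(ids=[s.patient_id for s in complete.subjects])
            pat.insert(0, "endpoint", endpoint)
            pat_frames.append(pat.reset_index())
            for label, curve in cmp_res["curves"].items():
                for t, nr, ne, sv in zip(
                    curve.times, curve.n_risk, curve.n_event, curve.survival
                ):
                    km_rows.append(
                        {
                            "endpoint": endpoint,
                            "risk_class": label,
                            "time": t,
                            "n_risk": nr,
                            "n_event": ne,
                            "survival": round(sv, 6),
                        }
                    )

            for cov in loocv.retained:
                fit = cox_fit(data.subset([cov]))
                (lo, hi), = fit.hr_ci_95
                uni_rows.append(
                    {
                        "endpoint": endpoint,
                        "covariate": cov,
                        "hr": round(fit.hr[0], 4),
                        "ci_low": round(lo, 4),
                        "ci_high": round(hi, 4),
                        "p": round(fit.wald_p[0], 5),
                    }
                )

            fwd = forward_select(data, loocv.retained, entry_p=entry_p)
            if fwd.fit is not None:
                for j, cov in enumerate(fwd.fit.names):
                    multi_rows.append(
                        {
                            "endpoint": endpoint,
                            "covariate": cov,
                            "hr": round(fwd.fit.hr[j], 4),
                            "ci_low": round(fwd.fit.hr_ci_95[j, 0], 4),
                            "ci_high": round(fwd.fit.hr_ci_95[j, 1], 4),
                            "wald_p": round(fwd.fit.wald_p[j], 5),
                        }
                    )
                sup = ph_supremum_test(
                    fwd.fit,
                    data.subset(fwd.fit.names),
                    n_realizations=n_sup_realizations,
                    seed=seed + 2000,
                )
                for r in sup:
                    sup_rows.append(
                        {
                            "endpoint": endpoint,
                            "covariate": r.covariate,
                            "sup_observed": round(r.sup_observed, 4),
                            "p": r.p_value,
                        }
                    )
        except AnalysisError:
            raise
        except Exception as exc:
            finish(False)
            raise AnalysisError(f"stage modelling[{endpoint}] failed: {exc}") from exc

    emit("loocv_prevalence.csv", pd.DataFrame(prev_rows))
    emit("loocv_patients.csv", pd.concat(pat_frames, ignore_index=True))
    emit("univariate.csv", pd.DataFrame(uni_rows))
    emit("multivariable.csv", pd.DataFrame(multi_rows))
    emit("km_curves.csv", pd.DataFrame(km_rows))
    emit("ph_supremum.csv", pd.DataFrame(sup_rows))
    finish(True)
    return summary
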