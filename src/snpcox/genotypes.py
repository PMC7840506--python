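"""Allele frequencies and the two genotype contrast dummy variables.

Each biallelic SNP is recoded into two indicator covariates, a
model-free alternative to committing to a dominant/recessive/additive
genetic model:

* ``"<rs>-1"`` — 1 for the homozygote-major genotype (vs heterozygote or
  homozygote minor);
* ``"<rs>-2"`` — 1 for the homozygote-minor genotype (vs the other two).

Major/minor status is determined from the sample allele counts; an exact
tie is broken towards the lexicographically smaller allele so the coding
is reproducible without external annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from snpcox.cohort import Cohort

__all__ = ["SNPSummary", "summarize_snp", "code_contrasts", "contrast_columns"]


@dataclass(frozen=True)
class SNPSummary:
    """Genotype class counts and minor-allele frequency for one SNP."""

    snp_id: str
    major_allele: str
    minor_allele: str
    n_hom_major: int
    n_het: int
    n_hom_minor: int

    @property
    def n_total(self) -> int:
        return self.n_hom_major + self.n_het + self.n_hom_minor

    @property
    def maf(self) -> float:
        return (2 * self.n_hom_minor + self.n_het) / (2 * self.n_total)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_hom_major, self.n_het, self.n_hom_minor)


def summarize_snp(cohort: Cohort, snp_id: str) -> SNPSummary:
    """Tabulate genotype classes and assign major/minor alleles.

    Missing calls are excluded.  Raises if every call is missing or if
    more than two distinct alleles appear.
    """
    calls = [
        s.genotypes[snp_id] for s in cohort.subjects if s.genotypes.get(snp_id) is not None
    ]
    if not calls:
        raise ValueError(f"{snp_id}: all genotype calls missing")
    allele_counts: dict[str, int] = {}
    for call in calls:
        for a in call:
            allele_counts[a] = allele_counts.get(a, 0) + 1
    if len(allele_counts) > 2:
        top2 = {a for a, _ in sorted(allele_counts.items(), key=lambda kv: -kv[1])[:2]}
        bad = next(c for c in calls if not set(c) <= top2)
        raise ValueError(
            f"{snp_id}: more than two alleles observed {sorted(allele_counts)} "
            f"(offending call {bad!r})"
        )
    if len(allele_counts) == 1:
        only = next(iter(allele_counts))
        return SNPSummary(snp_id, only, only, n_hom_major=len(calls), n_het=0, n_hom_minor=0)
    # higher count is major; ties broken towards the lexicographically smaller allele
    (a1, c1), (a2, c2) = sorted(allele_counts.items())
    major, minor = (a1, a2) if c1 >= c2 else (a2, a1)
    hom_major = major + major
    hom_minor = minor + minor
    n_maj = sum(1 for c in calls if c == hom_major)
    n_min = sum(1 for c in calls if c == hom_minor)
    n_het = len(calls) - n_maj - n_min
    return SNPSummary(snp_id, major, minor, n_hom_major=n_maj, n_het=n_het, n_hom_minor=n_min)


def contrast_columns(snp_id: str) -> tuple[str, str]:
    return f"{snp_id}-1", f"{snp_id}-2"


def code_contrasts(cohort: Cohort, summaries: list[SNPSummary]) -> pd.DataFrame:
    """Per-patient contrast dummy matrix for the given SNP summaries.

    Columns ``"<rs>-1"`` (homozygote major) and ``"<rs>-2"`` (homozygote
    minor), indexed by patient id.  Missing calls yield pandas NA in both
    columns; downstream model fitting excludes such subjects.
    """
    by_id = {s.snp_id: s for s in summaries}
    data: dict[str, list] = {}
    for summ in by_id.values():
        c1, c2 = contrast_columns(summ.snp_id)
        col1, col2 = [], []
        hom_major = summ.major_allele * 2
        hom_minor = summ.minor_allele * 2
        het = "".join(sorted(summ.major_allele + summ.minor_allele))
        for subj in cohort.subjects:
            call = subj.genotypes.get(summ.snp_id)
            if call is None:
                col1.append(pd.NA)
                col2.append(pd.NA)
            elif call == hom_major:
                col1.append(1)
                col2.append(0)
            elif call == hom_minor:
                col1.append(0)
                col2.append(1)
            elif call == het:
                col1.append(0)
                col2.append(0)
            else:
                raise ValueError(
                    f"subject {subj.patient_id}: call {call!r} at {summ.snp_id} contains "
                    f"an allele absent from the summary ({summ.major_allele}/{summ.minor_allele})"
                )
        data[c1] = col1
        data[c2] = col2
    frame = pd.DataFrame(data, index=[s.patient_id for s in cohort.subjects], dtype="Int64")
    frame.index.name = "patient_id"
    return frame
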