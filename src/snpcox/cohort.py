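"""Cohort data model, CSV I/O and clinical covariate encoding.

A cohort is one row per patient: two time-to-event endpoints (overall
survival and freedom from loco-regional relapse, both clocked in months
from the start of radiotherapy), clinical covariates, and one genotype
call per SNP stored as a two-letter string such as ``"GA"``.

Missing values (p16 status, genotype calls) are written as ``NA`` in CSV
and held as ``None`` in memory.  Genotype strings are unordered and are
normalised to sorted form on ingest (``"AG" == "GA"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SubjectRecord",
    "Cohort",
    "ClinicalDesign",
    "read_cohort_csv",
    "write_cohort_csv",
    "encode_clinical",
    "CohortValidationError",
    "SchemaError",
]

P16_LEVELS = ("negative", "positive")
CHEMO_LEVELS = ("cisplatin", "mitomycinC")
GENDER_LEVELS = ("female", "male")
N_CATEGORY_LEVELS = ("N0", "N1", "N2", "N3")
TUMOR_SITE_LEVELS = ("oral_cavity", "oropharynx", "hypopharynx")

MISSING_TOKEN = "NA"
_VALID_BASES = frozenset("ACGT")


class CohortValidationError(ValueError):
    """A subject field violates the data model invariants."""


class SchemaError(ValueError):
    """A mandatory column is absent from the input file."""


def _normalize_genotype(call: str | None) -> str | None:
    if call is None:
        return None
    call = call.strip()
    if call == "" or call == MISSING_TOKEN:
        return None
    if len(call) != 2 or not set(call) <= _VALID_BASES:
        raise CohortValidationError(
            f"genotype call {call!r} is not a two-letter string over A/C/G/T"
        )
    return "".join(sorted(call))


@dataclass
class SubjectRecord:
    """One patient: endpoints, clinical covariates and genotype calls."""

    patient_id: str
    os_time: float
    os_event: int
    lrr_time: float
    lrr_event: int
    gtv_total: float
    p16: str | None  # "negative" / "positive" / None (missing)
    chemo_type: str
    age: float | None = None
    gender: str | None = None
    n_category: str | None = None
    tumor_site: str | None = None
    genotypes: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortValidationError("patient_id must be non-empty")
        for name in ("os_time", "lrr_time"):
            t = getattr(self, name)
            if not (t > 0) or not math.isfinite(t):
                raise CohortValidationError(
                    f"subject {self.patient_id}: {name}={t!r} must be strictly positive"
                )
        for name in ("os_event", "lrr_event"):
            e = getattr(self, name)
            if e not in (0, 1):
                raise CohortValidationError(
                    f"subject {self.patient_id}: {name}={e!r} must be 0 or 1"
                )
        if not (self.gtv_total > 0) or not math.isfinite(self.gtv_total):
            raise CohortValidationError(
                f"subject {self.patient_id}: gtv_total={self.gtv_total!r} must be > 0"
            )
        if self.p16 is not None and self.p16 not in P16_LEVELS:
            raise CohortValidationError(
                f"subject {self.patient_id}: p16={self.p16!r} not in {P16_LEVELS} or missing"
            )
        if self.chemo_type not in CHEMO_LEVELS:
            raise CohortValidationError(
                f"subject {self.patient_id}: chemo_type={self.chemo_type!r} not in {CHEMO_LEVELS}"
            )
        if self.gender is not None and self.gender not in GENDER_LEVELS:
            raise CohortValidationError(
                f"subject {self.patient_id}: gender={self.gender!r} not in {GENDER_LEVELS}"
            )
        if self.n_category is not None and self.n_category not in N_CATEGORY_LEVELS:
            raise CohortValidationError(
                f"subject {self.patient_id}: n_category={self.n_category!r} "
                f"not in {N_CATEGORY_LEVELS}"
            )
        if self.tumor_site is not None and self.tumor_site not in TUMOR_SITE_LEVELS:
            raise CohortValidationError(
                f"subject {self.patient_id}: tumor_site={self.tumor_site!r} "
                f"not in {TUMOR_SITE_LEVELS}"
            )
        self.genotypes = {
            snp: _normalize_genotype(call) for snp, call in self.genotypes.items()
        }


@dataclass
class Cohort:
    """Ordered list of subjects sharing a common SNP key set."""

    subjects: list[SubjectRecord]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        ids = [s.patient_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_ids: {dupes}")
        keyset = set(self.snp_ids)
        for s in self.subjects:
            if set(s.genotypes) != keyset:
                raise CohortValidationError(
                    f"subject {s.patient_id} genotype keys {sorted(s.genotypes)} "
                    f"!= cohort snp_ids {sorted(keyset)}"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    def drop_subjects(self, patient_ids: set[str]) -> "Cohort":
        keep = [s for s in self.subjects if s.patient_id not in patient_ids]
        return Cohort(subjects=keep, snp_ids=list(self.snp_ids))

    def complete_for_snps(self, snp_ids: list[str] | None = None) -> "Cohort":
        """Subjects with a non-missing call at every requested SNP.

        Mirrors the study design of excluding the few genotyping call
        failures from model fitting.
        """
        want = self.snp_ids if snp_ids is None else snp_ids
        keep = [
            s for s in self.subjects if all(s.genotypes.get(k) is not None for k in want)
        ]
        return Cohort(subjects=keep, snp_ids=list(self.snp_ids))


@dataclass
class ClinicalDesign:
    """Per-patient clinical covariate columns ready for Cox modelling.

    Always contains ``log(GTV)`` (natural log of the combined gross tumor
    volume), the p16 positivity indicator, the p16-missingness dummy, and
    the mitomycin-C (vs cisplatin) chemotherapy indicator; further coded
    indicators (age, gender, N category, tumor site) on request.
    """

    frame: pd.DataFrame  # indexed by patient_id

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


DEFAULT_SCHEMA = {
    "id": "patient_id",
    "os_time": "os_time",
    "os_event": "os_event",
    "lrr_time": "lrr_time",
    "lrr_event": "lrr_event",
    "gtv": "gtv_total",
    "p16": "p16",
    "chemo": "chemo_type",
    "age": "age",
    "gender": "gender",
    "n_category": "n_category",
    "tumor_site": "tumor_site",
}

GENOTYPE_PREFIX = "snp_"

_MANDATORY = ("id", "os_time", "os_event", "lrr_time", "lrr_event", "gtv", "p16", "chemo")


def read_cohort_csv(
    path,
    schema: dict[str, str] | None = None,
    genotype_columns: list[str] | None = None,
) -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path : str or Path
        Comma-separated UTF-8 file with a header row; ``NA`` (or an empty
        cell) marks a missing value.
    schema : dict, optional
        Mapping from logical field names (``id``, ``os_time`` ...) to
        column names; defaults to :data:`DEFAULT_SCHEMA`.
    genotype_columns : list of str, optional
        Explicit genotype column names.  By default every column starting
        with ``snp_`` is a genotype column and the SNP id is the suffix.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [schema[k] for k in _MANDATORY if schema[k] not in df.columns]
    if missing_cols:
        raise SchemaError(f"mandatory columns absent from {path}: {missing_cols}")

    if genotype_columns is None:
        genotype_columns = [c for c in df.columns if c.startswith(GENOTYPE_PREFIX)]
        snp_ids = [c[len(GENOTYPE_PREFIX):] for c in genotype_columns]
    else:
        for c in genotype_columns:
            if c not in df.columns:
                raise SchemaError(f"genotype column {c!r} absent from {path}")
        snp_ids = [
            c[len(GENOTYPE_PREFIX):] if c.startswith(GENOTYPE_PREFIX) else c
            for c in genotype_columns
        ]

    def cell(row, key, optional=False):
        col = schema.get(key)
        if col is None or col not in df.columns:
            return None
        v = row[col].strip()
        if v == "" or v == MISSING_TOKEN:
            if optional:
                return None
            raise CohortValidationError(f"row {row.name}: column {col!r} is empty")
        return v

    subjects = []
    for _, row in df.iterrows():
        try:
            subjects.append(
                SubjectRecord(
                    patient_id=cell(row, "id"),
                    os_time=float(cell(row, "os_time")),
                    os_event=int(cell(row, "os_event")),
                    lrr_time=float(cell(row, "lrr_time")),
                    lrr_event=int(cell(row, "lrr_event")),
                    gtv_total=float(cell(row, "gtv")),
                    p16=cell(row, "p16", optional=True),
                    chemo_type=cell(row, "chemo"),
                    age=(lambda v: float(v) if v is not None else None)(
                        cell(row, "age", optional=True)
                    ),
                    gender=cell(row, "gender", optional=True),
                    n_category=cell(row, "n_category", optional=True),
                    tumor_site=cell(row, "tumor_site", optional=True),
                    genotypes={
                        snp: (row[col].strip() or None)
                        for snp, col in zip(snp_ids, genotype_columns)
                    },
                )
            )
        except (ValueError, TypeError) as exc:
            if isinstance(exc, CohortValidationError):
                raise CohortValidationError(f"row {row.name}: {exc}") from None
            raise CohortValidationError(f"row {row.name}: {exc}") from None
    return Cohort(subjects=subjects, snp_ids=snp_ids)


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort as CSV; inverse of :func:`read_cohort_csv`."""
    rows = []
    for s in cohort.subjects:
        row = {
            "patient_id": s.patient_id,
            "os_time": s.os_time,
            "os_event": s.os_event,
            "lrr_time": s.lrr_time,
            "lrr_event": s.lrr_event,
            "gtv_total": s.gtv_total,
            "p16": s.p16 if s.p16 is not None else MISSING_TOKEN,
            "chemo_type": s.chemo_type,
            "age": s.age if s.age is not None else MISSING_TOKEN,
            "gender": s.gender if s.gender is not None else MISSING_TOKEN,
            "n_category": s.n_category if s.n_category is not None else MISSING_TOKEN,
            "tumor_site": s.tumor_site if s.tumor_site is not None else MISSING_TOKEN,
        }
        for snp in cohort.snp_ids:
            call = s.genotypes.get(snp)
            row[GENOTYPE_PREFIX + snp] = call if call is not None else MISSING_TOKEN
        rows.append(row)
    columns = list(DEFAULT_SCHEMA.values()) + [GENOTYPE_PREFIX + s for s in cohort.snp_ids]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def encode_clinical(
    cohort: Cohort,
    extras: tuple[str, ...] = (),
) -> ClinicalDesign:
    """Build the clinical part of the design matrix.

    Standard columns (matching the study's covariate list):

    * ``log_gtv`` — natural log of GTV_total (cm³);
    * ``p16_pos`` — 1 if p16 positive (vs negative reference);
    * ``p16_missing`` — 1 if p16 status not determined, so that the
      average prognostic p16 effect of the undetermined patients is
      absorbed by a dummy rather than dropping them;
    * ``chemo_mmc`` — 1 for mitomycin-C based concurrent chemotherapy
      (cisplatin-based is the reference).

    ``extras`` may list ``"age"``, ``"gender"``, ``"n_category"``,
    ``"tumor_site"`` for additional coded columns (first level is the
    reference for categorical extras).
    """
    rows = {}
    for s in cohort.subjects:
        row = {
            "log_gtv": math.log(s.gtv_total),
            "p16_pos": 1 if s.p16 == "positive" else 0,
            "p16_missing": 1 if s.p16 is None else 0,
            "chemo_mmc": 1 if s.chemo_type == "mitomycinC" else 0,
        }
        for extra in extras:
            if extra == "age":
                if s.age is None:
                    raise CohortValidationError(f"subject {s.patient_id}: age missing")
                row["age"] = s.age
            elif extra == "gender":
                row["gender_male"] = 1 if s.gender == "male" else 0
            elif extra == "n_category":
                for lev in N_CATEGORY_LEVELS[1:]:
                    row[f"ncat_{lev}"] = 1 if s.n_category == lev else 0
            elif extra == "tumor_site":
                for lev in TUMOR_SITE_LEVELS[1:]:
                    row[f"site_{lev}"] = 1 if s.tumor_site == lev else 0
            else:
                raise ValueError(f"unknown clinical extra {extra!r}")
        rows[s.patient_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "patient_id"
    return ClinicalDesign(frame=frame)
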