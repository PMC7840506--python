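"""Synthetic cohort generator.

Generates cohorts with the statistical structure the analysis assumes:
biallelic SNP genotypes in Hardy–Weinberg equilibrium with optional
pairwise linkage disequilibrium (haplotype frequencies solved by moment
matching to the two minor-allele frequencies and the target genotype
correlation), clinical covariates matching the study's marginal
distributions (log-normal tumor volume, p16 status with missingness,
chemotherapy mix), and Weibull event times for both endpoints with
covariate effects on the log-hazard scale and uniform-accrual censoring.

The default configuration emulates a 132-patient definitive
radiochemotherapy cohort: eight DNA-repair SNPs at the observed genotype
frequencies, strong LD (r ~ 0.68) between the two ERCC2 coding SNPs, and
censoring calibrated to roughly 65 deaths and 53 loco-regional relapses
in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from snpcox.cohort import Cohort, SubjectRecord, encode_clinical
from snpcox.genotypes import code_contrasts, summarize_snp

__all__ = [
    "SimulationConfig",
    "SNPSpec",
    "simulate_genotypes",
    "simulate_survival",
    "simulate_cohort",
    "default_config",
]


@dataclass(frozen=True)
class SNPSpec:
    """Major/minor alleles and minor-allele frequency for one simulated SNP."""

    snp_id: str
    major_allele: str
    minor_allele: str
    maf: float

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf={self.maf} must be in (0, 0.5]")


def _default_snps() -> list[SNPSpec]:
    # genotype frequencies of the eight DNA-repair SNPs in the 132-patient cohort
    return [
        SNPSpec("rs1799793", "G", "A", 103 / 264),
        SNPSpec("rs13181", "A", "C", 106 / 264),
        SNPSpec("rs50871", "A", "C", 111 / 264),
        SNPSpec("rs2267437", "C", "G", 121 / 264),
        SNPSpec("rs11615", "T", "C", 82 / 264),
        SNPSpec("rs4988023", "A", "C", 39 / 264),
        SNPSpec("rs17655", "G", "C", 57 / 264),
        SNPSpec("rs25487", "G", "A", 94 / 264),
    ]


def _default_os_effects() -> dict[str, float]:
    # univariate hazard ratios for overall survival, as marginal targets
    return {
        "log_gtv": math.log(2.092),
        "rs1799793-1": math.log(0.418),
        "rs13181-2": math.log(2.074),
        "p16_pos": math.log(0.369),
        "chemo_mmc": math.log(0.497),
        "p16_missing": math.log(0.381),
    }


def _default_lrr_effects() -> dict[str, float]:
    # univariate hazard ratios for freedom from loco-regional relapse
    return {
        "log_gtv": math.log(1.914),
        "rs1799793-1": math.log(0.435),
        "rs13181-2": math.log(1.974),
        "rs17655-1": math.log(0.630),
        "rs17655-2": math.log(0.365),
        "rs1799793-2": math.log(1.247),
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study cohort."""

    n_subjects: int = 132
    snps: list[SNPSpec] = field(default_factory=_default_snps)
    # (snp_a, snp_b, target genotype correlation); pairs must be disjoint
    ld_pairs: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("rs1799793", "rs13181", 0.68)]
    )
    # clinical margins
    gtv_median: float = 37.3
    gtv_log_sd: float = 0.72
    gtv_range: tuple[float, float] = (5.6, 221.8)
    p16_pos_rate: float = 18 / 132
    p16_missing_rate: float = 8 / 132
    chemo_mmc_rate: float = 24 / 132
    age_mean: float = 58.1
    age_sd: float = 8.6
    age_range: tuple[float, float] = (39.2, 81.9)
    female_rate: float = 23 / 132
    n_category_probs: tuple[float, ...] = (24 / 132, 7 / 132, 95 / 132, 6 / 132)
    tumor_site_probs: tuple[float, ...] = (24 / 132, 66 / 132, 42 / 132)
    # survival model (times in months from start of radiotherapy)
    os_log_hr: dict[str, float] = field(default_factory=_default_os_effects)
    lrr_log_hr: dict[str, float] = field(default_factory=_default_lrr_effects)
    weibull_shape: float = 1.2
    # baseline scales calibrated so the default cohort yields ~65 deaths
    # and ~53 loco-regional relapses in expectation (see docs/methods.md)
    os_weibull_scale: float = 102.0
    lrr_weibull_scale: float = 132.0
    censor_window: tuple[float, float] = (36.0, 108.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for r in (
            self.p16_pos_rate,
            self.p16_missing_rate,
            self.chemo_mmc_rate,
            self.female_rate,
        ):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.p16_pos_rate + self.p16_missing_rate > 1.0:
            raise ValueError("p16 positive + missing rates exceed 1")
        if self.weibull_shape <= 0 or self.os_weibull_scale <= 0 or self.lrr_weibull_scale <= 0:
            raise ValueError("Weibull parameters must be positive")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        paired = [s for a, b, _ in self.ld_pairs for s in (a, b)]
        if len(set(paired)) != len(paired):
            raise ValueError("LD pairs must be disjoint (each SNP in at most one pair)")
        for a, b, r in self.ld_pairs:
            if a not in ids or b not in ids:
                raise ValueError(f"LD pair ({a}, {b}) references an unknown SNP")
            _solve_haplotypes(self._spec(a).maf, self._spec(b).maf, r)  # feasibility

    def _spec(self, snp_id: str) -> SNPSpec:
        return next(s for s in self.snps if s.snp_id == snp_id)


def default_config(**overrides) -> SimulationConfig:
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def _solve_haplotypes(p1: float, p2: float, r: float) -> np.ndarray:
    """Two-locus haplotype frequencies matching (maf1, maf2, genotype r).

    Under random union of haplotypes the genotype (dosage) correlation
    equals the allelic correlation D / sqrt(p1 q1 p2 q2), so moment
    matching reduces to choosing the disequilibrium coefficient D.
    Order: (minor,minor), (minor,major), (major,minor), (major,major).
    """
    q1, q2 = 1 - p1, 1 - p2
    denom = math.sqrt(p1 * q1 * p2 * q2)
    d = r * denom
    d_max = min(p1 * q2, q1 * p2)
    d_min = -min(p1 * p2, q1 * q2)
    if not (d_min - 1e-12 <= d <= d_max + 1e-12):
        r_lo, r_hi = d_min / denom, d_max / denom
        raise ValueError(
            f"target r={r} infeasible for MAFs ({p1:.3f}, {p2:.3f}); "
            f"attainable range [{r_lo:.3f}, {r_hi:.3f}]"
        )
    h = np.array([p1 * p2 + d, p1 * q2 - d, q1 * p2 - d, q1 * q2 + d])
    return np.clip(h, 0.0, None) / np.clip(h, 0.0, None).sum()


def _call(spec: SNPSpec, dosage: int) -> str:
    alleles = [spec.major_allele] * (2 - dosage) + [spec.minor_allele] * dosage
    return "".join(sorted(alleles))


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-subject genotype call strings (n_subjects x n_snps).

    SNPs in an LD pair receive two haplotypes drawn jointly from the
    moment-matched haplotype distribution; all other SNPs draw two
    alleles independently (Hardy–Weinberg by construction).
    """
    n = config.n_subjects
    calls: dict[str, list[str]] = {}
    paired = set()
    for a, b, r in config.ld_pairs:
        sa, sb = config._spec(a), config._spec(b)
        h = _solve_haplotypes(sa.maf, sb.maf, r)
        # haplotype index: bit 0 = minor at b, bit 1 = minor at a
        hap_minor_a = np.array([1, 1, 0, 0])
        hap_minor_b = np.array([1, 0, 1, 0])
        h1 = rng.choice(4, size=n, p=h)
        h2 = rng.choice(4, size=n, p=h)
        dos_a = hap_minor_a[h1] + hap_minor_a[h2]
        dos_b = hap_minor_b[h1] + hap_minor_b[h2]
        calls[a] = [_call(sa, d) for d in dos_a]
        calls[b] = [_call(sb, d) for d in dos_b]
        paired.update((a, b))
    for spec in config.snps:
        if spec.snp_id in paired:
            continue
        dos = rng.binomial(2, spec.maf, size=n)
        calls[spec.snp_id] = [_call(spec, d) for d in dos]
    frame = pd.DataFrame({s.snp_id: calls[s.snp_id] for s in config.snps})
    return frame


def simulate_survival(
    config: SimulationConfig,
    design: pd.DataFrame,
    log_hr: dict[str, float],
    scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Weibull event times under a log-linear covariate effect, censored.

    ``design`` must contain every column named in ``log_hr``.  The linear
    predictor is centred at the configured population means so the
    baseline scale controls the marginal event rate.  Censoring is the
    administrative horizon of a uniform accrual window.
    """
    missing = [c for c in log_hr if c not in design.columns]
    if missing:
        raise ValueError(f"design lacks effect columns {missing}")
    eta = np.zeros(len(design))
    means = _effect_means(config)
    for name, beta in log_hr.items():
        col = design[name].to_numpy(dtype=float)
        eta += beta * (col - means.get(name, col.mean()))
    u = rng.exponential(size=len(design))
    t_event = scale * (u / np.exp(eta)) ** (1.0 / config.weibull_shape)
    lo, hi = config.censor_window
    c = rng.uniform(lo, hi, size=len(design))
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    time = np.maximum(time, 1e-6)
    return time, event


def _effect_means(config: SimulationConfig) -> dict[str, float]:
    """Theoretical means of the standard effect covariates."""
    means = {
        "log_gtv": math.log(config.gtv_median),
        "p16_pos": config.p16_pos_rate,
        "p16_missing": config.p16_missing_rate,
        "chemo_mmc": config.chemo_mmc_rate,
    }
    for s in config.snps:
        means[f"{s.snp_id}-1"] = (1 - s.maf) ** 2
        means[f"{s.snp_id}-2"] = s.maf**2
    return means


def simulate_cohort(config: SimulationConfig | None = None, seed: int | None = None) -> Cohort:
    """Full synthetic cohort: genotypes, clinical covariates, both endpoints.

    Deterministic given (config, seed); ``seed`` overrides ``config.seed``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects

    genotype_frame = simulate_genotypes(config, rng)

    lo, hi = config.gtv_range
    gtv = np.exp(rng.normal(math.log(config.gtv_median), config.gtv_log_sd, size=n))
    gtv = np.clip(gtv, lo, hi)
    u = rng.uniform(size=n)
    p16 = np.where(
        u < config.p16_pos_rate,
        "positive",
        np.where(u < config.p16_pos_rate + config.p16_missing_rate, None, "negative"),
    )
    chemo = np.where(rng.uniform(size=n) < config.chemo_mmc_rate, "mitomycinC", "cisplatin")
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), *config.age_range)
    gender = np.where(rng.uniform(size=n) < config.female_rate, "female", "male")
    ncat = rng.choice(["N0", "N1", "N2", "N3"], size=n, p=config.n_category_probs)
    site = rng.choice(
        ["oral_cavity", "oropharynx", "hypopharynx"], size=n, p=config.tumor_site_probs
    )

    # provisional cohort (placeholder times) to reuse the coding machinery
    subjects = [
        SubjectRecord(
            patient_id=f"P{i + 1:04d}",
            os_time=1.0,
            os_event=0,
            lrr_time=1.0,
            lrr_event=0,
            gtv_total=float(gtv[i]),
            p16=p16[i],
            chemo_type=str(chemo[i]),
            age=float(age[i]),
            gender=str(gender[i]),
            n_category=str(ncat[i]),
            tumor_site=str(site[i]),
            genotypes={s.snp_id: genotype_frame.iloc[i][s.snp_id] for s in config.snps},
        )
        for i in range(n)
    ]
    cohort = Cohort(subjects=subjects, snp_ids=[s.snp_id for s in config.snps])
    clinical = encode_clinical(cohort).frame
    summaries = [summarize_snp(cohort, s.snp_id) for s in config.snps]
    contrasts = code_contrasts(cohort, summaries).astype(float)
    design = pd.concat([clinical, contrasts], axis=1)

    os_time, os_event = simulate_survival(
        config, design, config.os_log_hr, config.os_weibull_scale, rng
    )
    lrr_time, lrr_event = simulate_survival(
        config, design, config.lrr_log_hr, config.lrr_weibull_scale, rng
    )
    for i, s in enumerate(subjects):
        s.os_time = float(os_time[i])
        s.os_event = int(os_event[i])
        s.lrr_time = float(lrr_time[i])
        s.lrr_event = int(lrr_event[i])
    return cohort
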