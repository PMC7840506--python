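"""Shared fixtures: small hand-built cohorts and simulated survival data."""

from __future__ import annotations

import numpy as np
import pytest

from snpcox.cohort import Cohort, SubjectRecord
from snpcox.simulate import simulate_cohort
from snpcox.survival import SurvivalData


def make_subject(i, genotypes, **overrides):
    base = dict(
        patient_id=f"P{i:03d}",
        os_time=12.0 + i,
        os_event=i % 2,
        lrr_time=10.0 + i,
        lrr_event=(i + 1) % 2,
        gtv_total=30.0 + i,
        p16="negative",
        chemo_type="cisplatin",
        age=60.0,
        gender="male",
        n_category="N2",
        tumor_site="oropharynx",
        genotypes=genotypes,
    )
    base.update(overrides)
    return SubjectRecord(**base)


@pytest.fixture
def tiny_cohort():
    """Three subjects, two SNPs, one missing call."""
    subs = [
        make_subject(1, {"rs1": "GG", "rs2": "AA"}),
        make_subject(2, {"rs1": "GA", "rs2": "AC"}, p16="positive"),
        make_subject(3, {"rs1": "AA", "rs2": None}, p16=None),
    ]
    return Cohort(subjects=subs, snp_ids=["rs1", "rs2"])


@pytest.fixture(scope="session")
def default_cohort():
    """Default 132-subject synthetic cohort (seeded)."""
    return simulate_cohort(seed=2024)


def random_survival_data(rng, n=100, p=3, beta=None, binary=False, censor=(0.2, 3.0)):
    """Exponential event times with optional covariate effects."""
    if binary:
        x = (rng.uniform(size=(n, p)) < 0.4).astype(float)
    else:
        x = rng.normal(size=(n, p))
    beta = np.zeros(p) if beta is None else np.asarray(beta, dtype=float)
    eta = x @ beta
    t_event = rng.exponential(1.0, n) / np.exp(eta - eta.mean())
    c = rng.uniform(*censor, size=n)
    time = np.maximum(np.minimum(t_event, c), 1e-9)
    event = (t_event <= c).astype(int)
    return SurvivalData(time, event, x, [f"x{j}" for j in range(p)])
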