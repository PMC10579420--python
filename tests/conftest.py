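"""Shared fixtures.

The expensive fixture is ``trained_cohort``: a small cohort of synthetic
subjects with two trained replicates each, shared session-wide by the
lesion, evaluation and acceptance tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from soasim.behavior import (
    SubjectProfile,
    generate_behavioral_dataset,
    generate_cohort,
)
from soasim.encoding import build_test_set
from soasim.training import TrainingConfig, make_m_subjects, reproduction_check

#: Training settings used throughout the suite; smaller test sets keep
#: the run affordable while leaving every statistic well-estimated.
N_SUBJECTS = 5
N_REPLICATES = 2
N_TEST_PER_CONDITION = 50
COHORT_SEED = 2024


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(n_subjects=N_SUBJECTS, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def training_config():
    return TrainingConfig(seed=COHORT_SEED)


@pytest.fixture()
def profile() -> SubjectProfile:
    return SubjectProfile(
        subject_id="P",
        inflection_ms=500.0,
        slope=0.015,
        upper_asymptote=0.95,
        lower_asymptote=0.05,
        epa_yes_prob=(0.2, 0.2, 0.2),
        rt_mean_ms=350.0,
        rt_sd_ms=50.0,
    )


@pytest.fixture()
def dataset(profile):
    return generate_behavioral_dataset(profile, seed=7)


@pytest.fixture(scope="session")
def trained_cohort(cohort, training_config):
    """(m_subjects, test_sets) for the session's small trained cohort."""
    m_subjects = []
    test_sets = {}
    for si, ds in enumerate(cohort):
        reps = make_m_subjects(ds, n_replicates=N_REPLICATES, cfg=training_config)
        for m in reps:
            test = build_test_set(
                ds.profile,
                n_per_condition=N_TEST_PER_CONDITION,
                seed=np.random.SeedSequence([COHORT_SEED, si, 2, m.replicate_index]),
            )
            reproduction_check(m, test, ds)
            test_sets[m.m_subject_id] = test
            m_subjects.append(m)
    return m_subjects, test_sets


@pytest.fixture(scope="session")
def passing_m_subjects(trained_cohort):
    m_subjects, test_sets = trained_cohort
    passing = [m for m in m_subjects if m.reproduction_pass]
    return passing, test_sets
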