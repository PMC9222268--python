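"""Shared fixtures.

The expensive cohorts (full 60 s tasks at 150 Hz) are session-scoped so the
feature tables are computed once and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from gazecomplexity import (
    SimConfig,
    build_complexity_table,
    build_conventional_table,
    default_profiles,
    identical_profiles,
    simulate_cohort,
    simulate_recording,
)

#: Seeds frozen for the whole suite.
COHORT_SEED = 0
NULL_COHORT_SEED = 1
BENCH_SEED = 100


@pytest.fixture(scope="session")
def tiny_recording():
    """One 60 s reading task (9000 samples)."""
    config = SimConfig(n_participants=1, seed=7)
    profile = default_profiles()["reading"]
    return simulate_recording(profile, config, "P001", seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Three participants x three activities, full-length tasks."""
    return simulate_cohort(SimConfig(n_participants=3, seed=11))


@pytest.fixture(scope="session")
def study_cohort():
    """The default 30-participant cohort used for end-to-end checks."""
    return simulate_cohort(SimConfig(n_participants=30, seed=COHORT_SEED))


@pytest.fixture(scope="session")
def study_tables(study_cohort):
    """Conventional and complexity tables for the default cohort."""
    return {
        "conventional": build_conventional_table(study_cohort),
        "complexity": build_complexity_table(study_cohort),
    }


@pytest.fixture(scope="session")
def null_cohort():
    """30 participants with all three activity profiles identical."""
    return simulate_cohort(
        SimConfig(n_participants=30, seed=NULL_COHORT_SEED),
        profiles=identical_profiles(),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
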