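"""Shared fixtures: synthetic cohorts and pipeline runs.

Expensive artefacts (the default seven-project cohort and the two
discovery runs over it) are session-scoped so every test module reuses
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from methpanel.pipeline import RunConfig, run_clustered, run_nonclustered
from methpanel.simulate import (
    CohortConfig,
    ProjectConfig,
    default_config,
    simulate_cohort,
)

COHORT_SEED = 11
RUN_SEED = 11
VERIFICATION_SEED = 211


@pytest.fixture(scope="session")
def default_cohort():
    """The default seven-project roster (matrix, sheet, annotation, truth)."""
    return simulate_cohort(default_config(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def small_cohort():
    """A two-project cohort small enough for per-test recomputation."""
    cfg = CohortConfig(
        projects={
            "AAA": ProjectConfig(n_tumor=20, n_normal=6, n_clusters=4,
                                 n_marker_probes=10),
            "BBB": ProjectConfig(n_tumor=20, n_normal=6, n_clusters=4,
                                 n_marker_probes=10, n_shared_probes=3),
        },
        n_background_probes=300,
        n_sexchrom_probes=10,
        n_duplicate_probes=2,
        missing_fraction=0.01,
        seed=5,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def nonclustered_result(default_cohort):
    m, sheet, ann, _ = default_cohort
    return run_nonclustered(m, sheet, ann, RunConfig(seed=RUN_SEED))


@pytest.fixture(scope="session")
def clustered_result(default_cohort):
    m, sheet, ann, _ = default_cohort
    return run_clustered(
        m, sheet, ann, RunConfig(approach="clustered", seed=RUN_SEED)
    )


@pytest.fixture(scope="session")
def verification_cohort():
    """Same generative parameters as the default roster, new seed."""
    return simulate_cohort(
        default_config(seed=VERIFICATION_SEED, dataset="verification")
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
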