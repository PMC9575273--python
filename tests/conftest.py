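"""Shared fixtures: scaled-down and full-design synthetic cohorts."""

import numpy as np
import pytest

from methtraj import (
    CohortDesign,
    IndividualTrajectoryFitter,
    simulate_cohort,
    simulate_truth,
)

#: reduced design for unit tests (same 3/4-wave structure, fewer people)
SMALL_DESIGN = CohortDesign(
    n_individuals=80,
    n_four_wave=50,
    missing_wave_counts=(8, 7, 6, 9),
)

#: the full study design: 600 individuals, 4 waves, 351x4 + 249x3
FULL_DESIGN = CohortDesign()


@pytest.fixture(scope="session")
def small_cohort():
    rng = np.random.default_rng(11)
    truth = simulate_truth(n_cpgs=60, tau=0.03, sigma_s=0.002, sigma_e=0.01, seed=rng)
    return simulate_cohort(SMALL_DESIGN, truth, seed=rng)


@pytest.fixture(scope="session")
def small_traj(small_cohort):
    return IndividualTrajectoryFitter(age_ref=70.0).fit(small_cohort.betas)


@pytest.fixture(scope="session")
def full_cohort():
    """The full-design cohort used by the estimator-equivalence checks."""
    rng = np.random.default_rng(123)
    truth = simulate_truth(n_cpgs=2000, tau=0.03, sigma_s=0.002, sigma_e=0.01, seed=rng)
    return simulate_cohort(FULL_DESIGN, truth, seed=rng)
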