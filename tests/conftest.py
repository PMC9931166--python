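import numpy as np
import pytest

from discountkit import CohortSpec, default_schedules, simulate_cohort


@pytest.fixture(scope="session")
def schedules():
    return default_schedules()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced but complete cohort: 6 participants x 3 sessions x 3 tasks."""
    spec = CohortSpec(n_participants=6, n_timepoints=3, master_seed=11)
    trials, truth = simulate_cohort(spec)
    return spec, trials, truth


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort at the full reference design size (23 x 3 x 3)."""
    spec = CohortSpec(master_seed=7)
    trials, truth = simulate_cohort(spec)
    return spec, trials, truth
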