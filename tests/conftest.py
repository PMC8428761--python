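import pytest

import wristrf as w


@pytest.fixture(scope="session")
def small_params():
    """A cheap cohort: 6+8 subjects on a coarse 21-point grid."""
    return w.SimulationParams(n_group1=6, n_group2=8, n_points=21, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return w.simulate_cohort(small_params)


@pytest.fixture(scope="session")
def study_cohort():
    """Study-sized synthetic cohort: 27 diseased + 40 healthy, 201 points."""
    return w.simulate_cohort(w.SimulationParams(seed=1))


@pytest.fixture
def fast_config():
    """Small classifier template for structural CV tests (not performance)."""
    return w.ClassifierConfig(n_in=201, n_hidden=6, epochs=30, seed=0)
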