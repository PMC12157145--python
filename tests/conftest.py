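import pytest

from monohip import GaitSimConfig, build_feature_table, simulate_cohort


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Small cohort with every stochastic disturbance off."""
    return simulate_cohort(GaitSimConfig(n_participants=5, seed=1)
                           .noise_free())


@pytest.fixture(scope="session")
def default_cohort():
    """The default 25-virtual-participant cohort with calibrated noise."""
    return simulate_cohort(GaitSimConfig())


@pytest.fixture(scope="session")
def default_table(default_cohort):
    """Feature table of the default cohort (one row per gait cycle)."""
    return build_feature_table(default_cohort)
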