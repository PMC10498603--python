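import numpy as np
import pytest

from circdif.synthgen import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (100 baseline circles/sample) shared across tests."""
    return simulate_cohort(SimulationConfig(seed=11, baseline_circles_per_sample=100))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
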