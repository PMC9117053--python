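import numpy as np
import pytest

from ldh_pipeline.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The reference study conditions: 142 patients, default noise, seed 0."""
    return simulate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Noise- and rounding-free cohort: observations sit exactly on the curves."""
    return simulate_cohort(SimulationConfig(n_patients=60, noise_sd=0.0, rounding=0.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
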