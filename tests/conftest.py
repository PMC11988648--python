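import numpy as np
import pytest

from aquaferm import SimParams, simulate_design, simulate_experiment, simulate_reference


@pytest.fixture(scope="session")
def default_design():
    return simulate_design()


@pytest.fixture(scope="session")
def default_params():
    return SimParams()


@pytest.fixture(scope="session")
def default_experiment(default_design, default_params):
    """Default campaign: 117 spectra + per-replicate reference, seed 42."""
    return simulate_experiment(default_design, default_params)


@pytest.fixture(scope="session")
def noiseless_experiment(default_design, default_params):
    params = default_params.noiseless()
    return simulate_experiment(default_design, params), params


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
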