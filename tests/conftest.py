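import pytest

from phenokit import (DielSimParams, SimConfig, simulate_diel_trace,
                      simulate_physio, simulate_stomata)


@pytest.fixture(scope="session")
def control_trace():
    """Default 14-day control diel trace, seed 1."""
    return simulate_diel_trace(SimConfig(seed=1, group="control"))


@pytest.fixture(scope="session")
def salt_trace():
    """Default 14-day salt-treated diel trace, seed 42."""
    return simulate_diel_trace(SimConfig(seed=42, group="salt"))


@pytest.fixture(scope="session")
def salt_stomata():
    """Default salt-treated stomata table, seed 7."""
    return simulate_stomata(SimConfig(seed=7, group="salt"))


@pytest.fixture(scope="session")
def control_stomata():
    return simulate_stomata(SimConfig(seed=3, group="control"))


@pytest.fixture(scope="session")
def physio_table():
    return simulate_physio(SimConfig(seed=0))


@pytest.fixture
def noiseless_params():
    return DielSimParams(noise_sd=0.0)
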