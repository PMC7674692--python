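import pytest

from gametolog_evo.simulate import SimulationConfig, simulate_system


@pytest.fixture(scope="session")
def truth():
    """One default synthetic system shared by read-only tests."""
    return simulate_system(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_truth():
    """A reduced system for the slower read-level tests."""
    return simulate_system(
        SimulationConfig(seed=7, n_species=4, n_families=8, n_background_genes=20)
    )
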