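import pytest

from vqfam.synthetic_data import (
    SimulationConfig,
    load_catalogue_genes,
    load_synteny_groups,
    simulate_family,
)


@pytest.fixture(scope="session")
def catalogue_genes():
    return load_catalogue_genes()


@pytest.fixture(scope="session")
def synteny_groups():
    return load_synteny_groups()


@pytest.fixture(scope="session")
def sim_family():
    """Default-condition synthetic family, fixed seed."""
    return simulate_family(SimulationConfig(seed=1))
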