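import pytest

from repdiv.germline import generate_germline_reference
from repdiv.simulate import SimulationConfig, simulate_repertoire


@pytest.fixture(scope="session")
def germline():
    """A small, mutually dissimilar germline reference shared across tests."""
    return generate_germline_reference(n_v=5, n_j=3, seed=42)


@pytest.fixture(scope="session")
def clean_repertoire(germline):
    """A repertoire with no SHM: molecules are exact ancestor copies."""
    config = SimulationConfig(
        n_naive_clones=20,
        n_molecules=120,
        shm_rate=0.0,
        seq_error_rate=0.0,
        seed=7,
    )
    return simulate_repertoire(germline, config)


@pytest.fixture(scope="session")
def mutated_repertoire(germline):
    """A repertoire with IgG-level SHM and known mutation positions."""
    config = SimulationConfig(
        n_naive_clones=30,
        n_molecules=200,
        shm_rate=0.01,
        seq_error_rate=0.0,
        seed=11,
    )
    return simulate_repertoire(germline, config)
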