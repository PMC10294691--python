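import pytest

from regulonkit.io import load_table1_fixture
from regulonkit.simulate import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def table1():
    """(peaks, sites, expression records) of the packaged binding table."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def sim_study():
    """One small synthetic study reused across read-only tests."""
    config = SimConfig(genome_length=120_000, n_genes=70, seed=11)
    return config, simulate_genome(config)
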