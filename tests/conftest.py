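import numpy as np
import pytest

from ribolens.synthetic import SimulationConfig, generate_genome


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(genome_length=90_000, n_genes=60, library_depth=400_000, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    genome, truth = generate_genome(small_config)
    return small_config, genome, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
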