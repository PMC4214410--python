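import numpy as np
import pytest
from hypothesis import settings

from manihot.sim.config import SimulationConfig, stage_rng

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from manihot.sim.genome import diverge_lineages, generate_ancestral_genome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(genome_length=120_000, n_genes=30, gene_length=900)


@pytest.fixture(scope="session")
def small_genome(small_config):
    """A 120-kb chromosome with 30 genes (session-cached)."""
    return generate_ancestral_genome(small_config, stage_rng(1, "genome"))


@pytest.fixture(scope="session")
def small_lineages(small_config, small_genome):
    genome, genes = small_genome
    return diverge_lineages(genome, genes, small_config, stage_rng(1, "divergence"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
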