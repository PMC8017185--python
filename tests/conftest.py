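import pytest

from circsponge.simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def genome_and_circles(default_config):
    return simulate_genome(default_config)


@pytest.fixture(scope="session")
def reads_and_manifest(default_config, genome_and_circles):
    genome, circles = genome_and_circles
    return simulate_reads(genome, circles, default_config)


@pytest.fixture(scope="session")
def expression(default_config):
    return simulate_expression(default_config)


@pytest.fixture(scope="session")
def small_genome_config() -> SimulationConfig:
    """A <=10 kb single-chromosome genome for exhaustive-oracle checks."""
    return SimulationConfig(
        seed=5, n_chromosomes=1, chromosome_length=10_000,
        n_genes=4, n_circles=3, n_linear_reads=40,
    )
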