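import pytest

from metharray.crossreact import ProbeScanner, build_converted_genomes
from metharray.methstats import compute_beta
from metharray.synthetic import SimulationConfig, simulate_all


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Compact configuration that still exercises every planted feature."""
    defaults = dict(
        seed=seed,
        genome_length_bp=120_000,
        n_chromosomes=2,
        n_islands=2,
        n_duplicated_segments=1,
        n_dhs_distal=6,
        n_genes=2,
        n_enhancers=2,
        n_dhs_proximal=1,
        n_probes_type1=12,
        n_probes_type2=48,
        n_variants=40,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def config():
    return small_config()


@pytest.fixture(scope="session")
def dataset(config):
    return simulate_all(config)


@pytest.fixture(scope="session")
def converted(dataset):
    return build_converted_genomes(dataset.genome)


@pytest.fixture(scope="session")
def scanner(converted):
    return ProbeScanner(converted)


@pytest.fixture(scope="session")
def beta_matrix(dataset):
    inten = dataset.intensities
    return compute_beta(
        inten.meth, inten.unmeth, inten.control_meth, inten.control_unmeth
    )
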