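import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pankit import SimConfig, simulate_genomes

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """2 species x 4 genomes, 60 core + 120 accessory families, no HGT."""
    cfg = SimConfig(
        n_species=2, genomes_per_species=4,
        n_core_families=60, n_accessory_families=120,
        accessory_presence_prob=0.3, gene_length=300, seed=11,
    )
    return simulate_genomes(cfg)


@pytest.fixture(scope="session")
def hgt_sim():
    """2 species x 4 genomes with 2 planted cross-species transfers."""
    cfg = SimConfig(
        n_species=2, genomes_per_species=4,
        n_core_families=60, n_accessory_families=0,
        gene_length=600, n_hgt_events=2, seed=23,
    )
    return simulate_genomes(cfg)
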