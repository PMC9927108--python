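import numpy as np
import pytest
from hypothesis import settings

from multikingdom import simulate

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> simulate.TruthConfig:
    """Reduced study for fast unit tests (full-size runs live in the
    acceptance suite)."""
    return simulate.TruthConfig(
        n_bact_species=40,
        n_fungal_species=12,
        n_votus=8,
        genome_length=10_000,
        contig_length=8_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> simulate.Dataset:
    return simulate.generate_dataset(small_config, n_decoys=10)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
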