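import numpy as np
import pytest

from alubis.consensus import DEFAULT_CONSENSUS
from alubis.simulate import MethylationProfile, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def consensus():
    return DEFAULT_CONSENSUS


@pytest.fixture(scope="session")
def small_dataset():
    """Shared small end-to-end dataset: clean reads, no errors."""
    config = SimulationConfig(
        seed=11,
        genome_length=60_000,
        n_background_alus=8,
        n_novel_insertions=4,
        reads_per_locus=4,
        conversion_rate=1.0,
        error_rate=0.0,
        methylation=MethylationProfile(default_level=0.8, element_level=0.907,
                                       n_islands=1),
    )
    return simulate_dataset(config, n_genes=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
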