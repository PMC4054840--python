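import numpy as np
import pytest
from hypothesis import settings

from codonsig.synthgen import SynthConfig, simulate_world

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def tiny_world():
    """A small two-genome world with sequences, for I/O and plumbing tests."""
    cfg = SynthConfig(
        n_genomes=2,
        n_genes_per_genome=60,
        he_fraction=0.25,
        n_cogs=4,
        n_taxonomy_features=10,
        n_phenotypes=4,
        bias_strength=0.8,
        seed=11,
    )
    return simulate_world(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
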