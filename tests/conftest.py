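import numpy as np
import pytest

from dtifuse.data_model import EntityIndex
from dtifuse.synthetic import SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def drug_index():
    return EntityIndex("drug", ("d1", "d2", "d3"))


@pytest.fixture
def target_index():
    return EntityIndex("target", ("t1", "t2", "t3", "t4"))


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic heterogeneous dataset shared across tests."""
    cfg = SyntheticConfig(n_drugs=20, n_targets=25, n_diseases=10,
                          n_side_effects=12, latent_dim=4, dti_density=0.12,
                          seed=11)
    dataset, latents = generate(cfg)
    return dataset, latents
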