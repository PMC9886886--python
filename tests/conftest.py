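import numpy as np
import pytest

from immunet.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Low-noise planted-module cohort shared across read-only tests."""
    cfg = SyntheticConfig(
        n_genes=40, n_modules=4, module_size=8, loading=3.0, noise_sd=1.0, seed=11
    )
    em, ppi, categories, truth = generate_dataset(cfg)
    return cfg, em, ppi, categories, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
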