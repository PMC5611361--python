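import numpy as np
import pytest

from twigscale.synthetic_data import default_config, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset shared by read-only tests."""
    cfg = default_config(seed=11, n_species=10)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisefree_dataset():
    """Zero-noise, fixed-count dataset: derived means must be exact."""
    cfg = default_config(
        seed=5,
        n_species=12,
        noise_sd_individual=0.0,
        noise_sd_twig=0.0,
        vessel_sigma=0.0,
        vessel_aspect_min=1.0,
        vessel_aspect_max=1.0,
        bending_noise=0.0,
        n_leaf_min=10,
        n_leaf_max=10,
        n_twigs_min=3,
        n_twigs_max=3,
    )
    return generate_dataset(cfg)
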