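import numpy as np
import pytest

from msmda.synthetic import SyntheticConfig, generate_collection, generate_multisource

# a deliberately small backbone so unit tests train in well under a second
TINY_NET = dict(hidden_dims=(8,), cfe_out_dim=6, dsfe_out_dim=4,
                epochs=3, batch_size=16)


@pytest.fixture
def tiny_task():
    cfg = SyntheticConfig(n_domains=3, n_per_domain=48, n_electrodes=4,
                          n_bands=5, seed=7)
    return generate_multisource(cfg)


@pytest.fixture
def tiny_collection():
    cfg = SyntheticConfig(n_domains=6, n_per_domain=30, n_electrodes=2,
                          n_bands=3, seed=11)
    return generate_collection(cfg, n_subjects=2, n_sessions=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
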