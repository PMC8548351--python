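import numpy as np
import pytest

from esiden import SyntheticSpec, make_toy_dataset


@pytest.fixture(scope="session")
def toy_dataset():
    """Small end-to-end fixture set shared by network-level tests."""
    return make_toy_dataset(SyntheticSpec(n_chains=12, length_range=(20, 30),
                                          msa_depth=20, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
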