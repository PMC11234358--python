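import numpy as np
import pytest

from dtafusion import SyntheticSpec, generate_embeddings_and_affinity


@pytest.fixture(scope="session")
def small_synth():
    """A small fully-informative synthetic benchmark shared across tests."""
    spec = SyntheticSpec(n_drugs=30, n_proteins=20, density=1.0, noise_sd=0.1, seed=11)
    embeddings, table = generate_embeddings_and_affinity(spec)
    return spec, embeddings, table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
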