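import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def hcp_like_sources():
    """One global + three network sources at the HCP-like TR (0.72 s)."""
    from boldlag import make_sources
    return make_sources(1200, 0.72, n_networks=3, seed=7)
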