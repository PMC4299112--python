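import numpy as np
import pytest

from semgcs import generate_ksparse, generate_semg, make_matrix


@pytest.fixture(scope="session")
def healthy_segment():
    return generate_semg("healthy", 1024, 2000.0, seed=1)


@pytest.fixture(scope="session")
def ksparse_1024_11():
    return generate_ksparse(1024, 11, "time", seed=7)


@pytest.fixture(scope="session")
def bernoulli_250():
    return make_matrix("bernoulli", 250, 1024, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
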