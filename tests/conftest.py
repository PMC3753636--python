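import numpy as np
import pytest

from stiffscan import GridSpec, gen_stiffness_table


@pytest.fixture(scope="session")
def table():
    """A seeded synthetic stiffness table shared across tests."""
    return gen_stiffness_table(7)


@pytest.fixture(scope="session")
def small_grid():
    """A low-dimensional grid (D = 24) so full-covariance paths stay cheap."""
    return GridSpec(span_start=-100, span_end=500, window_length=300, stride=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])
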