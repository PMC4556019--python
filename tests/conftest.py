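import numpy as np
import pytest

from hubsync.connectome import Connectome, Partition
from hubsync.synthetic import SynthSpec, generate_connectome


@pytest.fixture
def triangle():
    return Connectome(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]]))


@pytest.fixture
def path3():
    return Connectome(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]))


@pytest.fixture
def star5():
    W = np.zeros((5, 5), dtype=int)
    W[0, 1:] = 1
    W[1:, 0] = 1
    return Connectome(W)


@pytest.fixture
def two_node():
    return Connectome(np.array([[0, 1], [1, 0]]))


@pytest.fixture(scope="session")
def small_net():
    """60-node, 4-module rich-club network for fast dynamical tests."""
    c, p = generate_connectome(SynthSpec(n_nodes=60, n_modules=4,
                                         size_range=(10, 20), seed=1))
    return c, p


@pytest.fixture(scope="session")
def human_net():
    """The default 219-node, 11-module synthetic rich-club connectome."""
    return generate_connectome(SynthSpec(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_connectome(rng, n=20, p=0.3):
    W = (rng.random((n, n)) < p).astype(int)
    W = np.triu(W, 1)
    return Connectome(W + W.T)
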