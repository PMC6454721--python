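import numpy as np
import pytest

from ddibalance import SignedNetwork


def random_signed_network(m: int, seed: int, density: float = 0.5,
                          positive_rate: float = 0.6) -> SignedNetwork:
    """A random symmetric signed network for property tests."""
    rng = np.random.default_rng(seed)
    a = np.zeros((m, m), dtype=int)
    iu, ju = np.triu_indices(m, k=1)
    has = rng.random(iu.size) < density
    sign = np.where(rng.random(iu.size) < positive_rate, 1, -1)
    vals = np.where(has, sign, 0)
    a[iu, ju] = vals
    a[ju, iu] = vals
    return SignedNetwork(labels=tuple(f"n{i}" for i in range(m)), adjacency=a)


@pytest.fixture
def toy_network():
    from ddibalance import toy_signed_network

    return toy_signed_network()


@pytest.fixture
def triangle_factory():
    """Build a 3-node network with the given edge signs."""

    def make(s1, s2, s3):
        a = np.array([[0, s1, s3], [s1, 0, s2], [s3, s2, 0]])
        return SignedNetwork(labels=("x", "y", "z"), adjacency=a)

    return make
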