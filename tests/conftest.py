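import numpy as np
import pytest

from ssnmtf.io import ComplexCover, Network
from ssnmtf.synthetic import planted_partition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle_net():
    """Three nodes, edges a-b and b-c."""
    a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return Network(nodes=["a", "b", "c"], adjacency=a)


@pytest.fixture
def small_blocks():
    """Planted partition: 3 blocks of 10, p_in=0.8, p_out=0.05."""
    return planted_partition(3, 10, 0.8, 0.05, seed=7)


def random_instance(rng, n=5, k=3, n_pairs=3, alpha=10.0):
    """A random dense problem: network, factors and constraint matrices."""
    from ssnmtf.constraints import MustLinkConstraints, build_matrices
    from ssnmtf.factorization import FactorPair

    a = rng.uniform(size=(n, n))
    a = np.triu(a, 1)
    a = a + a.T
    net = Network(nodes=[f"v{i}" for i in range(n)], adjacency=a, weighted=True)
    F = rng.uniform(0.1, 1.0, size=(n, k))
    G = rng.uniform(0.1, 1.0, size=(k, k))
    G = 0.5 * (G + G.T)
    pairs = set()
    while len(pairs) < min(n_pairs, n * (n - 1) // 2):
        i, j = rng.choice(n, size=2, replace=False)
        pairs.add(frozenset((f"v{i}", f"v{j}")))
    ml = MustLinkConstraints(pairs=pairs, alpha=alpha)
    cm = build_matrices(ml, net)
    return net, FactorPair(F=F, G=G), cm
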