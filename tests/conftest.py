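import numpy as np
import pytest

from awge_espca import GeneNetwork, make_network, simulate_matrix
from awge_espca.simulate import SimulationSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def canonical_instance():
    """One seeded canonical simulated instance plus its truth record."""
    data, truth = simulate_matrix(SimulationSpec(), rng=np.random.default_rng(7))
    return data, truth, make_network()


@pytest.fixture
def tiny_network():
    """Three vertex-disjoint edges over six probes."""
    return GeneNetwork(np.array([[0, 1], [2, 3], [4, 5]]), n_probes=6)


def random_network(rng, m, n_edges):
    """Random simple network with n_edges distinct edges over m probes."""
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    idx = rng.choice(len(pairs), size=n_edges, replace=False)
    return GeneNetwork(np.array([pairs[i] for i in idx]), n_probes=m)
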