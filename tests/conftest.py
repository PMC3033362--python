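import numpy as np
import pytest

from nervenet.synthetic import SynthParams, generate_connectome, worked_fixture
from nervenet.wiring import AdjacencyNetwork, align_networks, build_network


@pytest.fixture(scope="session")
def fixture_diagram():
    return worked_fixture()


@pytest.fixture(scope="session")
def fixture_networks(fixture_diagram):
    gap = build_network(fixture_diagram, "gap")
    chem = build_network(fixture_diagram, "chem")
    return align_networks(gap, chem, fixture_diagram)


@pytest.fixture(scope="session")
def small_synthetic():
    return generate_connectome(SynthParams(n_neurons=120, seed=7))


def make_net(edges, n=None, directed=False, names=None, weights=None):
    """Small adjacency-network builder for hand-written test graphs."""
    if names is None:
        n = n or (max(max(e) for e in edges) + 1 if edges else 0)
        names = [f"v{i}" for i in range(n)]
    n = len(names)
    A = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[k]
        A[i, j] = w
        if not directed:
            A[j, i] = w
    return AdjacencyNetwork(names=names, weights=A, directed=directed, quantitation="binary")


@pytest.fixture
def path3():
    return make_net([(0, 1), (1, 2)])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
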