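import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssmutpa.network import build_network

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def path_net():
    """A - B - C path graph."""
    return build_network([("A", "B"), ("B", "C")])


@pytest.fixture
def triangle_net():
    return build_network([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star_net():
    """Hub H with leaves L1..L3."""
    return build_network([("H", "L1"), ("H", "L2"), ("H", "L3")])


@pytest.fixture
def rng():
    return np.random.default_rng(1)


def random_connected_pairs(rng, n, p):
    """Edge list of a random connected graph (retries until connected)."""
    import networkx as nx

    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return [(f"N{a:03d}", f"N{b:03d}") for a, b in g.edges()]
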