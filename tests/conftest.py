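import itertools

import numpy as np
import pytest

from cartonet import Network, Partition


def clique_edges(labels):
    return list(itertools.combinations(labels, 2))


@pytest.fixture
def path_abc():
    """Path graph A-B-C."""
    return Network.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def two_cliques():
    """Two disjoint 4-cliques with their natural 2-partition."""
    a = [f"a{i}" for i in range(4)]
    b = [f"b{i}" for i in range(4)]
    net = Network.from_edges(clique_edges(a) + clique_edges(b))
    part = Partition({**{n: "A" for n in a}, **{n: "B" for n in b}})
    return net, part


def random_network(rng, n_min=3, n_max=15, p=0.4, ensure_edge=False):
    """Erdős–Rényi G(n, p)-style test graph with string labels."""
    n = int(rng.integers(n_min, n_max + 1))
    labels = [f"n{i}" for i in range(n)]
    net = Network.from_edges([], nodes=labels)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(labels[i], labels[j])
    if ensure_edge and net.n_edges == 0:
        net.add_edge(labels[0], labels[1])
    return net


def random_partition(rng, net, k_max=5):
    k = int(rng.integers(1, min(k_max, net.n_nodes) + 1))
    labels = [f"M{rng.integers(k)}" for _ in net.nodes]
    return Partition(dict(zip(net.nodes, labels)))
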