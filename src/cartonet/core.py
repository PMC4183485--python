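"""Graph and partition data model shared by every other module.

The central objects are :class:`Network`, an undirected simple graph with
opaque string node labels and optional edge weights, and :class:`Partition`,
a total assignment of nodes to modules.  Matrix views (adjacency, Laplacian,
distance) always use the network's insertion order of nodes so that results
are reproducible run to run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "Partition",
    "DistanceMatrix",
    "adjacency_matrix",
    "degrees",
    "connected_components",
]


class Network:
    """Undirected simple graph with string labels and optional edge weights.

    Invariants: no self-loops, no duplicate edges, endpoints always present
    in the node set, node order deterministic (insertion order).  Edge
    weights are stored when given but are never consulted by the clustering
    engines or the cartography — only the unweighted adjacency view drives
    computation; the weighted view exists for export.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(cls, edges, nodes=None) -> "Network":
        """Build a network from an iterable of (u, v) or (u, v, weight).

        ``nodes`` may pre-seed (and order) the node set, e.g. to keep
        isolated nodes.  Duplicate edges and reversed orientations are
        deduplicated silently; a self-loop is dropped with a logged warning.
        """
        net = cls()
        if nodes is not None:
            for n in nodes:
                net.add_node(n)
        for e in edges:
            if len(e) == 2:
                net.add_edge(e[0], e[1])
            else:
                net.add_edge(e[0], e[1], weight=e[2])
        return net

    def add_node(self, label: str) -> None:
        self._g.add_node(str(label))

    def add_edge(self, u: str, v: str, weight: float | None = None) -> None:
        u, v = str(u), str(v)
        if u == v:
            logger.warning("dropping self-loop on node %r", u)
            return
        if weight is None:
            self._g.add_edge(u, v)
        else:
            self._g.add_edge(u, v, weight=float(weight))

    # -- views ------------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        """Node labels in insertion order."""
        return list(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v in self._g.edges]

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, u: str) -> bool:
        return self._g.has_node(u)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def weight(self, u: str, v: str, default: float | None = None):
        return self._g.edges[u, v].get("weight", default)

    def neighbors(self, u: str) -> list[str]:
        return list(self._g.neighbors(u))

    def degree(self, u: str) -> int:
        return self._g.degree[u]

    @property
    def graph(self) -> nx.Graph:
        """The underlying networkx view (read-only by convention)."""
        return self._g

    def __len__(self) -> int:
        return self.n_nodes

    def __repr__(self) -> str:
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


class Partition:
    """Total map node label -> module label, with contiguous internal indices.

    Module labels are opaque strings preserved for output; internally each
    module also gets an index 0..N-1 in first-seen order so matrix-based
    algorithms can address modules positionally.
    """

    def __init__(self, assignment: dict[str, str]) -> None:
        self.assignment: dict[str, str] = {str(n): str(m) for n, m in assignment.items()}
        self._module_index: dict[str, int] = {}
        for m in self.assignment.values():
            if m not in self._module_index:
                self._module_index[m] = len(self._module_index)

    @classmethod
    def from_labels(cls, nodes, labels) -> "Partition":
        return cls(dict(zip(nodes, (str(l) for l in labels))))

    @property
    def n_modules(self) -> int:
        return len(self._module_index)

    # alias matching the cartography's N (module count)
    N = n_modules

    @property
    def module_labels(self) -> list[str]:
        """Module labels in first-seen order (index order)."""
        return list(self._module_index)

    def module_of(self, node: str) -> str:
        return self.assignment[node]

    def index_of(self, module_label: str) -> int:
        return self._module_index[module_label]

    @property
    def modules(self) -> list[list[str]]:
        """Node lists per module, in module index order."""
        out: list[list[str]] = [[] for _ in range(self.n_modules)]
        for n, m in self.assignment.items():
            out[self._module_index[m]].append(n)
        return out

    def validate_over(self, net: Network) -> None:
        """Check the partition is total over ``net``; raise ValueError if not."""
        missing = [n for n in net.nodes if n not in self.assignment]
        if missing:
            raise ValueError(f"partition missing nodes: {missing[:5]}{'...' if len(missing) > 5 else ''}")

    def __len__(self) -> int:
        return len(self.assignment)

    def __repr__(self) -> str:
        return f"Partition(n_nodes={len(self)}, n_modules={self.n_modules})"


@dataclass
class DistanceMatrix:
    """Symmetric non-negative node x node metric table (zero diagonal)."""

    order: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.order)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match node order")


def adjacency_matrix(net: Network, weighted: bool = False) -> np.ndarray:
    """Square adjacency matrix in node insertion order.

    Unweighted (the default, used by all clustering engines): entry 1 iff an
    edge exists.  Weighted: the stored edge weight (1.0 where absent).
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    order = net.nodes
    idx = {n: i for i, n in enumerate(order)}
    a = np.zeros((len(order), len(order)))
    for u, v in net.edges:
        w = net.weight(u, v, default=1.0) if weighted else 1.0
        a[idx[u], idx[v]] = w
        a[idx[v], idx[u]] = w
    return a


def degrees(net: Network) -> dict[str, int]:
    """Degree (number of incident edges) per node; sums to 2|E|."""
    return {n: net.degree(n) for n in net.nodes}


def connected_components(net: Network) -> list[set[str]]:
    """Connected components as node sets, largest-first order not guaranteed.

    Components are returned in order of their first node's insertion, so the
    result is deterministic for a given network.
    """
    return [set(c) for c in nx.connected_components(net.graph)]
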