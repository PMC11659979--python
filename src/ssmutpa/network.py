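"""Working PPI graph: largest connected component + column-stochastic adjacency.

The propagation operates on an undirected, simple, connected gene graph. The
walk kernel is the column-normalized adjacency A with A[i, j] = 1/M_j when
(i, j) is an edge and M_j is the degree of node j, so every column of A sums
to 1 and applying A preserves the total mass of a vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = ["PPINetwork", "build_network", "column_normalized_adjacency", "edge_pairs"]


@dataclass(frozen=True, eq=False)
class PPINetwork:
    """Undirected, simple, connected gene graph.

    ``nodes`` is lexicographically sorted so every vector/matrix aligned to it
    is reproducible across runs. ``adjacency`` is the symmetric 0/1 CSR matrix
    in that node order.
    """

    nodes: tuple[str, ...]
    adjacency: sparse.csr_array
    degrees: np.ndarray
    index: Mapping[str, int] = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz) // 2

    def degree(self, gene: str) -> int:
        return int(self.degrees[self.index[gene]])

    def neighbors(self, gene: str) -> tuple[str, ...]:
        i = self.index[gene]
        row = self.adjacency[[i], :].tocoo()
        return tuple(self.nodes[j] for j in sorted(row.coords[1]))

    @cached_property
    def node_array(self) -> np.ndarray:
        return np.asarray(self.nodes)

    @cached_property
    def column_stochastic(self) -> sparse.csr_array:
        """Column-normalized adjacency A; y = A @ x preserves sum(x)."""
        inv_deg = 1.0 / self.degrees
        return sparse.csr_array(self.adjacency.multiply(inv_deg[np.newaxis, :]))


def build_network(pairs: Iterable[tuple[str, str]]) -> PPINetwork:
    """Build the working graph from undirected gene pairs.

    Self-loops are dropped, duplicate edges collapsed, and only the largest
    connected component is kept. A size tie between largest components is
    broken in favor of the component containing the lexicographically
    smallest gene symbol (with a warning).
    """
    graph = nx.Graph()
    for a, b in pairs:
        a, b = str(a).strip(), str(b).strip()
        if a and b and a != b:
            graph.add_edge(a, b)
    if graph.number_of_edges() == 0:
        raise ValueError("no usable edges: empty pair list or self-loops only")
    components = list(nx.connected_components(graph))
    max_size = max(len(c) for c in components)
    largest = [c for c in components if len(c) == max_size]
    if len(largest) > 1:
        logger.warning(
            "tie between %d connected components of size %d; keeping the one "
            "with the lexicographically smallest member",
            len(largest),
            max_size,
        )
    component = min(largest, key=min)
    if len(components) > 1:
        logger.info(
            "kept largest connected component: %d of %d nodes",
            max_size,
            graph.number_of_nodes(),
        )
    nodes = tuple(sorted(component))
    adjacency = sparse.csr_array(
        nx.to_scipy_sparse_array(graph.subgraph(component), nodelist=list(nodes), dtype=float)
    )
    degrees = np.asarray(adjacency.sum(axis=1)).ravel()
    return PPINetwork(
        nodes=nodes,
        adjacency=adjacency,
        degrees=degrees,
        index={g: i for i, g in enumerate(nodes)},
    )


def column_normalized_adjacency(net: PPINetwork) -> sparse.csr_array:
    """Return the column-stochastic walk kernel A of ``net``."""
    return net.column_stochastic


def edge_pairs(net: PPINetwork) -> list[tuple[str, str]]:
    """All edges of ``net`` as sorted (u, v) pairs with u < v."""
    upper = sparse.triu(net.adjacency, k=1).tocoo()
    return sorted(
        (net.nodes[i], net.nodes[j]) for i, j in zip(upper.row, upper.col)
    )
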