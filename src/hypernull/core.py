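"""Hypergraph container and matrix representations.

A hypergraph ``H = (V, E)`` is a node set together with a collection of
non-empty node subsets (hyperedges).  Internally nodes are 0-based integer
indices; the original labels are preserved in :attr:`Hypergraph.node_labels`
so that file I/O round-trips whatever identifiers a dataset uses.

The incidence matrix ``C`` (n x m, binary, ``c_ij = 1`` iff node *i* belongs
to hyperedge *j*) is the representation every randomization operates on.
From it derive the hyperdegree matrix ``D`` (``d_ij`` = number of hyperedges
containing both *i* and *j*; diagonal = hyperdegrees), the hyperedge-degree
matrix ``De`` (``de_ij`` = shared-node count of hyperedges *i* and *j*;
diagonal = hyperedge sizes) and the two adjacency matrices

    A = C C^T - D        (node-node, zero diagonal)
    B = C^T C - De       (hyperedge-hyperedge, zero diagonal)

Connectivity is defined through the projection: two nodes are connected iff
they share at least one hyperedge.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Hashable, Iterable, Sequence, Set

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

# above this many cells, matrices are realized sparse
_DENSE_CELL_LIMIT = 1_000_000


class Hypergraph:
    """A hypergraph over ``n`` labelled nodes with ``m`` hyperedges.

    Parameters
    ----------
    node_labels
        Sequence of distinct opaque labels; position is the node index.
    hyperedges
        Sequence of sets of node indices (``0 <= idx < n``); every
        hyperedge must be non-empty and every node must appear in at
        least one hyperedge.  Duplicate hyperedges are allowed.
    """

    __slots__ = ("node_labels", "hyperedges")

    def __init__(
        self,
        node_labels: Sequence[Hashable],
        hyperedges: Iterable[Set[int] | Iterable[int]],
    ) -> None:
        labels = list(node_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be distinct")
        edges = [frozenset(e) for e in hyperedges]
        n = len(labels)
        covered: set[int] = set()
        for j, e in enumerate(edges):
            if not e:
                raise ValueError(f"empty hyperedge at position {j}")
            for i in e:
                if not isinstance(i, (int, np.integer)) or not (0 <= i < n):
                    raise ValueError(
                        f"hyperedge {j} contains invalid node index {i!r} "
                        f"(must be an integer in [0, {n}))"
                    )
            covered.update(e)
        if covered != set(range(n)):
            missing = sorted(set(range(n)) - covered)
            raise ValueError(f"nodes never appear in any hyperedge: {missing}")
        self.node_labels: list[Hashable] = labels
        self.hyperedges: list[frozenset[int]] = edges

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of nodes."""
        return len(self.node_labels)

    @property
    def m(self) -> int:
        """Number of hyperedges."""
        return len(self.hyperedges)

    def memberships(self) -> list[set[int]]:
        """For each node, the set of hyperedge indices containing it."""
        mem: list[set[int]] = [set() for _ in range(self.n)]
        for j, e in enumerate(self.hyperedges):
            for i in e:
                mem[i].add(j)
        return mem

    def copy(self) -> "Hypergraph":
        return Hypergraph(self.node_labels, self.hyperedges)

    def labelled_hyperedges(self) -> list[frozenset]:
        """Hyperedges expressed with original labels."""
        return [frozenset(self.node_labels[i] for i in e) for e in self.hyperedges]

    # -- comparison ------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        """Equality up to hyperedge order (same labels, same multiset of edges)."""
        if not isinstance(other, Hypergraph):
            return NotImplemented
        return (
            set(self.node_labels) == set(other.node_labels)
            and Counter(self.labelled_hyperedges())
            == Counter(other.labelled_hyperedges())
        )

    def __hash__(self):  # pragma: no cover - explicit: mutable edge list
        raise TypeError("Hypergraph is not hashable")

    def __repr__(self) -> str:
        return f"Hypergraph(n={self.n}, m={self.m})"


def build_hypergraph(raw_hyperedges: Iterable[Iterable[Hashable]]) -> Hypergraph:
    """Build a :class:`Hypergraph` from hyperedges given as label collections.

    Node labels are the sorted union of all labels seen.  A label repeated
    inside one hyperedge collapses to a single membership (logged).

    Raises
    ------
    ValueError
        If any raw hyperedge is empty (the offending position is named).
    """
    raw = [list(e) for e in raw_hyperedges]
    for j, e in enumerate(raw):
        if not e:
            raise ValueError(f"empty hyperedge at line/position {j + 1}")
        if len(set(e)) != len(e):
            logger.info("hyperedge %d: duplicate labels collapsed to one membership", j + 1)
    labels = sorted({lab for e in raw for lab in e}, key=lambda x: (str(type(x)), x))
    index = {lab: i for i, lab in enumerate(labels)}
    edges = [frozenset(index[lab] for lab in e) for e in raw]
    return Hypergraph(labels, edges)


def incidence_matrix(H: Hypergraph, *, sparse: bool | None = None):
    """The n x m binary incidence matrix ``C``.

    Returns a dense ``numpy.ndarray`` for small hypergraphs and a CSR
    sparse matrix when ``n * m`` exceeds 10^6 cells (or when ``sparse``
    forces either representation).
    """
    n, m = H.n, H.m
    rows, cols = [], []
    for j, e in enumerate(H.hyperedges):
        for i in e:
            rows.append(i)
            cols.append(j)
    data = np.ones(len(rows), dtype=np.int64)
    C = sp.coo_matrix((data, (rows, cols)), shape=(n, m)).tocsr()
    if sparse is None:
        sparse = n * m > _DENSE_CELL_LIMIT
    return C if sparse else C.toarray()


def degree_matrices(H: Hypergraph):
    """The hyperdegree matrix ``D`` (n x n) and hyperedge-degree matrix ``De`` (m x m).

    ``d_ij`` counts hyperedges containing both nodes *i* and *j* (diagonal:
    hyperdegree); ``de_ij`` counts nodes shared by hyperedges *i* and *j*
    (diagonal: hyperedge degree).
    """
    C = np.asarray(incidence_matrix(H, sparse=False))
    D = C @ C.T
    De = C.T @ C
    return D, De


def adjacency_matrix(H: Hypergraph) -> np.ndarray:
    """Node adjacency ``A = C C^T - D``: multiplicities of shared hyperedges, zero diagonal."""
    C = np.asarray(incidence_matrix(H, sparse=False))
    A = C @ C.T
    np.fill_diagonal(A, 0)
    return A


def hyperedge_adjacency_matrix(H: Hypergraph) -> np.ndarray:
    """Hyperedge adjacency ``B = C^T C - De``: pairwise intersection sizes, zero diagonal."""
    C = np.asarray(incidence_matrix(H, sparse=False))
    B = C.T @ C
    np.fill_diagonal(B, 0)
    return B


def projected_graph(H: Hypergraph) -> nx.Graph:
    """Unweighted projection: simple graph joining nodes that share >= 1 hyperedge.

    All ``n`` nodes are present (isolated nodes included); no self-loops.
    """
    G = nx.Graph()
    G.add_nodes_from(range(H.n))
    for e in H.hyperedges:
        members = sorted(e)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                G.add_edge(members[a], members[b])
    return G


def giant_component_size(
    H: Hypergraph,
    removed_nodes: Set[int] = frozenset(),
    removed_hyperedges: Set[int] = frozenset(),
) -> int:
    """Size of the largest connected component of the surviving projection.

    Surviving nodes are those not removed; surviving hyperedges are the
    non-removed hyperedges restricted to surviving nodes.  Isolated
    surviving nodes count as components of size 1.
    """
    removed_nodes = set(removed_nodes)
    removed_hyperedges = set(removed_hyperedges)
    alive = [i for i in range(H.n) if i not in removed_nodes]
    if not alive:
        return 0
    G = nx.Graph()
    G.add_nodes_from(alive)
    for j, e in enumerate(H.hyperedges):
        if j in removed_hyperedges:
            continue
        members = sorted(i for i in e if i not in removed_nodes)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                G.add_edge(members[a], members[b])
    return max(len(c) for c in nx.connected_components(G))
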