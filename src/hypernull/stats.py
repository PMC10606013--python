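"""Hypergraph statistics, hypertriangle counting and the significance ratio μ.

Per-node statistics come in two families: incidence-level quantities
(hyperdegree = number of hyperedges containing a node, strength = total
shared memberships with other nodes) and projection-level quantities
(degree, clustering, average neighbor degree, assortativity) computed on the
unweighted projection graph, where two nodes are adjacent iff they share at
least one hyperedge.  "Degree" always means projection degree; "hyperdegree"
always means incidence row sum.

The significance ratio μ = (statistic on a null model) / (statistic on the
original network) quantifies how much of a statistic survives
randomization: μ near 1 means the statistic is explained by the constraints
the null model preserves, μ far from 1 flags a non-trivial structural
feature.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import Hypergraph, adjacency_matrix, projected_graph


def hyperdegrees(H: Hypergraph) -> np.ndarray:
    """Number of hyperedges containing each node (incidence row sums)."""
    d = np.zeros(H.n, dtype=np.int64)
    for e in H.hyperedges:
        for i in e:
            d[i] += 1
    return d


def hyperedge_degrees(H: Hypergraph) -> np.ndarray:
    """Number of nodes in each hyperedge (incidence column sums)."""
    return np.array([len(e) for e in H.hyperedges], dtype=np.int64)


def _neighbor_sets(H: Hypergraph) -> list[set[int]]:
    nbrs: list[set[int]] = [set() for _ in range(H.n)]
    for e in H.hyperedges:
        for i in e:
            nbrs[i].update(e)
    for i in range(H.n):
        nbrs[i].discard(i)
    return nbrs


def co_average_hyperdegree(H: Hypergraph, i: int | None = None):
    """Mean hyperdegree over a node's distinct projection neighbors.

    Nodes isolated in the projection (members of singleton hyperedges
    only) get 0.  With ``i=None`` the full length-n vector is returned.
    """
    d = hyperdegrees(H)
    nbrs = _neighbor_sets(H)

    def one(v: int) -> float:
        if not nbrs[v]:
            return 0.0
        return float(np.mean([d[u] for u in sorted(nbrs[v])]))

    if i is not None:
        return one(i)
    return np.array([one(v) for v in range(H.n)])


def hyperdegree_distribution(H: Hypergraph) -> dict[int, float]:
    """P(hyperdegree = k) for a uniformly random node; probabilities sum to 1."""
    counts = Counter(hyperdegrees(H).tolist())
    return {k: c / H.n for k, c in sorted(counts.items())}


def joint_hyperdegree_signature(H: Hypergraph) -> Counter:
    """Multiset, over hyperedges, of the sorted tuple of members' hyperdegrees.

    This is the quantity the H2k swap preserves exactly: exchanging two
    equal-hyperdegree nodes between hyperedges leaves each hyperedge's
    hyperdegree tuple unchanged.
    """
    d = hyperdegrees(H)
    return Counter(tuple(sorted(int(d[i]) for i in e)) for e in H.hyperedges)


def local_clustering(H: Hypergraph, i: int) -> float:
    """Clustering of node *i* in the unweighted projection.

    (# adjacent pairs among i's distinct neighbors) / C(deg_i, 2);
    nodes with fewer than two neighbors get 0.
    """
    G = projected_graph(H)
    return float(nx.clustering(G, i))


def mean_clustering(H: Hypergraph) -> float:
    """Average projection clustering over *all* nodes (degree < 2 contributes 0)."""
    G = projected_graph(H)
    return float(nx.average_clustering(G, count_zeros=True))


def average_neighbor_degree(H: Hypergraph, i: int | None = None):
    """Mean projection degree over a node's distinct projection neighbors.

    Isolated nodes get 0.  With ``i=None`` the full vector is returned;
    the network value is the mean of this vector over all nodes.
    """
    nbrs = _neighbor_sets(H)
    deg = [len(s) for s in nbrs]

    def one(v: int) -> float:
        if not nbrs[v]:
            return 0.0
        return float(np.mean([deg[u] for u in sorted(nbrs[v])]))

    if i is not None:
        return one(i)
    return np.array([one(v) for v in range(H.n)])


def strength(H: Hypergraph, i: int | None = None):
    """Total shared memberships with other nodes: row sums of A = CC^T - D."""
    A = adjacency_matrix(H)
    s = A.sum(axis=1)
    return int(s[i]) if i is not None else s


def assortativity(H: Hypergraph, endpoint_degree: str = "projection") -> float:
    """Degree assortativity r over the M projection edges (Newman's formula).

    With x_i, y_i the endpoint degrees of projection edge i:

        r = [M^-1 Σ x_i y_i − (M^-1 Σ (x_i+y_i)/2)^2]
            / [M^-1 Σ (x_i²+y_i²)/2 − (M^-1 Σ (x_i+y_i)/2)^2]

    ``endpoint_degree`` selects whether endpoint values are projection
    degrees (default) or hyperdegrees.  Returns NaN with a warning when
    the endpoint-degree variance over edge ends is zero (e.g. a regular
    projection), where r is undefined.
    """
    G = projected_graph(H)
    M = G.number_of_edges()
    if M == 0:
        warnings.warn("assortativity undefined: projection has no edges")
        return float("nan")
    if endpoint_degree == "projection":
        val = dict(G.degree())
    elif endpoint_degree == "hyperdegree":
        d = hyperdegrees(H)
        val = {i: int(d[i]) for i in range(H.n)}
    else:
        raise ValueError("endpoint_degree must be 'projection' or 'hyperdegree'")
    x = np.array([val[u] for u, v in G.edges()], dtype=float)
    y = np.array([val[v] for u, v in G.edges()], dtype=float)
    mean_half = ((x + y) / 2).mean()
    num = (x * y).mean() - mean_half**2
    den = ((x**2 + y**2) / 2).mean() - mean_half**2
    if den == 0:
        warnings.warn("assortativity undefined: zero degree variance over edge ends")
        return float("nan")
    return float(num / den)


def count_hypertriangles(H: Hypergraph) -> int:
    """Number of hypertriangles: node triples pairwise covered by three distinct hyperedges.

    A triple {u, v, w} counts iff there exist pairwise-distinct hyperedges
    e_uv ⊇ {u,v}, e_vw ⊇ {v,w}, e_wu ⊇ {w,u}, and no single hyperedge
    contains all three nodes (such triples are excluded outright).
    """
    mem = H.memberships()
    nbrs = _neighbor_sets(H)
    count = 0
    for u in range(H.n):
        for v in sorted(nbrs[u]):
            if v <= u:
                continue
            common = nbrs[u] & nbrs[v]
            for w in sorted(common):
                if w <= v:
                    continue
                if mem[u] & mem[v] & mem[w]:
                    continue  # all three inside one hyperedge
                if _has_distinct_representatives(
                    mem[u] & mem[v], mem[v] & mem[w], mem[w] & mem[u]
                ):
                    count += 1
    return count


def _has_distinct_representatives(s1: set, s2: set, s3: set) -> bool:
    # brute-force system of distinct representatives for three small sets
    for a in s1:
        for b in s2:
            if b == a:
                continue
            if s3 - {a, b}:
                return True
    return False


def significance_mu(stat_null: float, stat_original: float) -> float:
    """Significance ratio μ = stat_null / stat_original (undefined for a zero original)."""
    if stat_original == 0:
        warnings.warn("significance μ undefined: original statistic is zero")
        return float("nan")
    return stat_null / stat_original


@dataclass
class StatReport:
    """Bundle of the per-node, per-hyperedge and global hypergraph statistics."""

    n: int
    m: int
    hyperdegree: np.ndarray
    hyperedge_degree: np.ndarray
    strength: np.ndarray
    clustering: np.ndarray
    co_average_hyperdegree: np.ndarray
    average_neighbor_degree: np.ndarray
    mean_degree: float
    mean_hyperdegree: float
    mean_clustering: float
    assortativity: float
    hyperdegree_distribution: dict[int, float] = field(repr=False)
    joint_hyperdegree_signature: Counter = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "m": self.m,
            "mean_degree": self.mean_degree,
            "mean_hyperdegree": self.mean_hyperdegree,
            "mean_clustering": self.mean_clustering,
            "assortativity": self.assortativity,
            "hyperdegree": self.hyperdegree.tolist(),
            "hyperedge_degree": self.hyperedge_degree.tolist(),
            "strength": self.strength.tolist(),
            "clustering": self.clustering.tolist(),
            "co_average_hyperdegree": self.co_average_hyperdegree.tolist(),
            "average_neighbor_degree": self.average_neighbor_degree.tolist(),
            "hyperdegree_distribution": {
                str(k): v for k, v in self.hyperdegree_distribution.items()
            },
        }


def compute_stats(H: Hypergraph) -> StatReport:
    """Compute the full statistics report for a hypergraph."""
    G = projected_graph(H)
    d = hyperdegrees(H)
    clustering = np.array([nx.clustering(G, i) for i in range(H.n)], dtype=float)
    deg = np.array([G.degree(i) for i in range(H.n)], dtype=float)
    return StatReport(
        n=H.n,
        m=H.m,
        hyperdegree=d,
        hyperedge_degree=hyperedge_degrees(H),
        strength=strength(H),
        clustering=clustering,
        co_average_hyperdegree=co_average_hyperdegree(H),
        average_neighbor_degree=average_neighbor_degree(H),
        mean_degree=float(deg.mean()),
        mean_hyperdegree=float(d.mean()),
        mean_clustering=float(clustering.mean()),
        assortativity=assortativity(H),
        hyperdegree_distribution=hyperdegree_distribution(H),
        joint_hyperdegree_signature=joint_hyperdegree_signature(H),
    )
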