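"""Graph queries on the fitted gene network.

The zero pattern of Sigma^{-1} defines an undirected graph: an edge joins
genes i and j iff the precision entry sigma^{ij} is non-zero.  This module
answers the graph questions an analyst asks of that network: the maximal
cliques (which also drive the MLE-existence check), r-step neighbourhoods
around a gene, clusters of flagged (e.g. differentially expressed) genes,
and shortest paths.  networkx supplies the algorithms (Bron-Kerbosch with
pivoting for cliques, BFS for distances).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import scipy.sparse as sp

from .pattern import ZeroPattern

__all__ = [
    "GeneGraph",
    "maximal_cliques",
    "neighbourhood",
    "flagged_clusters",
    "shortest_path",
    "nearest_flagged",
    "write_graphml",
    "write_edge_list",
]


@dataclass
class GeneGraph:
    """Undirected gene network; no self-loops; labels are opaque strings."""

    G: nx.Graph
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.G.remove_edges_from(nx.selfloop_edges(self.G))
        if not self.labels:
            self.labels = [str(v) for v in self.G.nodes]
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @classmethod
    def from_pattern(cls, pattern: ZeroPattern, labels=None) -> "GeneGraph":
        p = pattern.p
        if labels is None:
            labels = [f"gene{j}" for j in range(p)]
        labels = [str(x) for x in labels]
        coo = pattern.offdiag_upper()
        G = nx.Graph()
        G.add_nodes_from(labels)
        G.add_edges_from((labels[i], labels[j])
                         for i, j in zip(coo.row, coo.col))
        return cls(G, labels)

    @classmethod
    def from_adjacency(cls, adj, labels=None) -> "GeneGraph":
        A = sp.csr_matrix(adj)
        return cls.from_pattern(ZeroPattern(A), labels)

    def index_of(self, label: str) -> int:
        return self._index[str(label)]

    def set_flags(self, name: str, flagged) -> None:
        flagged = {str(g) for g in flagged}
        nx.set_node_attributes(
            self.G, {v: (v in flagged) for v in self.G.nodes}, name=name)

    @property
    def n_nodes(self) -> int:
        return self.G.number_of_nodes()


def maximal_cliques(graph: GeneGraph) -> tuple[list[frozenset], Counter]:
    """All maximal cliques (Bron-Kerbosch with pivoting) + size histogram.

    Isolated vertices count as singleton cliques.
    """
    cliques = [frozenset(c) for c in nx.find_cliques(graph.G)]
    sizes = Counter(len(c) for c in cliques)
    return cliques, sizes


def neighbourhood(graph: GeneGraph, gene: str, r: int) -> GeneGraph:
    """Induced subgraph on all genes within r edges of ``gene``."""
    gene = str(gene)
    if gene not in graph.G:
        raise KeyError(f"gene {gene!r} not in graph")
    if r < 0:
        raise ValueError("radius must be >= 0")
    ball = nx.single_source_shortest_path_length(graph.G, gene, cutoff=r)
    sub = graph.G.subgraph(ball).copy()
    labels = [lab for lab in graph.labels if lab in ball]
    return GeneGraph(sub, labels)


def flagged_clusters(graph: GeneGraph, flagged) -> tuple[list[set], Counter]:
    """Connected components of the subgraph induced by flagged genes."""
    flagged = [str(g) for g in flagged]
    missing = [g for g in flagged if g not in graph.G]
    if missing:
        raise KeyError(f"flagged genes not in graph: {missing[:5]}")
    sub = graph.G.subgraph(flagged)
    comps = [set(c) for c in nx.connected_components(sub)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    sizes = Counter(len(c) for c in comps)
    return comps, sizes


def _bfs_lexicographic(G: nx.Graph, source: str):
    """BFS visiting neighbours in label order; yields (node, predecessor)."""
    from collections import deque

    seen = {source: None}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in sorted(G.neighbors(v)):
            if w not in seen:
                seen[w] = v
                queue.append(w)
    return seen


def shortest_path(graph: GeneGraph, g1: str, g2: str) -> list[str] | None:
    """Unweighted shortest path; ties broken by gene-label lexicographic
    order (the BFS explores neighbours in sorted order).  None if the two
    genes are disconnected."""
    g1, g2 = str(g1), str(g2)
    for g in (g1, g2):
        if g not in graph.G:
            raise KeyError(f"gene {g!r} not in graph")
    pred = _bfs_lexicographic(graph.G, g1)
    if g2 not in pred:
        return None
    path = [g2]
    while path[-1] != g1:
        path.append(pred[path[-1]])
    return path[::-1]


def nearest_flagged(graph: GeneGraph, gene: str, flagged) -> str | None:
    """Closest flagged gene to ``gene`` (itself excluded); BFS distance,
    ties broken lexicographically.  None if no flagged gene is reachable."""
    gene = str(gene)
    flagged = {str(g) for g in flagged} - {gene}
    if gene not in graph.G:
        raise KeyError(f"gene {gene!r} not in graph")
    dist = nx.single_source_shortest_path_length(graph.G, gene)
    best = None
    for g in flagged:
        if g in dist:
            key = (dist[g], g)
            if best is None or key < best:
                best = key
    return best[1] if best else None


def write_graphml(graph: GeneGraph, path) -> None:
    nx.write_graphml(graph.G, path)


def write_edge_list(graph: GeneGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\n")
        for u, v in sorted(map(sorted, graph.G.edges())):
            fh.write(f"{u}\t{v}\n")
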