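"""kNN/SNN graph construction and graph-level validation metrics.

The graph metrics score a labeling against the topology of a (shared)
nearest-neighbor graph built on a cell embedding: neighborhood purity and
class enrichment and the inverse Simpson index (LISI) work per node,
proportion of weakly connected nodes, cohesion/adhesion and adjusted mean
shortest path per class, modularity on the whole graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from .embedding import as_embedding, pairwise_distances
from .errors import InputError, UndefinedMetricError
from .partitions import as_partition

__all__ = [
    "NeighborGraph",
    "build_knn_graph",
    "build_snn_graph",
    "neighborhood_purity",
    "lisi",
    "pwc",
    "modularity",
    "cohesion",
    "adhesion",
    "amsp",
    "nce",
]


@dataclass
class NeighborGraph:
    """Undirected weighted graph over n nodes with per-node neighbor lists."""

    n: int
    adj: dict  # node -> {neighbor: weight}
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_edges(cls, n: int, edges, weights=None, meta=None) -> "NeighborGraph":
        adj: dict = {i: {} for i in range(n)}
        weights = weights if weights is not None else [1.0] * len(edges)
        for (i, j), w in zip(edges, weights):
            if i == j:
                continue
            if w < 0:
                raise InputError("edge weights must be nonnegative")
            adj[i][j] = float(w)
            adj[j][i] = float(w)
        return cls(n=n, adj=adj, meta=meta or {})

    def neighbors(self, i: int):
        return self.adj[i]

    def edges(self):
        for i, nbrs in self.adj.items():
            for j, w in nbrs.items():
                if i < j:
                    yield i, j, w

    def degree_weights(self) -> np.ndarray:
        return np.array([sum(self.adj[i].values()) for i in range(self.n)])

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_weighted_edges_from(self.edges())
        return g

    def subgraph(self, nodes) -> "NeighborGraph":
        nodes = list(nodes)
        remap = {v: i for i, v in enumerate(nodes)}
        edges, weights = [], []
        for v in nodes:
            for u, w in self.adj[v].items():
                if u in remap and v < u:
                    edges.append((remap[v], remap[u]))
                    weights.append(w)
        return NeighborGraph.from_edges(len(nodes), edges, weights, dict(self.meta))


def _knn_neighbor_sets(emb, k: int) -> list[set]:
    """Inclusive-tie k-nearest-neighbor sets (all points tied at the k-th
    distance are included), self excluded."""
    emb = as_embedding(emb)
    n = emb.n
    if k >= n:
        raise InputError(f"k={k} must be smaller than n={n}")
    D = pairwise_distances(emb)
    np.fill_diagonal(D, np.inf)
    sets = []
    for i in range(n):
        kth = np.partition(D[i], k - 1)[k - 1]
        # inclusive tie rule, with a relative tolerance so exact geometric
        # ties survive floating-point rounding
        sets.append(set(np.flatnonzero(D[i] <= kth * (1 + 1e-9))))
    return sets


def build_knn_graph(emb, k: int, mutual: bool = False) -> NeighborGraph:
    """Unweighted kNN graph, symmetrized by union (or intersection when
    mutual=True).  Ties at the k-th distance are all included."""
    emb = as_embedding(emb)
    sets = _knn_neighbor_sets(emb, k)
    edges = set()
    for i, s in enumerate(sets):
        for j in s:
            if mutual and i not in sets[j]:
                continue
            edges.add((min(i, j), max(i, j)))
    g = NeighborGraph.from_edges(emb.n, sorted(edges))
    g.meta.update(k=k, snn=False, metric=emb.metric, mutual=mutual)
    return g


def build_snn_graph(emb, k: int) -> NeighborGraph:
    """Shared-nearest-neighbor graph: edge weight = Jaccard overlap of the
    two nodes' kNN sets; zero-weight edges are dropped."""
    emb = as_embedding(emb)
    sets = _knn_neighbor_sets(emb, k)
    edges, weights = [], []
    candidates = set()
    for i, s in enumerate(sets):
        for j in s:
            candidates.add((min(i, j), max(i, j)))
    for i, j in sorted(candidates):
        inter = len(sets[i] & sets[j])
        union = len(sets[i] | sets[j])
        if union and inter:
            edges.append((i, j))
            weights.append(inter / union)
    g = NeighborGraph.from_edges(emb.n, edges, weights)
    g.meta.update(k=k, snn=True, metric=emb.metric)
    return g


def neighborhood_purity(g: NeighborGraph, labels) -> np.ndarray:
    """Per node, the fraction of graph neighbors sharing its label.

    Isolated nodes get NaN (no neighborhood to score).
    """
    part = as_partition(labels)
    if part.n != g.n:
        raise InputError("labels and graph disagree on n")
    out = np.full(g.n, np.nan)
    for i in range(g.n):
        nbrs = list(g.adj[i])
        if not nbrs:
            continue
        out[i] = float(np.mean(part.codes[nbrs] == part.codes[i]))
    return out


def lisi(emb_or_graph, labels, k: int | None = None) -> np.ndarray:
    """Per-node inverse Simpson index over the neighborhood's labels.

    1 means a perfectly homogeneous neighborhood; k means all classes
    equally represented.  On an embedding the k nearest neighbors are
    used; on a graph the node's neighbor list.
    """
    part = as_partition(labels)
    if isinstance(emb_or_graph, NeighborGraph):
        g = emb_or_graph
        if part.n != g.n:
            raise InputError("labels and graph disagree on n")
        neighbor_lists = [list(g.adj[i]) for i in range(g.n)]
    else:
        if k is None:
            raise InputError("k is required when computing LISI from an embedding")
        sets = _knn_neighbor_sets(emb_or_graph, k)
        neighbor_lists = [sorted(s) for s in sets]
    out = np.full(part.n, np.nan)
    for i, nbrs in enumerate(neighbor_lists):
        if not nbrs:
            continue
        p = np.bincount(part.codes[nbrs], minlength=part.K) / len(nbrs)
        out[i] = 1.0 / float((p ** 2).sum())
    return out


def pwc(g: NeighborGraph, labels) -> dict:
    """Proportion of weakly connected nodes per class.

    A node is weakly connected when its (weighted) degree toward other
    classes strictly exceeds its degree within its own class.
    """
    part = as_partition(labels)
    if part.n != g.n:
        raise InputError("labels and graph disagree on n")
    weak = np.zeros(part.K)
    sizes = part.group_sizes()
    for i in range(g.n):
        inside = outside = 0.0
        for j, w in g.adj[i].items():
            if part.codes[j] == part.codes[i]:
                inside += w
            else:
                outside += w
        if outside > inside:
            weak[part.codes[i]] += 1
    return {tok: float(weak[kk] / sizes[kk]) for kk, tok in enumerate(part.categories)}


def modularity(g: NeighborGraph, labels, gamma: float = 1.0) -> float:
    """Newman modularity with resolution gamma on the (weighted) graph:
    Q = (1/2m) sum_ij (A_ij - gamma k_i k_j / 2m) delta(c_i, c_j)."""
    part = as_partition(labels)
    if part.n != g.n:
        raise InputError("labels and graph disagree on n")
    two_m = 2.0 * g.total_weight()
    if two_m == 0:
        raise UndefinedMetricError("modularity undefined on an edgeless graph")
    deg = g.degree_weights()
    within = 0.0
    for i, j, w in g.edges():
        if part.codes[i] == part.codes[j]:
            within += 2.0 * w  # both (i,j) and (j,i)
    deg_by_class = np.zeros(part.K)
    np.add.at(deg_by_class, part.codes, deg)
    expected = gamma * float((deg_by_class ** 2).sum()) / two_m
    return (within - expected) / two_m


def cohesion(g: NeighborGraph) -> int:
    """Vertex connectivity: nodes to remove to disconnect the graph."""
    if g.n < 2:
        raise UndefinedMetricError("cohesion needs at least 2 nodes")
    return int(nx.node_connectivity(g.to_networkx()))


def adhesion(g: NeighborGraph) -> int:
    """Edge connectivity: edges to remove to disconnect the graph."""
    if g.n < 2:
        raise UndefinedMetricError("adhesion needs at least 2 nodes")
    return int(nx.edge_connectivity(g.to_networkx()))


def _csgraph(g: NeighborGraph, weighted: bool):
    from scipy.sparse import coo_matrix
    rows, cols, vals = [], [], []
    for i, j, w in g.edges():
        rows += [i, j]
        cols += [j, i]
        vals += [w if weighted else 1.0] * 2
    return coo_matrix((vals, (rows, cols)), shape=(g.n, g.n)).tocsr()


def amsp(g: NeighborGraph, labels=None, weighted: bool = False):
    """Adjusted mean shortest path of a (class sub)graph.

    Connected graph: mean all-pairs shortest path / sqrt(N).  Disconnected:
    sum over components of (1 + mean shortest path within the component)
    divided by sqrt(N); single-node components contribute 1.  Paths are in
    hops unless weighted=True.  With labels, returns a per-class dict over
    class-induced subgraphs.
    """
    if labels is not None:
        part = as_partition(labels)
        if part.n != g.n:
            raise InputError("labels and graph disagree on n")
        return {tok: amsp(g.subgraph(np.flatnonzero(part.codes == k)), None, weighted)
                for k, tok in enumerate(part.categories)}
    if g.n < 2:
        raise UndefinedMetricError("AMSP needs at least 2 nodes")
    mat = _csgraph(g, weighted)
    n_comp, comp = connected_components(mat, directed=False)
    D = shortest_path(mat, method="D", directed=False, unweighted=not weighted)
    if n_comp == 1:
        m = float(D[np.triu_indices(g.n, 1)].mean() if g.n > 1 else 0.0)
        return m / np.sqrt(g.n)
    total = 0.0
    for c in range(n_comp):
        idx = np.flatnonzero(comp == c)
        if len(idx) == 1:
            total += 1.0
        else:
            sub = D[np.ix_(idx, idx)]
            total += 1.0 + float(sub[np.triu_indices(len(idx), 1)].mean())
    return total / np.sqrt(g.n)


def nce(g: NeighborGraph, labels, pseudocount: float | None = None) -> np.ndarray:
    """Per-node log2 enrichment of the node's class among its neighbors
    over the class's global abundance.  The default pseudocount is
    1 / (mean degree + number of classes), guarding against -inf."""
    part = as_partition(labels)
    if part.n != g.n:
        raise InputError("labels and graph disagree on n")
    global_frac = part.group_sizes() / part.n
    if pseudocount is None:
        k_mean = float(np.mean([len(g.adj[i]) for i in range(g.n)]))
        pseudocount = 1.0 / (k_mean + part.K)
    out = np.full(g.n, np.nan)
    for i in range(g.n):
        nbrs = list(g.adj[i])
        if not nbrs:
            continue
        obs = float(np.mean(part.codes[nbrs] == part.codes[i]))
        exp = global_frac[part.codes[i]]
        with np.errstate(divide="ignore"):  # -inf is honest at pseudocount 0
            out[i] = np.log2((obs + pseudocount) / (exp + pseudocount))
    return out
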