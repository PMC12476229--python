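"""Embedding-level external validation: silhouette, CDbw, DBCV.

These metrics score how well a labeling (predicted clusters or annotated
classes) is supported by the geometry of a low-dimensional cell
embedding.  Silhouette contrasts mean within-group and nearest-other-
group distances; CDbw combines density-based cohesion, compactness and
separation computed from shrunken representative points; DBCV contrasts
the sparsest within-cluster density against the densest between-cluster
region via mutual-reachability minimum spanning trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import InputError, UndefinedMetricError
from .partitions import as_partition

__all__ = [
    "Embedding",
    "pairwise_distances",
    "silhouette_widths",
    "silhouette_summary",
    "select_representatives",
    "CDbwParams",
    "CDbwResult",
    "cdbw",
    "dbcv",
]


@dataclass(frozen=True)
class Embedding:
    """An n x d coordinate matrix with its distance metric."""

    X: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self):
        X = np.asarray(self.X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
            raise InputError("embedding must be an n x d matrix with n >= 2, d >= 1")
        if not np.isfinite(X).all():
            raise InputError("embedding contains non-finite values")
        if self.metric not in ("euclidean", "cosine"):
            raise InputError(f"unsupported metric {self.metric!r}")
        object.__setattr__(self, "X", X)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def as_embedding(X, metric: str = "euclidean") -> Embedding:
    if isinstance(X, Embedding):
        return X
    return Embedding(np.asarray(X, dtype=np.float64), metric=metric)


def pairwise_distances(emb: Embedding) -> np.ndarray:
    """Full n x n distance matrix under the embedding's metric.

    Cosine distances are computed by row-normalizing and using
    1 - inner product; rows of zero norm are left unnormalized.
    """
    if emb.metric == "cosine":
        norms = np.linalg.norm(emb.X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        Xn = emb.X / norms
        D = 1.0 - Xn @ Xn.T
        np.clip(D, 0.0, 2.0, out=D)
        np.fill_diagonal(D, 0.0)
        return D
    return squareform(pdist(emb.X))


def silhouette_widths(emb, labels, metric: str = "euclidean") -> np.ndarray:
    """Per-element silhouette width s = (b - a) / max(a, b).

    a is the mean distance to other members of the element's own group, b
    the mean distance to the nearest other group.  Members of singleton
    groups get s = 0 by convention.
    """
    emb = as_embedding(emb, metric)
    part = as_partition(labels)
    if part.n != emb.n:
        raise InputError("labels and embedding disagree on n")
    if part.K < 2:
        raise UndefinedMetricError("silhouette needs at least 2 groups")
    D = pairwise_distances(emb)
    codes = part.codes
    sizes = part.group_sizes()
    n, K = part.n, part.K
    # sum of distances from each point to each group
    group_sums = np.zeros((n, K))
    for k in range(K):
        group_sums[:, k] = D[:, codes == k].sum(axis=1)
    own = sizes[codes]
    intra = np.where(own > 1, group_sums[np.arange(n), codes] / np.maximum(own - 1, 1), 0.0)
    mean_other = group_sums / sizes[None, :]
    mean_other[np.arange(n), codes] = np.inf
    nearest = mean_other.min(axis=1)
    with np.errstate(invalid="ignore"):
        s = (nearest - intra) / np.maximum(nearest, intra)
    s[own == 1] = 0.0
    return s


def silhouette_summary(emb, labels, metric: str = "euclidean") -> dict:
    """Element widths plus group and dataset means."""
    part = as_partition(labels)
    s = silhouette_widths(emb, labels, metric)
    by_group = {tok: float(s[part.codes == k].mean())
                for k, tok in enumerate(part.categories)}
    return {"element": s, "group": by_group, "dataset": float(s.mean())}


def select_representatives(X: np.ndarray, k: int) -> np.ndarray:
    """Indices of k representative points chosen farthest-first.

    The first representative is the point nearest the centroid; each
    subsequent one maximizes its minimum distance to the chosen set
    (lowest index on ties).  k is clamped to the number of points.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if k > n:
        warnings.warn(f"requested {k} representatives from {n} points; clamping")
        k = n
    centroid = X.mean(axis=0)
    first = int(np.argmin(np.linalg.norm(X - centroid, axis=1)))
    chosen = [first]
    min_d = np.linalg.norm(X - X[first], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(min_d))
        chosen.append(nxt)
        min_d = np.minimum(min_d, np.linalg.norm(X - X[nxt], axis=1))
    return np.asarray(chosen, dtype=np.int64)


@dataclass
class CDbwParams:
    """Tunables of the CDbw index.

    n_reps: representative points per cluster (clamped to cluster size).
    shrink_factors: increasing sequence in (0, 1) moving representatives
    toward the cluster center.  The density-counting radius around a
    (shrunken) representative is the cluster standard deviation.
    """

    n_reps: int = 10
    shrink_factors: tuple = tuple(np.round(np.arange(0.1, 0.81, 0.1), 2))

    def __post_init__(self):
        s = np.asarray(self.shrink_factors, dtype=float)
        if self.n_reps < 2:
            raise InputError("n_reps must be >= 2")
        if not ((s > 0).all() and (s < 1).all() and (np.diff(s) > 0).all()):
            raise InputError("shrink factors must be strictly increasing within (0, 1)")


@dataclass
class CDbwResult:
    cohesion: float
    compactness: float
    separation: float
    cdbw: float
    intra_change: float
    per_pair: dict = field(default_factory=dict)


def _cluster_std(X: np.ndarray) -> float:
    """Root-mean-square per-dimension standard deviation of a cluster."""
    return float(np.sqrt(np.mean(np.var(X, axis=0))))


def cdbw(emb, labels, params: CDbwParams | None = None) -> CDbwResult:
    """Composed Density between and within clusters.

    cdbw = cohesion * compactness * separation, where compactness is the
    mean fraction of cluster members within one cluster-std of the
    shrunken representatives (over the shrink schedule), cohesion damps
    compactness by the density change across the schedule, and separation
    divides the mean nearest-cluster distance by 1 + the between-cluster
    density measured at midpoints of closest representative pairs.
    """
    params = params or CDbwParams()
    emb = as_embedding(emb)
    part = as_partition(labels)
    if part.n != emb.n:
        raise InputError("labels and embedding disagree on n")
    if part.K < 2:
        raise UndefinedMetricError("CDbw needs at least 2 clusters")
    X = emb.X
    K = part.K
    members = [np.flatnonzero(part.codes == k) for k in range(K)]
    reps = [members[k][select_representatives(X[members[k]], min(params.n_reps, len(members[k])))]
            for k in range(K)]
    stds = [_cluster_std(X[m]) for m in members]
    centroids = [X[m].mean(axis=0) for m in members]

    # ---- intra-cluster density over the shrink schedule
    shrink = np.asarray(params.shrink_factors, dtype=float)
    intra = np.zeros(len(shrink))
    for si, s in enumerate(shrink):
        dens_k = []
        for k in range(K):
            R = X[reps[k]] + s * (centroids[k] - X[reps[k]])
            rad = stds[k]
            if rad == 0:
                dens_k.append(0.0)
                continue
            cnt = (cdist(R, X[members[k]]) <= rad).sum(axis=1)
            dens_k.append(float(cnt.mean()) / len(members[k]))
        intra[si] = float(np.mean(dens_k))
    compactness = float(intra.mean())
    intra_change = float(np.abs(np.diff(intra)).mean()) if len(intra) > 1 else 0.0
    cohesion = compactness / (1.0 + intra_change)

    # ---- separation from closest representative pairs
    dist = np.full((K, K), np.inf)
    dens = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            Ri, Rj = X[reps[i]], X[reps[j]]
            Dij = cdist(Ri, Rj)
            # respective closest representatives: mutually nearest pairs
            pairs = [(u, int(np.argmin(Dij[u]))) for u in range(len(Ri))]
            pairs = [(u, v) for u, v in pairs if int(np.argmin(Dij[:, v])) == u]
            d_close = np.array([Dij[u, v] for u, v in pairs])
            dist[i, j] = dist[j, i] = float(d_close.mean())
            rad = 0.5 * (stds[i] + stds[j])
            both = np.concatenate([members[i], members[j]])
            if rad > 0:
                mids = np.array([(Ri[u] + Rj[v]) / 2.0 for u, v in pairs])
                cnt = (cdist(mids, X[both]) <= rad).sum(axis=1)
                dens[i, j] = dens[j, i] = float(cnt.mean()) / len(both)
    inter_dens = float(np.mean([dens[i][dist[i] < np.inf].max() if K > 1 else 0.0
                                for i in range(K)]))
    min_dist = np.array([dist[i][np.arange(K) != i].min() for i in range(K)])
    separation = float(min_dist.mean()) / (1.0 + inter_dens)

    return CDbwResult(cohesion=cohesion, compactness=compactness,
                      separation=separation, cdbw=cohesion * compactness * separation,
                      intra_change=intra_change)


def _core_distances(D: np.ndarray, d: int) -> np.ndarray:
    """All-points core distance within a cluster.

    Inverse-power mean of positive distances to the other members:
    core(o) = (mean over others of (1 / dist)^d) ^ (-1/d).  Zero
    distances (duplicate points) are excluded from the mean.
    """
    m = D.shape[0]
    core = np.zeros(m)
    for i in range(m):
        pos = D[i][(np.arange(m) != i) & (D[i] > 0)]
        if len(pos) == 0:
            core[i] = 0.0
        else:
            core[i] = float(np.mean((1.0 / pos) ** d) ** (-1.0 / d))
    return core


def dbcv(emb, labels) -> float:
    """Density-Based Clustering Validation index in [-1, 1].

    Per cluster, the density sparseness DSC is the largest edge of the
    mutual-reachability minimum spanning tree; the density separation
    DSPC to another cluster is the smallest cross-cluster mutual
    reachability.  The cluster validity (min DSPC - DSC) / max(min DSPC,
    DSC) is averaged over clusters weighted by size.
    """
    emb = as_embedding(emb)
    part = as_partition(labels)
    if part.n != emb.n:
        raise InputError("labels and embedding disagree on n")
    if part.K < 2:
        raise UndefinedMetricError("DBCV needs at least 2 clusters")
    sizes = part.group_sizes()
    if (sizes < 2).any():
        raise UndefinedMetricError("DBCV needs every cluster to have >= 2 points")
    X, d = emb.X, emb.d
    D = pairwise_distances(emb)
    K, n = part.K, part.n
    members = [np.flatnonzero(part.codes == k) for k in range(K)]
    core = np.zeros(n)
    dsc = np.zeros(K)
    for k in range(K):
        idx = members[k]
        Dk = D[np.ix_(idx, idx)]
        ck = _core_distances(Dk, d)
        core[idx] = ck
        if (Dk[np.triu_indices(len(idx), 1)] == 0).all():
            warnings.warn(f"cluster {part.categories[k]!r} is all duplicate points")
            dsc[k] = 0.0
            continue
        mreach = np.maximum(Dk, np.maximum(ck[:, None], ck[None, :]))
        np.fill_diagonal(mreach, 0.0)
        mst = minimum_spanning_tree(mreach).toarray()
        dsc[k] = float(mst.max())
    # min density separation to any other cluster
    vc = np.zeros(K)
    for k in range(K):
        idx = members[k]
        dspc = np.inf
        for j in range(K):
            if j == k:
                continue
            jdx = members[j]
            cross = np.maximum(D[np.ix_(idx, jdx)],
                               np.maximum(core[idx][:, None], core[jdx][None, :]))
            dspc = min(dspc, float(cross.min()))
        denom = max(dspc, dsc[k])
        vc[k] = 0.0 if denom == 0 else (dspc - dsc[k]) / denom
    return float((sizes / n * vc).sum())
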