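"""Spatially aware validation metrics for spatial domain detection.

Internal (ground-truth-free) smoothness scores — percentage of abnormal
spots (PAS), spatial chaos score (CHAOS), entropy-based local indicator
of spatial association (ELSA) — and external metrics that incorporate
spot coordinates: neighborhood-smoothed pair-counting metrics (ns*),
distance-weighted spatial RI/ARI, spot-wise pair concordance (SPC) and
its spatial variant, and neighborhood-smoothed set-matching accuracy.

Spatial neighborhoods use a radius rule: the radius is the median over
spots of the distance to the k-th nearest neighbor, and every spot within
that radius is a neighbor.  This keeps neighborhoods comparable at tissue
borders (border spots simply have fewer neighbors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._kernels import spatial_pair_sums
from .errors import InputError, UndefinedMetricError
from .fuzzy import FuzzyPartition, _block_agreement
from .partitions import as_partition, contingency, pair_counts, _comb2
from .partitions import _lexicographic_assignment

__all__ = [
    "SpatialContext",
    "spatial_neighbors",
    "smooth_labels",
    "ns_pair_metrics",
    "SpatialDecayParams",
    "spatial_ri_ari",
    "pas",
    "chaos",
    "ElsaParams",
    "elsa",
    "spc",
    "spatial_spc",
    "ns_accuracy",
]


@dataclass
class SpatialContext:
    """Coordinates plus the radius-defined neighbor structure."""

    coords: np.ndarray
    k: int
    radius: float
    neighbors: list  # list of int arrays, self excluded

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def isolated(self) -> np.ndarray:
        return np.array([len(nb) == 0 for nb in self.neighbors])


def spatial_neighbors(coords, k: int = 6) -> SpatialContext:
    """Build the radius neighborhood structure from 2D coordinates.

    radius = median over spots of the distance to the k-th nearest
    neighbor; the neighbors of a spot are all other spots within that
    radius.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise InputError("coords must be an n x 2 array")
    n = coords.shape[0]
    if n < 2 or k >= n:
        raise InputError("need n >= 2 and k < n")
    if np.allclose(coords, coords[0]):
        raise InputError("all coordinates identical; no spatial structure")
    tree = cKDTree(coords)
    dists, _ = tree.query(coords, k=k + 1)
    radius = float(np.median(dists[:, k]))
    pairs = tree.query_ball_tree(tree, r=radius * (1 + 1e-12))
    neighbors = [np.array([j for j in nb if j != i], dtype=np.int64)
                 for i, nb in enumerate(pairs)]
    return SpatialContext(coords=coords, k=k, radius=radius, neighbors=neighbors)


def smooth_labels(labels, ctx: SpatialContext, alpha_self: float = 0.5) -> FuzzyPartition:
    """Blend each spot's one-hot label with its neighborhood composition.

    w_i = alpha * onehot(label_i) + (1 - alpha) * neighbor label
    fractions.  The default alpha = 0.5 weighs spot and neighborhood
    equally.  Isolated spots keep their hard label.
    """
    if not 0.0 <= alpha_self <= 1.0:
        raise InputError("alpha_self must be in [0, 1]")
    part = as_partition(labels)
    if part.n != ctx.n:
        raise InputError("labels and spatial context disagree on n")
    W = np.zeros((part.n, part.K))
    isolated = 0
    for i, nb in enumerate(ctx.neighbors):
        ws = np.zeros(part.K)
        ws[part.codes[i]] = 1.0
        if len(nb) == 0:
            W[i] = ws
            isolated += 1
            continue
        wn = np.bincount(part.codes[nb], minlength=part.K) / len(nb)
        W[i] = alpha_self * ws + (1.0 - alpha_self) * wn
    if isolated:
        warnings.warn(f"{isolated} isolated spot(s) kept their hard label")
    return FuzzyPartition(W, part.categories)


def _fuzzy_hard_sums(t_codes, p_codes, R: np.ndarray | None, block: int = 1024):
    """Accumulate fuzzy-hard pair concordances in row blocks.

    For each unordered pair, C = 1 - min(|A_P - A_Q|, |A_P - A_R|) where
    A_P/A_Q are the 0/1 disagreements of the hard prediction/truth and
    A_R the fuzzy agreement of the smoothed truth (R=None uses hard truth
    only).  Returns total C, per-truth-class and per-cluster weighted
    sums (hard pair memberships), and per-spot row sums.
    """
    n = len(t_codes)
    K_t = int(t_codes.max()) + 1
    K_p = int(p_codes.max()) + 1
    total = 0.0
    num_c = np.zeros(K_t)
    den_c = np.zeros(K_t)
    num_h = np.zeros(K_p)
    den_h = np.zeros(K_p)
    row_sums = np.zeros(n)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        Ap = (p_codes[lo:hi, None] != p_codes[None, :]).astype(np.float64)
        Aq = (t_codes[lo:hi, None] != t_codes[None, :]).astype(np.float64)
        diff = np.abs(Ap - Aq)
        if R is not None:
            Ar = _block_agreement(R, slice(lo, hi), slice(0, n))
            diff = np.minimum(diff, np.abs(Ap - Ar))
        C = 1.0 - diff
        np.einsum("ii->i", C[:, lo:hi])[:] = 0.0  # no self pairs
        row_sums[lo:hi] += C.sum(axis=1)
        mask_upper = np.arange(n)[None, :] > np.arange(lo, hi)[:, None]
        Cu = np.where(mask_upper, C, 0.0)
        total += float(Cu.sum())
        same_t = (t_codes[lo:hi, None] == t_codes[None, :]) & mask_upper
        same_p = (p_codes[lo:hi, None] == p_codes[None, :]) & mask_upper
        for X in range(K_t):
            sel = same_t & (t_codes[lo:hi, None] == X)
            num_c[X] += float(C[sel].sum())
            den_c[X] += float(sel.sum())
        for Y in range(K_p):
            sel = same_p & (p_codes[lo:hi, None] == Y)
            num_h[Y] += float(C[sel].sum())
            den_h[Y] += float(sel.sum())
    return total, num_c, den_c, num_h, den_h, row_sums


def ns_pair_metrics(truth, pred, ctx: SpatialContext, alpha_self: float = 0.5,
                    n_perm: int = 100, seed: int = 0, adjusted: bool = True) -> dict:
    """Neighborhood-smoothed pair-counting metrics (fuzzy-hard mode).

    The prediction stays hard; the ground truth is used both hard and
    smoothed over the spatial neighborhood, and each pair takes the more
    favorable concordance of the two, so a prediction identical to the
    hard truth still scores 1.  Wallace pair memberships come from the
    hard labels.  Adjusted versions (nsARI, nsAWH, nsAWC) subtract a
    permutation null of the predicted labels.
    """
    t = as_partition(truth)
    p = as_partition(pred)
    if t.n != p.n or t.n != ctx.n:
        raise InputError("truth, prediction and spatial context disagree on n")
    R = smooth_labels(t, ctx, alpha_self).W
    n_pairs = t.n * (t.n - 1) / 2

    def compute(p_codes):
        total, num_c, den_c, num_h, den_h, _ = _fuzzy_hard_sums(t.codes, p_codes, R)
        ri = total / n_pairs
        wc = num_c.sum() / den_c.sum() if den_c.sum() > 0 else np.nan
        wh = num_h.sum() / den_h.sum() if den_h.sum() > 0 else np.nan
        return ri, wc, wh

    ri, wc, wh = compute(p.codes)
    out = {"nsRI": ri, "nsWC": wc, "nsWH": wh}
    if adjusted:
        rng = np.random.default_rng(seed)
        null = np.empty((n_perm, 3))
        for i in range(n_perm):
            null[i] = compute(p.codes[rng.permutation(t.n)])
        e_ri, e_wc, e_wh = null.mean(axis=0)
        for name, m, e in (("nsARI", ri, e_ri), ("nsAWC", wc, e_wc), ("nsAWH", wh, e_wh)):
            out[name] = np.nan if e >= 1.0 else (m - e) / (1.0 - e)
    return out


@dataclass
class SpatialDecayParams:
    """Distance weighting of discordant pairs for spatial RI/ARI.

    mode='original' uses f(d) = a*exp(-d^2) for wrongly grouped pairs and
    h(d) = a*(1 - exp(-d^2)) for wrongly separated ones, with a = 0.8.
    mode='modified' (default) uses steeper exponential decays
    f(d) = a*exp(-beta_f*d), h(d) = a*(1 - exp(-beta_h*d)) with
    beta_f = 4 and beta_h = 1.  Distances are euclidean on per-axis
    min-max normalized coordinates.
    """

    alpha: float = 0.8
    beta_f: float = 4.0
    beta_h: float = 1.0
    mode: str = "modified"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise InputError("alpha must be in [0, 1]")
        if self.beta_f <= 0 or self.beta_h <= 0:
            raise InputError("decay rates must be positive")
        if self.mode not in ("original", "modified"):
            raise InputError("mode must be 'original' or 'modified'")

    def f(self, d):
        d = np.asarray(d, dtype=float)
        return self.alpha * (np.exp(-self.beta_f * d) if self.mode == "modified"
                             else np.exp(-d ** 2))

    def h(self, d):
        d = np.asarray(d, dtype=float)
        return self.alpha * (1 - (np.exp(-self.beta_h * d) if self.mode == "modified"
                                  else np.exp(-d ** 2)))


def normalize_coords(coords: np.ndarray) -> np.ndarray:
    """Per-axis min-max scaling to [0, 1] (constant axes map to 0)."""
    coords = np.asarray(coords, dtype=np.float64)
    lo = coords.min(axis=0)
    rng = coords.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return (coords - lo) / rng


def spatial_ri_ari(truth, pred, coords, params: SpatialDecayParams | None = None,
                   adjusted: bool = True) -> dict:
    """Distance-weighted spatial Rand index and its chance-adjusted
    version.

    Concordant pairs score 1; wrongly grouped pairs score f(d) and
    wrongly separated pairs h(d).  The pair sum is streamed in O(1)
    memory, so the metric scales to 10^5+ spots.  spatialARI subtracts
    the exact expectation of the score under the permutation null of the
    predicted labels: a uniformly permuted prediction merges every pair
    with the same probability q = sum_c m_c(m_c - 1) / (n(n - 1)), so
    E = mean over pairs of q + (1-q) h(d) (same-class pairs) or
    (1-q) + q f(d) (different-class pairs).
    """
    params = params or SpatialDecayParams()
    t = as_partition(truth)
    p = as_partition(pred)
    xy = normalize_coords(coords)
    if t.n != p.n or t.n != xy.shape[0]:
        raise InputError("truth, prediction and coords disagree on n")
    x, y = np.ascontiguousarray(xy[:, 0]), np.ascontiguousarray(xy[:, 1])
    n = t.n
    n_pairs = n * (n - 1) / 2
    modified = params.mode == "modified"
    score_sum, n_same_t, h_same_t, f_diff_t = spatial_pair_sums(
        t.codes, p.codes, x, y, params.alpha, params.beta_f, params.beta_h, modified)
    ri = float(score_sum / n_pairs)
    out = {"spatialRI": ri}
    if adjusted:
        m_c = np.bincount(p.codes).astype(np.float64)
        q = float((m_c * (m_c - 1)).sum()) / (n * (n - 1))
        n_diff_t = n_pairs - n_same_t
        e = (n_same_t * q + h_same_t * (1 - q)
             + n_diff_t * (1 - q) + f_diff_t * q) / n_pairs
        out["spatialARI"] = np.nan if e >= 1.0 else (ri - e) / (1.0 - e)
    return out


def pas(labels, ctx: SpatialContext) -> dict:
    """Percentage of abnormal spots.

    A spot is abnormal when a strict majority of its spatial neighbors
    carries a different domain label.  Isolated spots are excluded.
    """
    part = as_partition(labels)
    if part.n != ctx.n:
        raise InputError("labels and spatial context disagree on n")
    abnormal = np.zeros(part.n, dtype=bool)
    scored = np.zeros(part.n, dtype=bool)
    for i, nb in enumerate(ctx.neighbors):
        if len(nb) == 0:
            continue
        scored[i] = True
        n_diff = int((part.codes[nb] != part.codes[i]).sum())
        abnormal[i] = n_diff > len(nb) / 2
    if not scored.all():
        warnings.warn(f"{int((~scored).sum())} isolated spot(s) excluded from PAS")
    if not scored.any():
        raise UndefinedMetricError("no spot has spatial neighbors")
    per_domain = {}
    for k, tok in enumerate(part.categories):
        sel = (part.codes == k) & scored
        per_domain[tok] = float(abnormal[sel].mean()) if sel.any() else np.nan
    return {"dataset": float(abnormal[scored].mean()),
            "domain": per_domain, "abnormal": abnormal, "scored": scored}


def chaos(labels, coords) -> dict:
    """Spatial chaos score: per domain, the mean edge length of the
    1-nearest-neighbor graph among that domain's spots (on min-max
    normalized coordinates), averaged across domains.  Lower is smoother;
    singleton domains are skipped."""
    part = as_partition(labels)
    xy = normalize_coords(coords)
    if part.n != xy.shape[0]:
        raise InputError("labels and coords disagree on n")
    per_domain = {}
    for k, tok in enumerate(part.categories):
        idx = np.flatnonzero(part.codes == k)
        if len(idx) < 2:
            warnings.warn(f"domain {tok!r} has fewer than 2 spots; skipped in CHAOS")
            continue
        tree = cKDTree(xy[idx])
        d, _ = tree.query(xy[idx], k=2)
        per_domain[tok] = float(d[:, 1].mean())
    if not per_domain:
        raise UndefinedMetricError("no domain has at least 2 spots")
    return {"dataset": float(np.mean(list(per_domain.values()))), "domain": per_domain}


@dataclass
class ElsaParams:
    """ELSA configuration.

    dissimilarity: 'binary' (d = 1 between different categories),
    'rank' (absolute difference of category ranks in first-appearance
    order), or an explicit symmetric matrix with zero diagonal.
    include_self: whether the focal spot joins its neighborhood's
    category distribution (default False).
    """

    dissimilarity: object = "binary"
    include_self: bool = False


def elsa(labels, ctx: SpatialContext, params: ElsaParams | None = None) -> dict:
    """Entropy-based local indicator of spatial association, per spot.

    E_i = E_ai * E_ci: E_ai is the mean category dissimilarity between
    the spot and its neighbors scaled by the maximum dissimilarity; E_ci
    is the Shannon entropy of the neighborhood's category mix normalized
    by log2 of the attainable category count.  0 = locally homogeneous.
    """
    params = params or ElsaParams()
    part = as_partition(labels)
    if part.n != ctx.n:
        raise InputError("labels and spatial context disagree on n")
    m = part.K
    if m < 2:
        warnings.warn("single global category; all ELSA scores are 0")
        return {"element": np.zeros(part.n), "dataset": 0.0}
    if isinstance(params.dissimilarity, str):
        if params.dissimilarity == "binary":
            dmat = 1.0 - np.eye(m)
        elif params.dissimilarity == "rank":
            ranks = np.arange(m, dtype=float)
            dmat = np.abs(ranks[:, None] - ranks[None, :])
        else:
            raise InputError(f"unknown dissimilarity {params.dissimilarity!r}")
    else:
        dmat = np.asarray(params.dissimilarity, dtype=float)
        if dmat.shape != (m, m) or not np.allclose(dmat, dmat.T) or np.diag(dmat).any():
            raise InputError("dissimilarity matrix must be symmetric with zero diagonal")
    maxd = dmat.max()
    scores = np.full(part.n, np.nan)
    for i, nb in enumerate(ctx.neighbors):
        if len(nb) == 0:
            continue
        e_ai = float(dmat[part.codes[i], part.codes[nb]].mean()) / maxd
        pool = np.append(nb, i) if params.include_self else nb
        counts = np.bincount(part.codes[pool], minlength=m)
        p = counts[counts > 0] / counts.sum()
        m_i = min(m, len(pool))
        if m_i < 2:
            e_ci = 0.0
        else:
            e_ci = float(-(p * np.log2(p)).sum()) / np.log2(m_i)
        scores[i] = e_ai * e_ci
    valid = ~np.isnan(scores)
    return {"element": scores, "dataset": float(scores[valid].mean())}


def spc(truth, pred, exclude_negatives: bool = False) -> np.ndarray:
    """Spot-wise pair concordance: per spot, the fraction of its pairs
    that are concordant between prediction and truth.

    The dataset mean equals the Rand index.  All spots sharing one
    (class, cluster) combination get the same value.  With
    exclude_negatives=True, pairs separated in both partitions are
    dropped from the denominator.
    """
    t = as_partition(truth)
    p = as_partition(pred)
    if t.n != p.n:
        raise InputError("partitions disagree on n")
    if t.n < 2:
        raise UndefinedMetricError("SPC needs at least 2 elements")
    ct = contingency(t, p).counts.astype(np.float64)
    a_g = ct.sum(axis=1)
    b_p = ct.sum(axis=0)
    n = t.n
    n_gp = ct[t.codes, p.codes]
    same_both = n_gp - 1.0
    diff_both = n - a_g[t.codes] - b_p[p.codes] + n_gp
    if exclude_negatives:
        denom = (n - 1.0) - diff_both
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, same_both / denom, np.nan)
        return out
    return (same_both + diff_both) / (n - 1.0)


def spatial_spc(truth, pred, ctx: SpatialContext, alpha_self: float = 0.5) -> np.ndarray:
    """Per-spot mean fuzzy-hard pair concordance (spatial SPC).

    Uses the same fuzzy-hard concordance as the ns* metrics: each pair
    scores the better of its agreement with the hard and the
    neighborhood-smoothed ground truth.
    """
    t = as_partition(truth)
    p = as_partition(pred)
    if t.n != p.n or t.n != ctx.n:
        raise InputError("truth, prediction and spatial context disagree on n")
    R = smooth_labels(t, ctx, alpha_self).W
    _, _, _, _, _, row_sums = _fuzzy_hard_sums(t.codes, p.codes, R)
    return row_sums / (t.n - 1.0)


def ns_accuracy(truth, pred, ctx: SpatialContext, match: str = "auto",
                use_pred_neighbors: bool = False) -> float:
    """Neighborhood-smoothed set-matching accuracy.

    Predicted clusters are matched one-to-one to classes (Hungarian
    matching, unless the label vocabularies already coincide).  Correct
    spots contribute 1; a misclassified spot contributes the fraction of
    its spatial neighbors whose true class equals the spot's matched
    predicted class (so boundary errors assigned to the adjacent domain
    are tolerated).  use_pred_neighbors scores against the neighbors'
    predicted classes instead.
    """
    t = as_partition(truth)
    p = as_partition(pred)
    if t.n != p.n or t.n != ctx.n:
        raise InputError("truth, prediction and spatial context disagree on n")
    shared = set(p.categories) <= set(t.categories)
    if match == "identity" or (match == "auto" and shared):
        tok_to_truth_code = {tok: i for i, tok in enumerate(t.categories)}
        pred_class = np.array([tok_to_truth_code[p.categories[c]] for c in p.codes])
    else:
        ct = contingency(t, p)
        assignment = _lexicographic_assignment(np.asarray(ct.counts, dtype=np.int64))
        mapped = np.full(p.K, -1, dtype=np.int64)
        for j, i in assignment.items():
            mapped[j] = i
        pred_class = mapped[p.codes]
    ref_codes = pred_class if use_pred_neighbors else t.codes
    total = 0.0
    isolated_errors = 0
    for i in range(t.n):
        if pred_class[i] == t.codes[i]:
            total += 1.0
            continue
        nb = ctx.neighbors[i]
        if len(nb) == 0 or pred_class[i] < 0:
            isolated_errors += len(nb) == 0
            continue
        total += float((ref_codes[nb] == pred_class[i]).mean())
    if isolated_errors:
        warnings.warn(f"{isolated_errors} misclassified isolated spot(s) contributed 0")
    return total / t.n
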