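"""Fuzzy pair-counting concordance metrics.

Two soft partitions (row-stochastic membership matrices) are compared
through the pairwise agreement A_ij = ||w_i - w_j||_1 / 2: the degree to
which elements i and j are separated within one partition.  The
concordance of a pair across partitions is C_ij = 1 - |A_ij^P - A_ij^Q|.
Averaging C over pairs yields the normalized degree of concordance (NDC),
a fuzzy generalization of the Rand index; permutation-based chance
adjustment of NDC yields the adjusted concordance index (ACI), a fuzzy
ARI.  Fuzzy Wallace indices weight the pair concordances by the pair's
membership in each class (via a t-norm), generalizing the crisp Wallace
homogeneity and completeness.

All pair sums are computed in fixed-size row blocks, so memory stays
O(block * n) rather than O(n^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import InputError, UndefinedMetricError
from .partitions import HardPartition, as_partition, contingency, pair_counts

__all__ = [
    "FuzzyPartition",
    "as_fuzzy",
    "pair_agreement",
    "ndc",
    "ndc_subsampled",
    "aci",
    "fuzzy_wallace",
    "chance_adjust_permutation",
    "PermutationConfig",
]

_BLOCK = 1024

T_NORMS: dict[str, Callable] = {
    "product": lambda u, v: u * v,
    "min": np.minimum,
}


@dataclass(frozen=True)
class FuzzyPartition:
    """An n x m row-stochastic membership matrix.

    Hard partitions embed as one-hot rows; when every row is one-hot the
    integer codes are kept alongside to enable exact fast paths.
    """

    W: np.ndarray
    categories: tuple
    hard_codes: np.ndarray | None = None

    def __post_init__(self):
        W = np.asarray(self.W, dtype=np.float64)
        if W.ndim != 2:
            raise InputError("membership matrix must be 2D")
        if (W < -1e-12).any():
            raise InputError("negative membership values")
        rs = W.sum(axis=1)
        bad = np.flatnonzero(np.abs(rs - 1.0) > 1e-9)
        if len(bad):
            raise InputError(f"membership rows do not sum to 1 (first offending row: {bad[0]})")
        object.__setattr__(self, "W", W)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> int:
        return self.W.shape[1]

    @property
    def is_hard(self) -> bool:
        return self.hard_codes is not None

    def permuted(self, order: np.ndarray) -> "FuzzyPartition":
        codes = self.hard_codes[order] if self.hard_codes is not None else None
        return FuzzyPartition(self.W[order], self.categories, codes)


def as_fuzzy(x) -> FuzzyPartition:
    """Coerce labels / HardPartition / membership matrix to FuzzyPartition."""
    if isinstance(x, FuzzyPartition):
        return x
    if isinstance(x, np.ndarray) and x.ndim == 2 and x.dtype.kind == "f":
        W = x
        onehot = ((W == 1.0).sum(axis=1) == 1) & (np.abs(W.sum(axis=1) - 1) < 1e-12)
        codes = W.argmax(axis=1).astype(np.int64) if onehot.all() else None
        return FuzzyPartition(W, tuple(range(W.shape[1])), codes)
    part = as_partition(x)
    return FuzzyPartition(part.one_hot(), part.categories, part.codes.copy())


def pair_agreement(fp: FuzzyPartition) -> np.ndarray:
    """Full n x n within-partition agreement matrix A_ij = ||w_i - w_j||_1 / 2.

    Intended for small n; the metrics below never materialize it.
    """
    from scipy.spatial.distance import pdist, squareform
    return squareform(pdist(fp.W, metric="cityblock")) / 2.0


def _block_agreement(W: np.ndarray, rows: slice, cols: slice) -> np.ndarray:
    return 0.5 * np.abs(W[rows, None, :] - W[None, cols, :]).sum(axis=2)


def ndc(truth, pred, block: int = _BLOCK) -> float:
    """Normalized degree of concordance: mean pair concordance in [0, 1].

    Reduces exactly to the Rand index when both inputs are hard.
    """
    P, Q = as_fuzzy(pred), as_fuzzy(truth)
    if P.n != Q.n:
        raise InputError("partitions disagree on n")
    if P.n < 2:
        raise UndefinedMetricError("NDC needs at least 2 elements")
    if P.is_hard and Q.is_hard:
        pc = pair_counts(contingency(Q.hard_codes, P.hard_codes))
        return (pc.a + pc.d) / pc.n_pairs
    n = P.n
    total = 0.0
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        Ap = _block_agreement(P.W, slice(lo, hi), slice(lo, n))
        Aq = _block_agreement(Q.W, slice(lo, hi), slice(lo, n))
        C = 1.0 - np.abs(Ap - Aq)
        # C covers rows lo..hi vs cols lo..n; keep strictly upper pairs
        mask = np.arange(lo, n)[None, :] > np.arange(lo, hi)[:, None]
        total += float(C[mask].sum())
    return total / (n * (n - 1) / 2)


def ndc_subsampled(truth, pred, n_sample: int = 100_000, seed: int = 0) -> tuple[float, float]:
    """Approximate NDC from a seeded random sample of element pairs.

    Returns (estimate, standard error).  Intended for n where the exact
    O(n^2) pair sum is too expensive; clearly approximate — the exact
    :func:`ndc` is preferred whenever feasible.
    """
    P, Q = as_fuzzy(pred), as_fuzzy(truth)
    if P.n != Q.n:
        raise InputError("partitions disagree on n")
    if P.n < 2:
        raise UndefinedMetricError("NDC needs at least 2 elements")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, P.n, size=n_sample)
    j = rng.integers(0, P.n - 1, size=n_sample)
    j = np.where(j >= i, j + 1, j)  # uniform over ordered pairs, i != j
    ap = 0.5 * np.abs(P.W[i] - P.W[j]).sum(axis=1)
    aq = 0.5 * np.abs(Q.W[i] - Q.W[j]).sum(axis=1)
    c = 1.0 - np.abs(ap - aq)
    return float(c.mean()), float(c.std(ddof=1) / np.sqrt(n_sample))


def fuzzy_wallace(truth, pred, tnorm: str = "product", block: int = _BLOCK) -> dict:
    """Fuzzy Wallace completeness and homogeneity.

    Completeness of a truth class X averages the pair concordances C_ij
    weighted by the pair's membership in X (t-norm of the two elements'
    class-X memberships); homogeneity does the same over the prediction's
    clusters.  Returns per-class values and pair-mass-weighted aggregates.
    Classes with zero pair mass are omitted.
    """
    if tnorm not in T_NORMS:
        raise InputError(f"unknown t-norm {tnorm!r}")
    tn = T_NORMS[tnorm]
    P, Q = as_fuzzy(pred), as_fuzzy(truth)
    if P.n != Q.n:
        raise InputError("partitions disagree on n")
    n = P.n
    num_c = np.zeros(Q.m)
    den_c = np.zeros(Q.m)
    num_h = np.zeros(P.m)
    den_h = np.zeros(P.m)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        Ap = _block_agreement(P.W, slice(lo, hi), slice(lo, n))
        Aq = _block_agreement(Q.W, slice(lo, hi), slice(lo, n))
        C = 1.0 - np.abs(Ap - Aq)
        mask = np.arange(lo, n)[None, :] > np.arange(lo, hi)[:, None]
        Cm = np.where(mask, C, 0.0)
        for X in range(Q.m):
            m_pair = tn(Q.W[lo:hi, X][:, None], Q.W[lo:, X][None, :])
            m_pair = np.where(mask, m_pair, 0.0)
            num_c[X] += float((m_pair * Cm).sum())
            den_c[X] += float(m_pair.sum())
        for Y in range(P.m):
            m_pair = tn(P.W[lo:hi, Y][:, None], P.W[lo:, Y][None, :])
            m_pair = np.where(mask, m_pair, 0.0)
            num_h[Y] += float((m_pair * Cm).sum())
            den_h[Y] += float(m_pair.sum())
    import warnings as _w
    wc = {}
    for X, tok in enumerate(Q.categories):
        if den_c[X] > 0:
            wc[tok] = num_c[X] / den_c[X]
        else:
            _w.warn(f"truth class {tok!r} has zero pair mass; omitted")
    wh = {}
    for Y, tok in enumerate(P.categories):
        if den_h[Y] > 0:
            wh[tok] = num_h[Y] / den_h[Y]
        else:
            _w.warn(f"predicted cluster {tok!r} has zero pair mass; omitted")
    return {
        "WC": wc,
        "WH": wh,
        "WC_overall": float(num_c.sum() / den_c.sum()) if den_c.sum() > 0 else np.nan,
        "WH_overall": float(num_h.sum() / den_h.sum()) if den_h.sum() > 0 else np.nan,
    }


@dataclass
class PermutationConfig:
    """Permutation scheme for chance adjustment.

    n_perm seeded permutations of the membership rows; permute selects
    whether the prediction (default), the truth, or both are shuffled.
    """

    n_perm: int = 100
    seed: int = 0
    permute: str = "pred"
    tnorm: str = "product"

    def __post_init__(self):
        if self.n_perm < 1:
            raise InputError("n_perm must be >= 1")
        if self.permute not in ("pred", "truth", "both"):
            raise InputError("permute must be 'pred', 'truth' or 'both'")


def chance_adjust_permutation(metric_fn, truth, pred,
                              cfg: PermutationConfig | None = None) -> float:
    """Adjust a pair metric for chance: (M - E) / (1 - E).

    E is the metric's mean over seeded row permutations of the predicted
    (and/or true) memberships.
    """
    cfg = cfg or PermutationConfig()
    P, Q = as_fuzzy(pred), as_fuzzy(truth)
    m = metric_fn(Q, P)
    rng = np.random.default_rng(cfg.seed)
    vals = np.empty(cfg.n_perm)
    for t in range(cfg.n_perm):
        Pp = P.permuted(rng.permutation(P.n)) if cfg.permute in ("pred", "both") else P
        Qp = Q.permuted(rng.permutation(Q.n)) if cfg.permute in ("truth", "both") else Q
        vals[t] = metric_fn(Qp, Pp)
    e = float(vals.mean())
    if e >= 1.0:
        raise UndefinedMetricError("chance expectation reached 1; adjustment undefined")
    return (m - e) / (1.0 - e)


def aci(truth, pred, cfg: PermutationConfig | None = None) -> float:
    """Adjusted concordance index: permutation-chance-adjusted NDC."""
    return chance_adjust_permutation(ndc, truth, pred, cfg)


def fuzzy_adjusted_wallace(truth, pred, cfg: PermutationConfig | None = None) -> dict:
    """Permutation-adjusted overall fuzzy Wallace indices (AWC, AWH)."""
    cfg = cfg or PermutationConfig()

    def _wc(Q, P):
        return fuzzy_wallace(Q, P, tnorm=cfg.tnorm)["WC_overall"]

    def _wh(Q, P):
        return fuzzy_wallace(Q, P, tnorm=cfg.tnorm)["WH_overall"]

    return {
        "AWC": chance_adjust_permutation(_wc, truth, pred, cfg),
        "AWH": chance_adjust_permutation(_wh, truth, pred, cfg),
    }
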