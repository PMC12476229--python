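"""Partition-based external validation metrics.

Pair-counting (RI, Wallace homogeneity/completeness and their
chance-adjusted versions, ARI, NCR), information-theoretic (MI, entropy
homogeneity/completeness, V-measure, NMI, AMI) and set-matching (weighted
F-measure, matching accuracy) measures comparing a predicted partition P
against a ground-truth partition G.

Chance adjustment throughout follows the (M - E[M]) / (1 - E[M]) scheme,
with expectations under the generalized hypergeometric (permutation)
model where a closed form exists, and under seeded label permutation for
NCR where it does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError
from .partitions import (ContingencyTable, PairCounts, as_partition,
                         contingency, pair_counts, set_matching_accuracy,
                         _comb2)

__all__ = [
    "rand_index",
    "wallace_homogeneity",
    "wallace_completeness",
    "adjusted_rand_index",
    "adjusted_wallace",
    "ncr",
    "entropy_suite",
    "EntropyContext",
    "weighted_f_measure",
    "set_matching_accuracy",
    "partition_report",
]


def rand_index(pc: PairCounts) -> float:
    """(a + d) / (n choose 2): fraction of concordant element pairs."""
    if pc.n < 2:
        raise UndefinedMetricError("Rand index needs at least 2 elements")
    return (pc.a + pc.d) / pc.n_pairs


def wallace_homogeneity(pc: PairCounts) -> float:
    """a / (a + c): of the pairs merged by P, the fraction also merged in G."""
    if pc.a + pc.c == 0:
        raise UndefinedMetricError(
            "Wallace homogeneity undefined: the prediction is all singletons "
            "(no pair is in the same cluster)")
    return pc.a / (pc.a + pc.c)


def wallace_completeness(pc: PairCounts) -> float:
    """a / (a + b): of the pairs merged by G, the fraction also merged in P."""
    if pc.a + pc.b == 0:
        raise UndefinedMetricError(
            "Wallace completeness undefined: the ground truth is all singletons "
            "(no pair is in the same class)")
    return pc.a / (pc.a + pc.b)


def adjusted_rand_index(pc: PairCounts) -> float:
    """Chance-adjusted Rand index, 2(ad - bc) / ((a+b)(b+d) + (a+c)(c+d)).

    Two identical partitions score 1 (including the case where both are a
    single group); independent partitions score ~0.
    """
    if pc.n < 2:
        raise UndefinedMetricError("ARI needs at least 2 elements")
    a, b, c, d = pc.a, pc.b, pc.c, pc.d
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        if b == 0 and c == 0:
            return 1.0
        raise UndefinedMetricError("ARI denominator is zero for non-identical partitions")
    return 2.0 * (a * d - b * c) / denom


def _expected_same_pred(ct: ContingencyTable) -> float:
    """P(random pair in same predicted cluster) = sum C(b_j,2) / C(n,2)."""
    n_pairs = ct.n * (ct.n - 1) // 2
    return float(_comb2(ct.col_sums).sum()) / n_pairs


def _expected_same_truth(ct: ContingencyTable) -> float:
    n_pairs = ct.n * (ct.n - 1) // 2
    return float(_comb2(ct.row_sums).sum()) / n_pairs


def adjusted_wallace(pc: PairCounts, ct: ContingencyTable) -> tuple[float, float]:
    """(AWH, AWC): Wallace indices adjusted under the hypergeometric model.

    E[WH] is the probability that a random pair falls in the same class of
    G, and symmetrically E[WC] uses the cluster sizes of P.
    """
    wh = wallace_homogeneity(pc)
    wc = wallace_completeness(pc)
    e_wh = _expected_same_truth(ct)
    e_wc = _expected_same_pred(ct)
    if e_wh >= 1.0 or e_wc >= 1.0:
        raise UndefinedMetricError(
            "adjusted Wallace undefined: one partition is a single group, "
            "its expected Wallace index is 1")
    awh = (wh - e_wh) / (1.0 - e_wh)
    awc = (wc - e_wc) / (1.0 - e_wc)
    return awh, awc


def _ncr_raw(ct: ContingencyTable) -> float:
    """Unadjusted per-class normalized concordance, averaged over classes."""
    counts = np.asarray(ct.counts, dtype=np.float64)
    n = ct.n
    a_i = ct.row_sums.astype(np.float64)
    b_j = ct.col_sums.astype(np.float64)
    # within-class pairs correctly merged by P
    correct_within = (counts * (counts - 1) / 2).sum(axis=1)
    total_within = a_i * (a_i - 1) / 2
    # cross (class X, non-X) pairs correctly separated by P
    merged_cross = (counts * (b_j[None, :] - counts)).sum(axis=1)
    total_cross = a_i * (n - a_i)
    correct_cross = total_cross - merged_cross
    denom = total_within + total_cross
    return float(np.mean((correct_within + correct_cross) / denom))


def ncr(ct: ContingencyTable, n_permutations: int = 200, seed: int = 0) -> float:
    """Normalized class-size Rand index.

    Per ground-truth class, concordant pairs involving that class are
    normalized by the maximum attainable concordance for the class; the
    unweighted mean over classes is then chance-adjusted as
    (M - E) / (1 - E), with E estimated by seeded permutation of the
    predicted labels.  Because each class is normalized separately, an
    error costs more in a small class than in a large one.
    """
    if ct.counts.shape[0] < 2:
        raise UndefinedMetricError("NCR needs at least 2 ground-truth classes")
    m = _ncr_raw(ct)
    rng = np.random.default_rng(seed)
    truth_codes = np.repeat(np.arange(ct.counts.shape[0]), ct.row_sums)
    pred_codes = np.concatenate(
        [np.repeat(np.arange(ct.counts.shape[1]), ct.counts[i]) for i in range(ct.counts.shape[0])])
    exps = np.empty(n_permutations)
    K_G, K_P = ct.counts.shape
    for t in range(n_permutations):
        perm = rng.permutation(pred_codes)
        cnt = np.zeros((K_G, K_P), dtype=np.int64)
        np.add.at(cnt, (truth_codes, perm), 1)
        exps[t] = _ncr_raw(ContingencyTable(cnt, ct.row_labels, ct.col_labels))
    e = float(exps.mean())
    if e >= 1.0:
        raise UndefinedMetricError("NCR chance expectation is 1")
    return (m - e) / (1.0 - e)


@dataclass
class EntropyContext:
    """Configuration for the information-theoretic metrics.

    base: logarithm base for entropies (ratios are base-invariant, MI is
    reported in this base).  beta: homogeneity-vs-completeness weight in
    the V-measure.  nmi_norm: 'arithmetic' | 'geometric' | 'max'.
    """

    base: float = 2.0
    beta: float = 1.0
    nmi_norm: str = "arithmetic"


def _entropy(p: np.ndarray, base: float) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / math.log(base))


def expected_mutual_information(ct: ContingencyTable, base: float = 2.0) -> float:
    """E[MI] between G and a random partition with P's group sizes.

    Expectation under the generalized hypergeometric model: each cell
    count n_ij follows a hypergeometric law given the margins; the sum of
    (n_ij/n) log(n n_ij / (a_i b_j)) is averaged over it.
    """
    n = ct.n
    a = ct.row_sums.astype(np.int64)
    b = ct.col_sums.astype(np.int64)
    log = math.log
    # log-factorials 0..n
    lgamma = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, n + 1)))))
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            # hypergeometric log-pmf at nij
            log_pmf = (lgamma[ai] + lgamma[bj] + lgamma[n - ai] + lgamma[n - bj]
                       - lgamma[n] - lgamma[nij] - lgamma[ai - nij]
                       - lgamma[bj - nij] - lgamma[n - ai - bj + nij])
            term = (nij / n) * (np.log(n * nij) - log(ai * bj))
            emi += float((term * np.exp(log_pmf)).sum())
    return emi / log(base)


def entropy_suite(ct: ContingencyTable, cfg: EntropyContext | None = None) -> dict:
    """MI, EH, EC, V-measure, NMI and AMI from one contingency table."""
    cfg = cfg or EntropyContext()
    n = ct.n
    p_joint = ct.counts.ravel() / n
    h_g = _entropy(ct.row_sums / n, cfg.base)
    h_p = _entropy(ct.col_sums / n, cfg.base)
    h_gp = _entropy(p_joint, cfg.base)
    mi = max(0.0, h_g + h_p - h_gp)
    h_g_given_p = h_gp - h_p
    h_p_given_g = h_gp - h_g

    eh = 1.0 if h_g == 0 else 1.0 - h_g_given_p / h_g
    ec = 1.0 if h_p == 0 else 1.0 - h_p_given_g / h_p
    beta = cfg.beta
    vm = 0.0 if (beta * eh + ec) == 0 else (1 + beta) * eh * ec / (beta * eh + ec)

    if h_g == 0 and h_p == 0:
        nmi = 1.0
    else:
        if cfg.nmi_norm == "arithmetic":
            norm = (h_g + h_p) / 2.0
        elif cfg.nmi_norm == "geometric":
            norm = math.sqrt(h_g * h_p)
        elif cfg.nmi_norm == "max":
            norm = max(h_g, h_p)
        else:
            raise ValueError(f"unknown NMI normalization {cfg.nmi_norm!r}")
        nmi = 0.0 if norm == 0 else mi / norm

    if h_g == 0 and h_p == 0:
        ami = 1.0
    else:
        emi = expected_mutual_information(ct, cfg.base)
        norm = (h_g + h_p) / 2.0
        denom = norm - emi
        ami = 0.0 if abs(denom) < 1e-15 else (mi - emi) / denom
    return {"MI": mi, "EH": eh, "EC": ec, "VM": vm, "NMI": nmi, "AMI": ami}


def weighted_f_measure(ct: ContingencyTable) -> float:
    """Class-size-weighted best F1 over clusters.

    For each ground-truth class the best harmonic mean of precision
    (n_ij / cluster size) and recall (n_ij / class size) over clusters is
    taken; classes are weighted by their relative size.
    """
    counts = np.asarray(ct.counts, dtype=np.float64)
    a_i = ct.row_sums.astype(np.float64)
    b_j = ct.col_sums.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(b_j[None, :] > 0, counts / b_j[None, :], 0.0)
        recall = counts / a_i[:, None]
        f = np.where(precision + recall > 0,
                     2 * precision * recall / (precision + recall), 0.0)
    best_f = f.max(axis=1)
    return float((a_i / ct.n * best_f).sum())


def partition_report(truth, pred, metrics=None, *, base: float = 2.0,
                     beta: float = 1.0, nmi_norm: str = "arithmetic",
                     n_permutations: int = 200, seed: int = 0) -> dict:
    """Compute a selection of partition metrics in one pass.

    metrics: iterable of names among {RI, WH, WC, ARI, AWH, AWC, NCR, MI,
    EH, EC, VM, NMI, AMI, wFM, accuracy}; None computes all.
    """
    t, p = as_partition(truth), as_partition(pred)
    ct = contingency(t, p)
    pc = pair_counts(ct)
    wanted = set(m.upper() for m in metrics) if metrics is not None else None

    def want(name):
        return wanted is None or name.upper() in wanted

    out: dict = {}
    if want("RI"):
        out["RI"] = rand_index(pc)
    if want("WH"):
        out["WH"] = wallace_homogeneity(pc)
    if want("WC"):
        out["WC"] = wallace_completeness(pc)
    if want("ARI"):
        out["ARI"] = adjusted_rand_index(pc)
    if want("AWH") or want("AWC"):
        awh, awc = adjusted_wallace(pc, ct)
        if want("AWH"):
            out["AWH"] = awh
        if want("AWC"):
            out["AWC"] = awc
    if want("NCR"):
        out["NCR"] = ncr(ct, n_permutations=n_permutations, seed=seed)
    ent_names = {"MI", "EH", "EC", "VM", "NMI", "AMI"}
    if wanted is None or ent_names & wanted:
        ent = entropy_suite(ct, EntropyContext(base=base, beta=beta, nmi_norm=nmi_norm))
        for k, v in ent.items():
            if want(k):
                out[k] = v
    if want("WFM"):
        out["wFM"] = weighted_f_measure(ct)
    if want("ACCURACY"):
        out["accuracy"] = set_matching_accuracy(t, p)
    return out
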