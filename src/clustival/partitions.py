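"""Core partition containers and pair-counting machinery.

Every external validation metric in the package is built on top of three
objects: a :class:`HardPartition` (a label vector), a
:class:`ContingencyTable` (class x cluster co-occurrence counts between a
ground-truth partition G and a predicted partition P), and the
:class:`PairCounts` quadruple (a, b, c, d) counting element pairs that are
grouped/separated consistently or inconsistently between the two
partitions.  A Hungarian-based cluster-to-class matching is also provided,
as several set-matching metrics require a one-to-one correspondence
between predicted clusters and annotated classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import InputError, UndefinedMetricError

__all__ = [
    "HardPartition",
    "ContingencyTable",
    "PairCounts",
    "MetricReport",
    "contingency",
    "pair_counts",
    "hungarian_match",
]

#: Sentinel used for clusters/classes left without a partner when the two
#: partitions have different numbers of groups.
UNMATCHED = "unmatched"


@dataclass(frozen=True)
class HardPartition:
    """A hard partition of n elements into K groups.

    Labels may be arbitrary hashable tokens (strings, ints); they are
    mapped to dense 0-based codes in first-appearance order.  Reported
    outputs use the original tokens.  Only realized (non-empty) groups
    count toward K.
    """

    codes: np.ndarray
    categories: tuple

    @classmethod
    def from_labels(cls, labels: Sequence[Hashable]) -> "HardPartition":
        labels = list(labels)
        if len(labels) == 0:
            raise InputError("a partition needs at least one element")
        seen: dict = {}
        codes = np.empty(len(labels), dtype=np.int64)
        for i, lab in enumerate(labels):
            if lab not in seen:
                seen[lab] = len(seen)
            codes[i] = seen[lab]
        return cls(codes=codes, categories=tuple(seen))

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def K(self) -> int:
        return len(self.categories)

    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.codes, minlength=self.K)

    def one_hot(self) -> np.ndarray:
        """n x K one-hot membership matrix (rows sum to 1)."""
        W = np.zeros((self.n, self.K))
        W[np.arange(self.n), self.codes] = 1.0
        return W


def as_partition(labels) -> HardPartition:
    """Coerce a label sequence (or pass through a HardPartition)."""
    if isinstance(labels, HardPartition):
        return labels
    return HardPartition.from_labels(labels)


@dataclass(frozen=True)
class ContingencyTable:
    """Class x cluster co-occurrence counts.

    Rows index ground-truth classes (sizes ``a_i``), columns predicted
    clusters (sizes ``b_j``).
    """

    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or (c < 0).any():
            raise InputError("contingency counts must be a nonnegative 2D array")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class PairCounts:
    """The pair-confusion quadruple over all n(n-1)/2 element pairs.

    a: same group in both partitions; b: same class in G, split in P;
    c: different classes in G, merged in P; d: separated in both.
    """

    a: int
    b: int
    c: int
    d: int
    n: int

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2


@dataclass
class MetricReport:
    """A metric result with its evaluation level and parameters.

    level is one of ``"element"``, ``"group"`` or ``"dataset"``; values is
    a scalar for dataset-level metrics and a dict keyed by element index
    or group token otherwise.
    """

    metric: str
    level: str
    values: object
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        vals = self.values
        if isinstance(vals, dict):
            vals = {str(k): (None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v))
                    for k, v in vals.items()}
        elif isinstance(vals, np.ndarray):
            vals = [None if np.isnan(v) else float(v) for v in vals]
        elif vals is not None:
            vals = float(vals)
        return {"metric": self.metric, "level": self.level,
                "values": vals, "parameters": dict(self.parameters)}


def contingency(truth, pred) -> ContingencyTable:
    """Build the class x cluster contingency table of two hard partitions."""
    t, p = as_partition(truth), as_partition(pred)
    if t.n != p.n:
        raise InputError(f"partition lengths differ: {t.n} != {p.n}")
    counts = np.zeros((t.K, p.K), dtype=np.int64)
    np.add.at(counts, (t.codes, p.codes), 1)
    return ContingencyTable(counts=counts, row_labels=t.categories, col_labels=p.categories)


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    return x * (x - 1) // 2


def pair_counts(ct: ContingencyTable) -> PairCounts:
    """Pair-confusion quantities (a, b, c, d) from a contingency table."""
    n = ct.n
    n_pairs = n * (n - 1) // 2
    a = int(_comb2(ct.counts).sum())
    same_truth = int(_comb2(ct.row_sums).sum())   # a + b
    same_pred = int(_comb2(ct.col_sums).sum())    # a + c
    b = same_truth - a
    c = same_pred - a
    d = n_pairs - a - b - c
    return PairCounts(a=a, b=b, c=c, d=d, n=n)


def _optimal_assignment_value(counts: np.ndarray) -> int:
    r, c = linear_sum_assignment(counts, maximize=True)
    return int(counts[r, c].sum())


def hungarian_match(ct: ContingencyTable) -> dict:
    """One-to-one cluster-to-class matching maximizing matched counts.

    Returns a dict mapping each predicted cluster token to its matched
    class token, or to the string ``"unmatched"`` when the cluster has no
    partner (more clusters than classes).  Among equally optimal
    assignments the lexicographically smallest one in (cluster code,
    class code) order is returned, so results are reproducible.
    """
    counts = np.asarray(ct.counts, dtype=np.int64)
    if counts.size == 0 or counts.sum() == 0:
        raise InputError("empty contingency table")
    assignment = _lexicographic_assignment(counts)
    out: dict = {}
    for j, tok in enumerate(ct.col_labels):
        i = assignment.get(j)
        out[tok] = ct.row_labels[i] if i is not None else UNMATCHED
    return out


def _lexicographic_assignment(counts: np.ndarray) -> dict[int, int]:
    """Optimal assignment, lexicographically smallest in (cluster, class)."""
    K_G, K_P = counts.shape
    n_assign = min(K_G, K_P)
    best = _optimal_assignment_value(counts)
    assignment: dict[int, int] = {}
    used_classes: set[int] = set()
    total = 0
    for j in range(K_P):
        if len(assignment) == n_assign:
            break
        remaining_slots = n_assign - len(assignment) - 1
        free_cols = [jj for jj in range(j + 1, K_P)]
        for i in range(K_G):
            if i in used_classes:
                continue
            rows = [ii for ii in range(K_G) if ii not in used_classes and ii != i]
            sub = counts[np.ix_(rows, free_cols)] if rows and free_cols else np.zeros((0, 0), dtype=np.int64)
            if min(len(rows), len(free_cols)) >= remaining_slots:
                rem_best = _optimal_assignment_value(sub) if sub.size else 0
                if total + counts[i, j] + rem_best == best:
                    assignment[j] = i
                    used_classes.add(i)
                    total += int(counts[i, j])
                    break
        # if no class can be fixed at column j while staying optimal, the
        # optimal solution leaves cluster j unmatched
    return assignment


def set_matching_accuracy(truth, pred) -> float:
    """Fraction of elements whose Hungarian-matched cluster equals their class."""
    t, p = as_partition(truth), as_partition(pred)
    ct = contingency(t, p)
    mapping = _lexicographic_assignment(np.asarray(ct.counts, dtype=np.int64))
    matched = sum(int(ct.counts[i, j]) for j, i in mapping.items())
    return matched / t.n
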