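import itertools

import numpy as np
import pytest

from clustival import HardPartition, PairCounts


def brute_force_pair_counts(truth_codes, pred_codes) -> PairCounts:
    """O(n^2) enumeration oracle for the pair-confusion quantities."""
    t = np.asarray(truth_codes)
    p = np.asarray(pred_codes)
    n = len(t)
    a = b = c = d = 0
    for i, j in itertools.combinations(range(n), 2):
        st, sp = t[i] == t[j], p[i] == p[j]
        if st and sp:
            a += 1
        elif st:
            b += 1
        elif sp:
            c += 1
        else:
            d += 1
    return PairCounts(a=a, b=b, c=c, d=d, n=n)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_hard_partition(rng, n, k) -> HardPartition:
    assert k <= n, "cannot realize more groups than elements"
    while True:
        codes = rng.integers(0, k, size=n)
        if len(np.unique(codes)) == k:
            return HardPartition.from_labels(codes)
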