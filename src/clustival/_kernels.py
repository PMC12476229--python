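"""Compiled pair-sum kernels.

The distance-weighted spatial Rand index needs a pass over all n(n-1)/2
element pairs.  Done naively with dense matrices this requires O(n^2)
memory, which is infeasible for modern spatial datasets (10^5+ cells); the
kernel below streams over pairs in O(1) memory and is JIT-compiled.
"""

from __future__ import annotations

import math

import numba
import numpy as np


@numba.njit(cache=False, fastmath=True)
def spatial_pair_sums(truth, pred, x, y, alpha, beta_f, beta_h, modified):
    """One streaming pass over all unordered pairs.

    Returns (score_sum, n_same_truth, h_sum_same_truth, f_sum_diff_truth):

    - score_sum: the spatial pair concordance total.  Concordant pairs
      score 1; pairs wrongly grouped by the prediction score f(d)
      (decaying with distance), wrongly separated pairs score h(d)
      (growing with distance), d being the euclidean distance on
      pre-normalized coordinates.
    - the three auxiliary sums give the exact expectation of the score
      under a uniform permutation of the predicted labels, for chance
      adjustment, without extra passes.
    """
    n = truth.shape[0]
    score = 0.0
    n_same_t = 0.0
    h_same_t = 0.0
    f_diff_t = 0.0
    for i in range(n - 1):
        ti = truth[i]
        pi = pred[i]
        xi = x[i]
        yi = y[i]
        for j in range(i + 1, n):
            same_t = ti == truth[j]
            same_p = pi == pred[j]
            dx = xi - x[j]
            dy = yi - y[j]
            d = math.sqrt(dx * dx + dy * dy)
            if same_t:
                if modified:
                    h = alpha * (1.0 - math.exp(-beta_h * d))
                else:
                    h = alpha * (1.0 - math.exp(-d * d))
                n_same_t += 1.0
                h_same_t += h
                score += 1.0 if same_p else h
            else:
                if modified:
                    f = alpha * math.exp(-beta_f * d)
                else:
                    f = alpha * math.exp(-d * d)
                f_diff_t += f
                score += f if same_p else 1.0
    return score, n_same_t, h_same_t, f_diff_t
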