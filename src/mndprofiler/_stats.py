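"""Exact one-sided rank-sum p-value by enumeration of rank assignments.

The null distribution of the rank sum of a size-m subset of N combined
observations is computed by an integer dynamic program over doubled
midranks (doubling makes tied midranks exact integers), so ties are handled
without approximation. Complexity O(N * m * S) with S the doubled-rank sum
range — comfortably fast for the test-set sizes (<= 10) it is used for.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.stats import rankdata

__all__ = ["exact_ranksum_p_greater"]


def exact_ranksum_p_greater(test: np.ndarray, background: np.ndarray) -> float:
    """P(rank sum of a random size-m subset >= observed), one-sided greater.

    ``test`` and ``background`` are pooled, midranked, and the observed rank
    sum of ``test`` compared against the exact permutation distribution of
    all C(m+N, m) subsets.
    """
    test = np.asarray(test, dtype=float)
    background = np.asarray(background, dtype=float)
    m, n = len(test), len(background)
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([test, background])
    ranks2 = np.rint(2 * rankdata(combined)).astype(int)  # doubled midranks
    w_obs = int(ranks2[:m].sum())

    # ways[j][s] = number of size-j subsets of the items seen so far with
    # doubled-rank sum s (dict keyed by s keeps the table sparse).
    ways: list[dict[int, int]] = [dict() for _ in range(m + 1)]
    ways[0][0] = 1
    for r in ranks2:
        for j in range(m - 1, -1, -1):  # descending so each item is used once
            if not ways[j]:
                continue
            tgt = ways[j + 1]
            for s, c in ways[j].items():
                tgt[s + r] = tgt.get(s + r, 0) + c
    count_ge = sum(c for s, c in ways[m].items() if s >= w_obs)
    return count_ge / comb(m + n, m)
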