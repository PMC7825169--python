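"""Independent oracles used by the test suite.

These deliberately avoid the package's dynamic-programming / Lance-Williams
code paths: the alignment oracle enumerates every alignment recursively and
the linkage oracle is scipy's independent implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform


def brute_force_align_score(a: str, b: str, match=2, mismatch=-3,
                            gap_open=-5, gap_extend=-2) -> int:
    """Best global affine-gap score by exhaustive recursive enumeration.

    A gap run of length L costs gap_open + L*gap_extend; terminal gaps are
    penalised (global mode).  Exponential: lengths must stay small (<= 8).
    """
    n, m = len(a), len(b)
    best = [-(10 ** 9)]

    def rec(i: int, j: int, state: int, score: int) -> None:
        # state: 0 = last column was a match/mismatch (or start),
        #        1 = gap run in b (consuming a), 2 = gap run in a
        if i == n and j == m:
            if score > best[0]:
                best[0] = score
            return
        if i < n and j < m:
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, 0, score + s)
        if i < n:
            cost = gap_extend if state == 1 else gap_open + gap_extend
            rec(i + 1, j, 1, score + cost)
        if j < m:
            cost = gap_extend if state == 2 else gap_open + gap_extend
            rec(i, j + 1, 2, score + cost)

    rec(0, 0, 0, 0)
    return best[0]


def scipy_ward_heights(values: np.ndarray) -> np.ndarray:
    """Merge heights of Ward (ward.D2 on distances) linkage, ascending."""
    Z = scipy_linkage(squareform(values, checks=False), method="ward")
    return np.sort(Z[:, 2])
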