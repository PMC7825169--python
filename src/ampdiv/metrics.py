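"""Small partition-comparison utilities."""

from __future__ import annotations

from typing import Dict, Hashable, Sequence

import numpy as np
from scipy.special import comb

__all__ = ["adjusted_rand_index"]


def adjusted_rand_index(labels_a: Sequence[Hashable],
                        labels_b: Sequence[Hashable]) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    Standard pair-counting formulation; 1 for identical partitions, ~0 for
    independent ones.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences differ in length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty partitions")
    table: Dict[tuple, int] = {}
    rows: Dict[Hashable, int] = {}
    cols: Dict[Hashable, int] = {}
    for a, b in zip(labels_a, labels_b):
        table[(a, b)] = table.get((a, b), 0) + 1
        rows[a] = rows.get(a, 0) + 1
        cols[b] = cols.get(b, 0) + 1
    sum_ij = sum(comb(v, 2) for v in table.values())
    sum_a = sum(comb(v, 2) for v in rows.values())
    sum_b = sum(comb(v, 2) for v in cols.values())
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (all-singletons/all-one)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
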