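"""Bray-Curtis dissimilarity, matrix averaging and Ward.D2 phylogeography.

For each lineage, pairwise Bray-Curtis dissimilarities of within-lineage ASV
composition are computed among the samples that pass the lineage's read
floor; matrices of the dominant lineages are then averaged entry-wise (over
the lineages in which both samples are included, with the per-pair support
recorded) and the averaged matrix is clustered with Ward.D2 agglomerative
linkage.  Bray-Curtis between count vectors a, b is

    BC = 1 - 2 * sum_i min(a_i, b_i) / (sum_i a_i + sum_i b_i)

and on within-lineage proportions (the default, guarding against uneven
sequencing depths) this equals half the L1 distance of the proportion
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .profiles import LineageProfile

__all__ = ["DissimMatrix", "LinkageTree", "bray_curtis_matrix",
           "average_matrices", "ward_d2_linkage", "cut_tree", "pairwise_values"]


@dataclass
class DissimMatrix:
    sample_ids: List[str]
    values: np.ndarray  # symmetric, zero diagonal, in [0,1]; NaN = missing
    #: per-pair count of contributing lineages (1 for single-lineage matrices)
    support: np.ndarray = field(default=None)  # type: ignore[assignment]
    source: str = "single"

    def __post_init__(self):
        n = len(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample_ids")
        if self.support is None:
            self.support = np.ones((n, n), dtype=int)
            np.fill_diagonal(self.support, 0)
        self.validate()

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("dissimilarity diagonal is not zero")
        finite = v[~np.isnan(v)]
        if ((finite < -1e-12) | (finite > 1 + 1e-12)).any():
            raise ValueError("dissimilarity values outside [0, 1]")
        off = ~np.eye(len(v), dtype=bool)
        if (np.isnan(v[off]) != (self.support[off] == 0)).any():
            raise ValueError("support inconsistent with missing entries")

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def submatrix(self, sample_ids: Sequence[str]) -> "DissimMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DissimMatrix(list(sample_ids), self.values[np.ix_(idx, idx)],
                            self.support[np.ix_(idx, idx)], self.source)


@dataclass
class LinkageTree:
    """Agglomerative merge list; leaves 0..n-1, merge k creates node n+k."""

    n_leaves: int
    merges: List[Tuple[int, int, float, int]]  # (node_a, node_b, height, new_size)

    def __post_init__(self):
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a tree over n leaves needs n-1 merges")
        sizes = {i: 1 for i in range(self.n_leaves)}
        prev = -np.inf
        for k, (a, b, h, size) in enumerate(self.merges):
            if sizes[a] + sizes[b] != size:
                raise ValueError(f"merge {k}: size {size} != |{a}|+|{b}|")
            if h < prev - 1e-9:
                raise ValueError(f"merge {k}: height {h} decreases (not monotone)")
            prev = max(prev, h)
            sizes[self.n_leaves + k] = size

    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])


def bray_curtis_matrix(profile: LineageProfile, normalize: bool = True
                       ) -> DissimMatrix:
    """Pairwise Bray-Curtis among the profile's included samples.

    With ``normalize`` (default) compositions are within-lineage proportions,
    making the dissimilarity depth-independent.
    """
    samples = profile.included_samples
    if len(samples) < 2:
        raise ValueError(f"{profile.otu_id}: need >= 2 included samples, "
                         f"have {len(samples)}")
    mat = profile.counts[samples].to_numpy(dtype=float).T  # samples x ASVs
    totals = mat.sum(axis=1)
    if (totals == 0).any():
        zero = samples[int(np.argmax(totals == 0))]
        raise ValueError(f"{profile.otu_id}: included sample {zero} has zero reads")
    if normalize:
        mat = mat / totals[:, None]
    values = squareform(pdist(mat, metric="braycurtis"))
    return DissimMatrix(list(samples), values, source=profile.otu_id)


def average_matrices(matrices: Sequence[DissimMatrix], min_support: int = 1
                     ) -> DissimMatrix:
    """Entry-wise mean over lineages in which both samples are included.

    Sample universe is the union (order of first appearance).  Entries whose
    support falls below ``min_support`` are marked missing (NaN).
    """
    if not matrices:
        raise ValueError("no matrices to average")
    universe: List[str] = []
    for m in matrices:
        for s in m.sample_ids:
            if s not in universe:
                universe.append(s)
    n = len(universe)
    pos = {s: i for i, s in enumerate(universe)}
    total = np.zeros((n, n))
    support = np.zeros((n, n), dtype=int)
    for m in matrices:
        idx = np.array([pos[s] for s in m.sample_ids])
        total[np.ix_(idx, idx)] += m.values
        support[np.ix_(idx, idx)] += 1
    np.fill_diagonal(support, 0)
    with np.errstate(invalid="ignore"):
        values = np.where(support >= max(min_support, 1),
                          total / np.maximum(support, 1), np.nan)
    np.fill_diagonal(values, 0.0)
    support = np.where(support >= max(min_support, 1), support, 0)
    return DissimMatrix(universe, values, support, source="averaged")


def ward_d2_linkage(m: DissimMatrix) -> LinkageTree:
    """Ward.D2 agglomerative clustering on (unsquared) dissimilarities.

    Implements the Lance-Williams update on squared distances under a square
    root:

        d(i+j, k) = sqrt[((n_i+n_k) d_ik^2 + (n_j+n_k) d_jk^2 - n_k d_ij^2)
                         / (n_i+n_j+n_k)]

    merging the globally minimal pair each step; ties broken by the smallest
    (node_a, node_b) index pair.
    """
    if not m.is_complete:
        raise ValueError("cannot cluster a matrix with missing entries; raise "
                         "min coverage or drop samples")
    n = len(m.sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    dist: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(m.values[i, j])
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: List[Tuple[int, int, float, int]] = []
    for step in range(n - 1):
        best = None
        for pair, d in dist.items():
            if best is None or d < best[0] - 1e-15 or (
                    abs(d - best[0]) <= 1e-15 and pair < best[1]):
                best = (d, pair)
        d_ij, (i, j) = best
        new = n + step
        size = sizes[i] + sizes[j]
        merges.append((i, j, d_ij, size))
        active.discard(i)
        active.discard(j)
        for k in sorted(active):
            d_ik = dist.pop((min(i, k), max(i, k)))
            d_jk = dist.pop((min(j, k), max(j, k)))
            num = ((sizes[i] + sizes[k]) * d_ik ** 2
                   + (sizes[j] + sizes[k]) * d_jk ** 2
                   - sizes[k] * d_ij ** 2)
            dist[(k, new)] = np.sqrt(max(num / (size + sizes[k]), 0.0))
        del dist[(i, j)]
        sizes[new] = size
        active.add(new)
    return LinkageTree(n, merges)


def cut_tree(tree: LinkageTree, k: int) -> Dict[int, int]:
    """Leaf -> cluster label from removing the k-1 highest (last) merges.

    Labels are numbered by first-leaf order: scanning leaves 0..n-1, each
    newly encountered cluster receives the next label starting from 0.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, _h, _s) in enumerate(tree.merges[: n - k]):
        node = n + step
        parent[find(a)] = node
        parent[find(b)] = node
    labels: Dict[int, int] = {}
    relabel: Dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in relabel:
            relabel[root] = len(relabel)
        labels[leaf] = relabel[root]
    return labels


def pairwise_values(m: DissimMatrix,
                    sample_filter: Optional[Callable[[str], bool]] = None
                    ) -> List[Tuple[Tuple[str, str], float]]:
    """Upper-triangle (pair, value) list for samples passing the filter.

    Missing entries (zero support) are omitted.  Suitable for per-lineage
    dissimilarity distribution summaries.
    """
    keep = [s for s in m.sample_ids if sample_filter is None or sample_filter(s)]
    idx = [m.sample_ids.index(s) for s in keep]
    out = []
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            v = m.values[idx[a], idx[b]]
            if not np.isnan(v):
                out.append(((keep[a], keep[b]), float(v)))
    return out
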