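"""Greedy centroid clustering of 16S regions and re-assignment of ASVs.

Clustering at 97% identity groups ASVs into lineage-level OTUs; at 100% into
SSU-ASVs (identical 16S regions, possibly differing in ITS).  Semantics
mirror greedy length-sorted centroid clustering: inputs are processed in
(length desc, abundance desc, id asc) order and each joins the FIRST
existing centroid at or above the threshold, else founds a new one.
Re-assignment (:func:`map_to_centroids`) instead picks the BEST centroid at
or above the threshold, matching the distinct semantics of a global search
against a fixed centroid database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .align import (DEFAULT_SCORING, Scoring, anchored_msa, sequence_identity)

__all__ = ["ClusterSet", "greedy_cluster", "map_to_centroids",
           "cluster_consensus", "validate_cluster_set"]


@dataclass
class ClusterSet:
    threshold: float
    #: cluster_id -> centroid sequence, in creation order
    centroids: Dict[str, str]
    #: asv_id -> (cluster_id, identity to centroid)
    assignments: Dict[str, Tuple[str, float]]
    #: the sorted input order used
    processing_order: List[str] = field(default_factory=list)

    @property
    def cluster_ids(self) -> List[str]:
        return list(self.centroids)

    def members(self) -> Dict[str, List[str]]:
        """cluster_id -> member asv_ids (assignment order)."""
        out: Dict[str, List[str]] = {c: [] for c in self.centroids}
        for asv, (cid, _ident) in self.assignments.items():
            out[cid].append(asv)
        return out

    def otu_map(self) -> Dict[str, str]:
        return {asv: cid for asv, (cid, _ident) in self.assignments.items()}


def _identity_if_possible(query: str, centroid: str, threshold: float,
                          scoring: Scoring) -> Optional[float]:
    """Identity, short-circuiting pairs that provably fall below a 1.0 threshold.

    At threshold 1.0 identity can only reach 1.0 when the alignment is all
    matches apart from terminal gaps, i.e. when one sequence is a contiguous
    substring of the other; anything else cannot qualify and the alignment
    is skipped.
    """
    if query == centroid:
        return 1.0
    if threshold >= 1.0:
        shorter, longer = sorted((query, centroid), key=len)
        if shorter not in longer:
            return None
    return sequence_identity(query, centroid, scoring)


def greedy_cluster(seqs: Mapping[str, str], abundances: Mapping[str, int],
                   threshold: float, prefix: str = "C",
                   scoring: Scoring = DEFAULT_SCORING) -> ClusterSet:
    """Greedy centroid clustering at an identity threshold in (0, 1].

    Identical input sequences necessarily make identical join decisions, so
    they are grouped up front and decided once (the outcome is provably the
    same as processing them individually in sorted order).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    for asv, seq in seqs.items():
        if not seq:
            raise ValueError(f"empty sequence for {asv}")
    order = sorted(seqs, key=lambda a: (-len(seqs[a]), -abundances.get(a, 0), a))
    groups: Dict[str, List[str]] = {}
    for asv in order:
        groups.setdefault(seqs[asv], []).append(asv)
    centroid_ids: List[str] = []
    centroids: Dict[str, str] = {}
    assignments: Dict[str, Tuple[str, float]] = {}
    for seq, members in groups.items():
        hit: Optional[Tuple[str, float]] = None
        for cid in centroid_ids:
            ident = _identity_if_possible(seq, centroids[cid], threshold, scoring)
            if ident is not None and ident >= threshold:
                hit = (cid, ident)
                break
        if hit is None:
            cid = f"{prefix}{len(centroid_ids) + 1}"
            centroid_ids.append(cid)
            centroids[cid] = seq
            hit = (cid, 1.0)
        for asv in members:
            assignments[asv] = hit
    return ClusterSet(threshold, centroids, assignments, order)


def map_to_centroids(seqs: Mapping[str, str], clusters: ClusterSet,
                     threshold: Optional[float] = None,
                     scoring: Scoring = DEFAULT_SCORING
                     ) -> Dict[str, Tuple[Optional[str], float]]:
    """Assign each sequence to the best centroid at/above the threshold.

    Ties go to the earlier centroid (creation order); sequences below the
    threshold against every centroid map to ``(None, best_identity)``.
    """
    if threshold is None:
        threshold = clusters.threshold
    out: Dict[str, Tuple[Optional[str], float]] = {}
    for asv, seq in seqs.items():
        best_cid: Optional[str] = None
        best_ident = 0.0
        for cid, centroid in clusters.centroids.items():
            ident = _identity_if_possible(seq, centroid, threshold, scoring)
            if ident is None:
                continue
            if ident > best_ident:  # strict: ties keep the earlier centroid
                best_ident = ident
                if ident >= threshold:
                    best_cid = cid
        out[asv] = (best_cid, best_ident)
    return out


def cluster_consensus(members: Mapping[str, str],
                      abundances: Optional[Mapping[str, int]] = None,
                      scoring: Scoring = DEFAULT_SCORING) -> str:
    """Majority-rule consensus of a cluster, anchored on the most abundant member.

    Per reference column the majority state is emitted (ties broken
    alphabetically A<C<G<T); a strict gap majority deletes the column.
    Insertions relative to the reference are retained when more than half of
    all members (the reference counting as one) carry an identical inserted
    string at that position.
    """
    if not members:
        raise ValueError("cluster_consensus requires at least one member")
    abundances = abundances or {}
    ranked = sorted(members, key=lambda a: (-abundances.get(a, 0), a))
    ref_id = ranked[0]
    others = ranked[1:]
    if not others:
        return members[ref_id]
    msa = anchored_msa(members[ref_id], [members[m] for m in others],
                       member_ids=others, reference_id=ref_id, scoring=scoring)
    n_total = len(ranked)
    pieces: List[str] = []
    for pos in range(len(msa.reference) + 1):
        ins = msa.insertions.get(pos, {})
        if ins:
            counts: Dict[str, int] = {}
            for s in ins.values():
                counts[s] = counts.get(s, 0) + 1
            string, votes = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            if 2 * votes > n_total:
                pieces.append(string)
        if pos == len(msa.reference):
            break
        states = msa.column(pos)
        gap_votes = states.count("-")
        if 2 * gap_votes > n_total:
            continue
        tally: Dict[str, int] = {}
        for st in states:
            if st != "-":
                tally[st] = tally.get(st, 0) + 1
        pieces.append(min(tally.items(), key=lambda kv: (-kv[1], kv[0]))[0])
    return "".join(pieces)


def validate_cluster_set(clusters: ClusterSet, seqs: Mapping[str, str],
                         scoring: Scoring = DEFAULT_SCORING) -> None:
    """Check the structural invariants of a clustering result.

    Every input assigned exactly once; every member at/above the threshold
    to its centroid; every centroid pair below the threshold.  Intended for
    tests and post-run verification (quadratic in centroid count).
    """
    if set(clusters.assignments) != set(seqs):
        raise AssertionError("assignments do not cover the inputs exactly")
    for asv, (cid, ident) in clusters.assignments.items():
        actual = sequence_identity(seqs[asv], clusters.centroids[cid], scoring)
        if actual < clusters.threshold:
            raise AssertionError(
                f"{asv}: identity {actual:.4f} to {cid} below threshold")
        if abs(actual - ident) > 1e-12:
            raise AssertionError(f"{asv}: recorded identity {ident} != {actual}")
    cids = clusters.cluster_ids
    for i, ci in enumerate(cids):
        for cj in cids[i + 1:]:
            ident = sequence_identity(clusters.centroids[ci],
                                      clusters.centroids[cj], scoring)
            if ident >= clusters.threshold:
                raise AssertionError(
                    f"centroids {ci},{cj} identity {ident:.4f} >= threshold")
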