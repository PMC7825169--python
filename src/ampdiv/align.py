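"""Pairwise DNA alignment, identity, primer matching and amplicon partitioning.

The clustering and SNP analyses downstream all reduce to pairwise global
(Needleman-Wunsch/Gotoh, affine gaps) or overlap (free terminal gaps)
alignments of near-identical rRNA amplicons.  The dynamic program is
implemented here with a fixed, documented tie-breaking order so that every
downstream result is bit-reproducible:

* among co-optimal moves, a match/mismatch column is preferred over a gap,
  and a gap in sequence ``b`` is preferred over a gap in sequence ``a``;
* overlap alignments ending short of a corner prefer the smallest overhang.

Percent identity follows the convention of greedy centroid clustering tools:
matching columns divided by alignment columns excluding terminal-gap
columns; internal gap columns count against identity.  A consequence worth
knowing: a sequence that is a flush substring of another scores identity 1.0
even though the sequences differ (terminal overhangs are not penalised).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

__all__ = [
    "Scoring",
    "DEFAULT_SCORING",
    "AlignmentResult",
    "RegionPartition",
    "AnchoredMsa",
    "AberrantOperonError",
    "global_align",
    "overlap_align",
    "pairwise_identity",
    "sequence_identity",
    "match_degenerate_primer",
    "reverse_complement",
    "anchored_msa",
    "partition_regions",
]

_NEG = np.int32(-(2 ** 28))
_M, _X, _Y = 0, 1, 2  # states: diagonal, gap-in-b (consumes a), gap-in-a


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring; a gap of length L costs ``gap_open + L*gap_extend``."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()


class AberrantOperonError(ValueError):
    """Amplicon does not partition into ordered 16S / ITS / 23S-fragment spans."""


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: int
    matches: int
    mismatches: int
    internal_gap_columns: int
    #: (leading gaps in a, trailing gaps in a, leading gaps in b, trailing gaps in b)
    terminal_gap_spans: Tuple[int, int, int, int]

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    @property
    def terminal_gap_columns(self) -> int:
        la, ta, lb, tb = self.terminal_gap_spans
        return la + ta + lb + tb


@dataclass
class RegionPartition:
    """0-based half-open SSU / ITS / LSU intervals tiling an amplicon."""

    asv_id: str
    ssu: Tuple[int, int]
    its: Tuple[int, int]
    lsu: Tuple[int, int]

    def region_of(self, pos: int) -> str:
        """Region label for a 0-based amplicon position."""
        if self.ssu[0] <= pos < self.ssu[1]:
            return "SSU"
        if self.its[0] <= pos < self.its[1]:
            return "ITS"
        if self.lsu[0] <= pos < self.lsu[1]:
            return "LSU"
        raise IndexError(f"position {pos} outside amplicon of {self.asv_id}")

    def region_relative(self, pos: int) -> Tuple[str, int]:
        """(region, 1-based position within region) for a 0-based position."""
        region = self.region_of(pos)
        start = {"SSU": self.ssu[0], "ITS": self.its[0], "LSU": self.lsu[0]}[region]
        return region, pos - start + 1

    def validate(self, seq_len: int) -> None:
        if not (0 == self.ssu[0] <= self.ssu[1] == self.its[0] <= self.its[1]
                == self.lsu[0] <= self.lsu[1] == seq_len):
            raise AberrantOperonError(
                f"{self.asv_id}: intervals {self.ssu},{self.its},{self.lsu} "
                f"do not tile [0,{seq_len})")


@dataclass
class AnchoredMsa:
    """Reference-anchored multiple alignment in reference coordinates.

    Every member is globally aligned to the reference independently; columns
    are reference positions.  Member bases opposite a reference gap
    (insertions) are stored separately keyed by the 0-based reference
    position they precede.
    """

    reference_id: str
    reference: str
    member_ids: List[str]
    #: member_id -> string of len(reference) over {A,C,G,T,-} (reference row excluded)
    rows: Dict[str, str]
    #: ref position (insertion before it; len(ref) = after end) -> member_id -> string
    insertions: Dict[int, Dict[str, str]]

    def column(self, pos: int, include_reference: bool = True) -> List[str]:
        states = [self.reference[pos]] if include_reference else []
        states.extend(self.rows[m][pos] for m in self.member_ids)
        return states


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend,
                free_lead_a, free_lead_b):  # pragma: no cover - exercised via wrapper
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), _NEG, np.int32)
    X = np.full((n + 1, m + 1), _NEG, np.int32)
    Y = np.full((n + 1, m + 1), _NEG, np.int32)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = 0 if free_lead_b else gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = 0 if free_lead_a else gap_open + j * gap_extend
    oe = gap_open + gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + s
            v = M[i - 1, j] + oe
            w = X[i - 1, j] + gap_extend
            if w > v:
                v = w
            w = Y[i - 1, j] + oe
            if w > v:
                v = w
            X[i, j] = v
            v = M[i, j - 1] + oe
            w = X[i, j - 1] + oe
            if w > v:
                v = w
            w = Y[i, j - 1] + gap_extend
            if w > v:
                v = w
            Y[i, j] = v
    return M, X, Y


_ENCODE = np.full(128, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
# IUPAC ambiguity codes get private codes so they never match anything,
# including themselves (conservative for identity purposes).
for _i, _c in enumerate("RYSWKMBDHVN"):
    _ENCODE[ord(_c)] = 100 + _i


def _encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-IUPAC character {bad!r} in sequence")
    return arr


def _choose_end(M, X, Y, free_trail_a, free_trail_b):
    """Best-scoring end cell/state under the documented preference order."""
    n = M.shape[0] - 1
    m = M.shape[1] - 1
    candidates = [(int(M[n, m]), n, m, _M), (int(X[n, m]), n, m, _X),
                  (int(Y[n, m]), n, m, _Y)]
    if free_trail_b:  # trailing gaps in b: unaligned suffix of a is free
        for i in range(n - 1, -1, -1):
            candidates.append((int(M[i, m]), i, m, _M))
            candidates.append((int(Y[i, m]), i, m, _Y))
    if free_trail_a:
        for j in range(m - 1, -1, -1):
            candidates.append((int(M[n, j]), n, j, _M))
            candidates.append((int(X[n, j]), n, j, _X))
    best = candidates[0]
    for cand in candidates[1:]:
        if cand[0] > best[0]:
            best = cand
    return best


def _align(a: str, b: str, scoring: Scoring,
           free_lead_a=False, free_trail_a=False,
           free_lead_b=False, free_trail_b=False) -> AlignmentResult:
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    ea, eb = _encode(a), _encode(b)
    M, X, Y = _gotoh_fill(ea, eb, np.int32(scoring.match), np.int32(scoring.mismatch),
                          np.int32(scoring.gap_open), np.int32(scoring.gap_extend),
                          free_lead_a, free_lead_b)
    score, ei, ej, state = _choose_end(M, X, Y, free_trail_a, free_trail_b)
    n, m = len(a), len(b)
    cols_a: List[str] = []
    cols_b: List[str] = []
    # free trailing overhang (appended after reversal)
    trail_a = ["-"] * (m - ej) if ej < m else []
    trail_b = list(b[ej:]) if ej < m else []
    if ei < n:
        trail_a = list(a[ei:])
        trail_b = ["-"] * (n - ei)
    oe = scoring.gap_open + scoring.gap_extend
    i, j, st = ei, ej, state
    while i > 0 or j > 0:
        if j == 0:
            cols_a.append(a[i - 1])
            cols_b.append("-")
            i -= 1
            continue
        if i == 0:
            cols_a.append("-")
            cols_b.append(b[j - 1])
            j -= 1
            continue
        if st == _M:
            s = scoring.match if ea[i - 1] == eb[j - 1] else scoring.mismatch
            target = int(M[i, j]) - s
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            if int(M[i - 1, j - 1]) == target:
                st = _M
            elif int(X[i - 1, j - 1]) == target:
                st = _X
            else:
                st = _Y
            i -= 1
            j -= 1
        elif st == _X:
            cols_a.append(a[i - 1])
            cols_b.append("-")
            cur = int(X[i, j])
            if int(M[i - 1, j]) + oe == cur:
                st = _M
            elif int(X[i - 1, j]) + scoring.gap_extend == cur:
                st = _X
            else:
                st = _Y
            i -= 1
        else:
            cols_a.append("-")
            cols_b.append(b[j - 1])
            cur = int(Y[i, j])
            if int(M[i, j - 1]) + oe == cur:
                st = _M
            elif int(X[i, j - 1]) + oe == cur:
                st = _X
            else:
                st = _Y
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    aligned_a = "".join(cols_a) + "".join(trail_a)
    aligned_b = "".join(cols_b) + "".join(trail_b)
    return _build_result(aligned_a, aligned_b, score)


def _build_result(aligned_a: str, aligned_b: str, score: int) -> AlignmentResult:
    L = len(aligned_a)
    assert L == len(aligned_b)
    lead = 0
    while lead < L and (aligned_a[lead] == "-" or aligned_b[lead] == "-"):
        lead += 1
    trail = 0
    while trail < L - lead and (aligned_a[L - 1 - trail] == "-"
                                or aligned_b[L - 1 - trail] == "-"):
        trail += 1
    matches = mismatches = internal_gaps = 0
    for k in range(lead, L - trail):
        ca, cb = aligned_a[k], aligned_b[k]
        if ca == "-" or cb == "-":
            internal_gaps += 1
        elif ca == cb:
            matches += 1
        else:
            mismatches += 1
    spans = (
        aligned_a[:lead].count("-") + 0,
        aligned_a[L - trail:].count("-"),
        aligned_b[:lead].count("-"),
        aligned_b[L - trail:].count("-"),
    )
    return AlignmentResult(aligned_a, aligned_b, score, matches, mismatches,
                           internal_gaps, spans)


def global_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch) alignment with affine gap costs.

    Terminal gaps are penalised in the score but excluded by
    :func:`pairwise_identity`.  Ties are broken deterministically: diagonal
    over gap, gap in ``b`` over gap in ``a``.
    """
    return _align(a, b, scoring)


def overlap_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult:
    """Semi-global alignment with free terminal gaps on both sequences."""
    return _align(a, b, scoring, free_lead_a=True, free_trail_a=True,
                  free_lead_b=True, free_trail_b=True)


def pairwise_identity(aln: AlignmentResult) -> float:
    """Matches / alignment columns excluding terminal-gap columns."""
    lead_a, trail_a, lead_b, trail_b = aln.terminal_gap_spans
    denom = aln.length - (lead_a + lead_b) - (trail_a + trail_b)
    if denom <= 0:
        raise ValueError("alignment has no non-terminal columns")
    return aln.matches / denom


_IDENTITY_CACHE: Dict[Tuple[str, str], float] = {}


def sequence_identity(a: str, b: str, scoring: Scoring = DEFAULT_SCORING,
                      cache: bool = True) -> float:
    """Pairwise identity of two sequences under global alignment.

    The argument pair is canonicalised (lexicographic order) before aligning,
    which makes the value exactly symmetric despite the direction-dependent
    alignment tie-break.  Results are memoised because clustering revisits
    the same pairs.
    """
    if a == b:
        return 1.0
    key = (a, b) if a <= b else (b, a)
    if cache and scoring == DEFAULT_SCORING:
        hit = _IDENTITY_CACHE.get(key)
        if hit is not None:
            return hit
    ident = pairwise_identity(global_align(key[0], key[1], scoring))
    if cache and scoring == DEFAULT_SCORING:
        _IDENTITY_CACHE[key] = ident
    return ident


IUPAC_SETS: Dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def match_degenerate_primer(seq: str, primer: str, max_mismatch: int = 0,
                            orientation: str = "forward") -> List[Tuple[int, int]]:
    """All start positions where an IUPAC primer matches ``seq``.

    A primer letter matches when its IUPAC set contains the sequence base.
    ``orientation="reverse-complement"`` matches the reverse complement of
    the primer against the forward strand.  Returns ``(position, mismatches)``
    pairs with ``mismatches <= max_mismatch``; a primer longer than the
    sequence yields an empty list.
    """
    if orientation not in ("forward", "reverse-complement"):
        raise ValueError(f"unknown orientation {orientation!r}")
    probe = primer.upper()
    if orientation == "reverse-complement":
        probe = reverse_complement(probe)
    try:
        sets = [IUPAC_SETS[c] for c in probe]
    except KeyError as exc:
        raise ValueError(f"non-IUPAC primer letter {exc.args[0]!r}") from None
    hits = []
    for start in range(len(seq) - len(probe) + 1):
        mm = 0
        for offset, allowed in enumerate(sets):
            if seq[start + offset] not in allowed:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append((start, mm))
    return hits


def anchored_msa(reference: str, members: Sequence[str],
                 member_ids: Optional[Sequence[str]] = None,
                 reference_id: str = "reference",
                 scoring: Scoring = DEFAULT_SCORING,
                 warn_identity: float = 0.9) -> AnchoredMsa:
    """Align every member to the reference independently, in reference coordinates.

    Intended for near-identical within-lineage sequences; a warning is issued
    when any member falls below ``warn_identity`` to the reference.
    """
    if member_ids is None:
        member_ids = [f"member_{k + 1}" for k in range(len(members))]
    if len(member_ids) != len(members):
        raise ValueError("member_ids length does not match members")
    rows: Dict[str, str] = {}
    insertions: Dict[int, Dict[str, str]] = {}
    for mid, seq in zip(member_ids, members):
        aln = global_align(reference, seq, scoring)
        if pairwise_identity(aln) < warn_identity:
            warnings.warn(f"member {mid} has identity < {warn_identity} to "
                          f"{reference_id}; anchored MSA may be unreliable")
        row: List[str] = []
        ref_pos = 0
        pending = ""
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca == "-":
                pending += cb  # insertion relative to the reference
            else:
                if pending:
                    insertions.setdefault(ref_pos, {})[mid] = pending
                    pending = ""
                row.append(cb)
                ref_pos += 1
        if pending:
            insertions.setdefault(ref_pos, {})[mid] = pending
        rows[mid] = "".join(row)
    return AnchoredMsa(reference_id, reference, list(member_ids), rows, insertions)


def _covered_span(aln: AlignmentResult) -> Tuple[int, int]:
    """Span of ``b`` (0-based half-open) covered by the aligned block of ``a``."""
    first = last = None
    bpos = 0
    start = end = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-":
            if first is None:
                first = True
                start = bpos
            if cb != "-":
                end = bpos + 1
        if cb != "-":
            bpos += 1
    if first is None:
        raise ValueError("reference entirely unaligned")
    return start, end


def partition_regions(seq: str, ssu_reference: str, lsu_reference: str,
                      asv_id: str = "", min_its: int = 1,
                      scoring: Scoring = DEFAULT_SCORING) -> RegionPartition:
    """Partition a primer-trimmed amplicon into SSU / ITS / LSU-fragment spans.

    The SSU span is located by overlap-aligning a full-length 16S reference
    against the amplicon (free terminal gaps on both); the LSU span by
    overlap-aligning a short 23S 5'-fragment reference against the amplicon
    tail.  The amplicon is assumed to start inside the 16S gene, so the SSU
    interval is clamped to position 0 and the LSU interval extends to the
    amplicon end; the ITS is everything between.
    """
    if len(seq) < 0.8 * len(ssu_reference):
        raise AberrantOperonError(
            f"{asv_id or 'sequence'}: length {len(seq)} is >20% shorter than "
            f"the 16S reference ({len(ssu_reference)} nt)")
    ssu_aln = overlap_align(ssu_reference, seq, scoring)
    ssu_start, ssu_end = _covered_span(ssu_aln)
    if ssu_end - ssu_start < 0.8 * len(ssu_reference):
        raise AberrantOperonError(
            f"{asv_id or 'sequence'}: 16S reference covers only "
            f"{ssu_end - ssu_start} nt of the amplicon")
    window = max(0, len(seq) - 2 * len(lsu_reference) - 50)
    tail_aln = overlap_align(lsu_reference, seq[window:], scoring)
    lsu_start = window + _covered_span(tail_aln)[0]
    its_len = lsu_start - ssu_end
    if its_len < min_its:
        raise AberrantOperonError(
            f"{asv_id or 'sequence'}: ITS between 16S end ({ssu_end}) and 23S "
            f"start ({lsu_start}) is shorter than {min_its} nt; putative "
            "unlinked or aberrant rRNA operon")
    part = RegionPartition(asv_id, (0, ssu_end), (ssu_end, lsu_start),
                           (lsu_start, len(seq)))
    part.validate(len(seq))
    return part
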