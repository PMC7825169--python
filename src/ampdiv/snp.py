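"""Concordance between ASV-expected variant sites and metagenomic pileups.

Validation procedure for single-nucleotide-resolved amplicon analysis: the
variant positions *expected* from the within-lineage ASVs of one sample
(abundance-weighted state frequencies from a reference-anchored MSA) are
compared against the variants *detected* in a per-position base-count pileup
of metagenomic reads mapped to the same reference.  Each site in the union
is classified as ``both``, ``expected_only`` or ``detected_only``.

Positions are reported 1-based on the reference amplicon, alongside
region-relative coordinates (SSU / ITS / LSU).  Deletions in the pileup map
to the MSA gap state; ASV insertions relative to the reference have no
reference column and are kept out of the site table (reported via the MSA's
insertion records).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from .align import AnchoredMsa, RegionPartition
from .io import PileupTable

__all__ = ["SnpSite", "ConcordanceSummary", "DetectionThresholds",
           "expected_variant_sites", "detected_variant_sites",
           "classify_concordance", "compare_major_props"]

_STATES = ("A", "C", "G", "T", "gap")


@dataclass(frozen=True)
class DetectionThresholds:
    """A pileup state is called only with count >= min_count AND frequency >=
    min_freq, at positions with depth >= min_depth.  Defaults suppress
    singleton sequencing errors while retaining sub-10% variants."""

    min_count: int = 2
    min_freq: float = 0.01
    min_depth: int = 10


@dataclass
class SnpSite:
    position: int  # 1-based on the reference amplicon
    region: str  # SSU | ITS | LSU
    region_position: int  # 1-based within the region
    expected_props: Optional[Dict[str, float]] = None
    detected_freqs: Optional[Dict[str, float]] = None
    status: str = "expected_only"

    def __post_init__(self):
        for props in (self.expected_props, self.detected_freqs):
            if props is not None:
                total = sum(props.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"site {self.position}: proportions sum "
                                     f"to {total}, not 1")


@dataclass
class ConcordanceSummary:
    sites: List[SnpSite]
    thresholds: DetectionThresholds

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def proportions(self) -> Dict[str, float]:
        if not self.sites:
            return {"both": 0.0, "expected_only": 0.0, "detected_only": 0.0}
        out = {s: 0 for s in ("both", "expected_only", "detected_only")}
        for site in self.sites:
            out[site.status] += 1
        return {k: v / self.n_sites for k, v in out.items()}

    def table(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            row = {"position": s.position, "region": s.region,
                   "region_position": s.region_position, "status": s.status}
            for st in _STATES:
                row[f"expected_{st}"] = (s.expected_props or {}).get(st, 0.0)
                row[f"detected_{st}"] = (s.detected_freqs or {}).get(st, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)


def expected_variant_sites(msa: AnchoredMsa, abundances: Mapping[str, float],
                           partition: RegionPartition) -> List[SnpSite]:
    """Variant sites expected from within-lineage ASVs, abundance-weighted.

    The MSA reference must be the most abundant ASV and participates as a
    member with its own abundance.  A reference column is expected-variable
    iff at least two distinct states (gap included) occur among members.
    """
    members = [msa.reference_id] + msa.member_ids
    missing = [m for m in members if m not in abundances]
    if missing:
        raise ValueError(f"abundance missing for member(s) {missing[:5]}")
    weights = {m: float(abundances[m]) for m in members}
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("total abundance is zero")
    sites: List[SnpSite] = []
    for pos in range(len(msa.reference)):
        states = msa.column(pos)
        if len(set(states)) < 2:
            continue
        props: Dict[str, float] = {}
        for member, st in zip(members, states):
            key = "gap" if st == "-" else st
            props[key] = props.get(key, 0.0) + weights[member] / total
        region, rel = partition.region_relative(pos)
        sites.append(SnpSite(position=pos + 1, region=region,
                             region_position=rel, expected_props=props,
                             status="expected_only"))
    return sites


def detected_variant_sites(pileup: PileupTable,
                           thresholds: DetectionThresholds = DetectionThresholds()
                           ) -> Tuple[Dict[int, Dict[str, float]], set]:
    """(position -> state frequencies at detected-variable positions, covered set).

    A position is detected-variable iff >= 2 states each pass the count and
    frequency thresholds at depth >= min_depth.  Frequencies are reported for
    passing and non-passing states alike (normalised by depth).  Positions
    below min_depth are left out of the covered set (uncovered).
    """
    variable: Dict[int, Dict[str, float]] = {}
    covered = set()
    df = pileup.rows
    for k in range(len(df)):
        depth = int(df["depth"].iat[k])
        if depth < thresholds.min_depth:
            continue
        pos = int(df["pos"].iat[k])
        covered.add(pos)
        counts = {"A": int(df["A"].iat[k]), "C": int(df["C"].iat[k]),
                  "G": int(df["G"].iat[k]), "T": int(df["T"].iat[k]),
                  "gap": int(df["del"].iat[k])}
        passing = sum(1 for c in counts.values()
                      if c >= thresholds.min_count
                      and c / depth >= thresholds.min_freq)
        if passing >= 2:
            variable[pos] = {st: c / depth for st, c in counts.items()
                             if c > 0}
    return variable, covered


def classify_concordance(expected: List[SnpSite],
                         detected: Mapping[int, Dict[str, float]],
                         partition: Optional[RegionPartition] = None,
                         thresholds: DetectionThresholds = DetectionThresholds()
                         ) -> ConcordanceSummary:
    """Union of expected- and detected-variable positions, classified per site.

    ``partition`` supplies region labels for detected-only positions (falls
    back to ``unknown`` when not given).
    """
    by_pos = {s.position: s for s in expected}
    sites: List[SnpSite] = []
    for pos in sorted(set(by_pos) | set(detected)):
        if pos in by_pos:
            site = by_pos[pos]
            if pos in detected:
                site.detected_freqs = dict(detected[pos])
                site.status = "both"
            else:
                site.status = "expected_only"
            sites.append(site)
        else:
            if partition is not None:
                region, rel = partition.region_relative(pos - 1)
            else:
                region, rel = "unknown", pos
            sites.append(SnpSite(position=pos, region=region,
                                 region_position=rel,
                                 detected_freqs=dict(detected[pos]),
                                 status="detected_only"))
    return ConcordanceSummary(sites, thresholds)


def compare_major_props(site: SnpSite) -> Tuple[List[str], List[float],
                                                List[float], float]:
    """State-aligned (states, expected, detected, total-variation distance).

    Only meaningful for sites with variation on both sides; calling this on
    a non-``both`` site is an error.
    """
    if site.status != "both":
        raise ValueError(f"site {site.position} has status {site.status!r}; "
                         "expected 'both'")
    states = [st for st in _STATES
              if site.expected_props.get(st, 0) > 0
              or site.detected_freqs.get(st, 0) > 0]
    exp = [site.expected_props.get(st, 0.0) for st in states]
    det = [site.detected_freqs.get(st, 0.0) for st in states]
    tv = 0.5 * sum(abs(e - d) for e, d in zip(exp, det))
    return states, exp, det, tv
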