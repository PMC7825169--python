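"""Per-lineage (OTU) ASV composition profiles, inclusion filters and dominance.

A lineage profile is the sub-table of ASV read counts for the members of one
OTU.  Samples contributing fewer than ``min_reads`` (default 20) reads to
the lineage are excluded from that lineage's downstream analysis; inclusion
is decided per lineage, so a sample may count for one lineage and not
another.  Dominant lineages are those ubiquitous (detected, with at least
one read, in at least ``min_samples`` samples — detection counted before the
read floor) and abundant (total reads at or above ``min_total_reads``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from .io import AsvTable, SampleMetadata

__all__ = ["LineageProfile", "DominanceStats", "build_profiles",
           "select_dominant_lineages", "dominance_stats", "regional_composition"]


@dataclass
class LineageProfile:
    otu_id: str
    counts: pd.DataFrame  # member ASV x all samples, integer
    included_samples: List[str]
    min_reads_filter: int = 20

    @property
    def member_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def included_counts(self) -> pd.DataFrame:
        return self.counts[self.included_samples]

    def n_detected_samples(self) -> int:
        """Samples with at least one read, before the read floor."""
        return int((self.counts.sum(axis=0) >= 1).sum())


@dataclass
class DominanceStats:
    """Per-sample proportions of the top-k most abundant member ASVs."""

    otu_id: str
    per_sample: pd.DataFrame  # index sample_id, columns top1/top2/top3
    means: pd.Series  # across included samples

    def __post_init__(self):
        ps = self.per_sample
        if not ((ps["top1"] <= ps["top2"] + 1e-12).all()
                and (ps["top2"] <= ps["top3"] + 1e-12).all()):
            raise AssertionError("top-k proportions are not monotone")


def build_profiles(table: AsvTable, otu_map: Mapping[str, str],
                   min_reads: int = 20) -> Dict[str, LineageProfile]:
    """One profile per OTU, with per-lineage sample inclusion at the read floor."""
    missing = [a for a in table.asv_ids if a not in otu_map]
    if missing:
        raise ValueError(f"otu_map does not cover ASV(s) {missing[:5]}")
    by_otu: Dict[str, List[str]] = {}
    for asv in table.asv_ids:
        by_otu.setdefault(otu_map[asv], []).append(asv)
    profiles: Dict[str, LineageProfile] = {}
    for otu_id, members in by_otu.items():
        counts = table.counts.loc[members]
        totals = counts.sum(axis=0)
        included = [s for s in counts.columns if totals[s] >= min_reads]
        profiles[otu_id] = LineageProfile(otu_id, counts, included, min_reads)
    return profiles


def select_dominant_lineages(profiles: Mapping[str, LineageProfile],
                             min_samples: int = 9,
                             min_total_reads: int = 301) -> List[str]:
    """OTUs detected in >= min_samples samples with >= min_total_reads reads.

    The defaults encode "detected in more than eight samples" and "more than
    300 reads".  Order: total reads descending, then otu_id.
    """
    chosen = [
        (p.total_reads, otu_id)
        for otu_id, p in profiles.items()
        if p.n_detected_samples() >= min_samples and p.total_reads >= min_total_reads
    ]
    return [otu_id for _reads, otu_id in
            sorted(chosen, key=lambda t: (-t[0], t[1]))]


def dominance_stats(profile: LineageProfile, ks=(1, 2, 3)) -> DominanceStats:
    """Proportion of lineage reads in the top-k member ASVs, per included sample."""
    if not profile.included_samples:
        raise ValueError(f"{profile.otu_id}: no samples pass the "
                         f"{profile.min_reads_filter}-read floor")
    rows = {}
    for s in profile.included_samples:
        col = profile.counts[s].to_numpy(dtype=float)
        total = col.sum()
        ordered = np.sort(col)[::-1]
        rows[s] = {f"top{k}": ordered[:k].sum() / total for k in ks}
    per_sample = pd.DataFrame.from_dict(rows, orient="index")
    per_sample.index.name = "sample_id"
    return DominanceStats(profile.otu_id, per_sample, per_sample.mean(axis=0))


def regional_composition(profile: LineageProfile,
                         metadata: Mapping[str, SampleMetadata],
                         grouping: str = "region",
                         included_only: bool = True) -> Dict[str, pd.Series]:
    """Pooled within-lineage ASV read shares per sample group.

    ``grouping`` is one of region / layer / lake (lake = lake_code).  Reads
    are pooled across the group's samples (included samples only by
    default); shares sum to 1 within every non-empty group.
    """
    attr = {"region": "region", "layer": "layer", "lake": "lake_code"}.get(grouping)
    if attr is None:
        raise ValueError(f"unknown grouping {grouping!r}")
    samples = profile.included_samples if included_only else list(profile.counts.columns)
    missing = [s for s in samples if s not in metadata]
    if missing:
        raise ValueError(f"metadata does not cover sample(s) {missing[:5]}")
    out: Dict[str, pd.Series] = {}
    groups: Dict[str, List[str]] = {}
    for s in samples:
        groups.setdefault(getattr(metadata[s], attr), []).append(s)
    for group, ids in groups.items():
        pooled = profile.counts[ids].sum(axis=1)
        total = pooled.sum()
        if total > 0:
            out[group] = pooled / total
    return out
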