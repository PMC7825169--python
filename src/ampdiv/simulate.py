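"""Ground-truthed simulator for biogeographically structured amplicon communities.

Generates what the analysis pipeline consumes: an ASV table of long 16S+ITS+
partial-23S amplicons with region- and layer-structured read counts across
lake samples, plus per-position pileups for SNP-concordance validation.  The
statistical structure mirrors the system the pipeline targets:

* a handful of deeply diverged lineage templates (16S identity separated by
  ``inter_lineage_divergence``, default 8%);
* 7-101 intra-lineage genotypes per lineage, each differing from the
  template by a few substitutions concentrated in the ITS, occasionally a
  1-bp indel (ITS only);
* three geographic regions of lakes sampled at two water layers, with
  genotype pools private to regions (``dispersal`` controls leakage) and a
  within-region abundance tilt between layers;
* per-sample mixtures drawn from a symmetric Dirichlet, read counts
  multinomial at uneven per-sample depths (log-uniform over 190-4515).

Everything is deterministic under (config, seed), and every emitted read
count traces to a genotype recorded in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import anchored_msa
from .io import (LAYERS, REGIONS, AsvTable, PileupTable, SampleMetadata,
                 load_bundled_references)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_templates",
           "simulate_genotypes", "simulate_community", "simulate_pileup"]

_BASES = np.array(list("ACGT"))
#: substitutions/indels keep clear of region boundaries so that
#: reference-anchored partitioning recovers the planted intervals exactly
#: (the flanks are primer-proximal and conserved in real operons too)
_BOUNDARY_MARGIN = 10


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_lineages: int = 11
    inter_lineage_divergence: float = 0.08
    genotypes_per_lineage: Tuple[int, int] = (7, 101)
    snps_per_genotype: Tuple[int, int] = (1, 6)
    its_bias: float = 0.8  # fraction of substitutions placed in the ITS
    indel_prob: float = 0.2  # probability of one extra 1-bp ITS indel
    regions: Tuple[str, ...] = REGIONS
    lakes_per_region: Tuple[int, ...] = (7, 3, 2)
    layers: Tuple[str, ...] = LAYERS
    dispersal: float = 0.05  # 0 = fully region-private genotype pools
    layer_bias: float = 0.8  # abundance weight share of a genotype's home layer
    dirichlet_alpha: float = 0.3
    depth_range: Tuple[int, int] = (190, 4515)
    its_length_range: Tuple[int, int] = (250, 500)
    error_rate: float = 0.005  # per-base, pileup simulation

    def __post_init__(self):
        for name in ("inter_lineage_divergence", "its_bias", "indel_prob",
                     "dispersal", "layer_bias", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("genotypes_per_lineage", "snps_per_genotype",
                     "depth_range", "its_length_range"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi:
                raise ValueError(f"{name}={lo, hi} is not a valid range")
        if len(self.lakes_per_region) != len(self.regions):
            raise ValueError("lakes_per_region must match regions")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")


@dataclass
class GenotypeTruth:
    genotype_id: str
    lineage_id: str
    sequence: str
    substitutions: List[Tuple[int, str, str]]  # (0-based pos, from, to)
    indel: Optional[Tuple[str, int, str]]  # (ins|del, 0-based pos, base)
    home_region: str
    home_layer: str
    asv_id: Optional[str] = None  # None when never observed in the table


@dataclass
class GroundTruth:
    config: SimulationConfig
    templates: Dict[str, str]
    #: lineage_id -> (ssu_end, lsu_start, length) of the template
    boundaries: Dict[str, Tuple[int, int, int]]
    genotypes: Dict[str, GenotypeTruth]
    #: sample_id -> genotype_id -> true mixture proportion
    mixtures: Dict[str, Dict[str, float]]
    depths: Dict[str, int]

    def lineage_of_asv(self) -> Dict[str, str]:
        return {g.asv_id: g.lineage_id for g in self.genotypes.values()
                if g.asv_id is not None}

    def genotype_of_asv(self) -> Dict[str, GenotypeTruth]:
        return {g.asv_id: g for g in self.genotypes.values()
                if g.asv_id is not None}


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    for p in positions:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_templates(cfg: SimulationConfig, rng: Optional[np.random.Generator]
                       = None) -> Tuple[Dict[str, str],
                                        Dict[str, Tuple[int, int, int]]]:
    """Lineage amplicon templates: mutated 16S + random ITS + mutated 23S fragment.

    Template 16S regions are pairwise separated by at least
    ``inter_lineage_divergence`` (checked, resampled on violation); ITS
    regions are independent random sequences per lineage; the 23S fragment
    keeps its primer-proximal ends intact.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ssu_ref, lsu_ref = load_bundled_references()
    n_sub = int(round(cfg.inter_lineage_divergence * len(ssu_ref)))
    if n_sub > len(ssu_ref) - 2 * _BOUNDARY_MARGIN:
        raise ValueError("inter_lineage_divergence infeasible for the 16S "
                         "reference length")
    templates: Dict[str, str] = {}
    boundaries: Dict[str, Tuple[int, int, int]] = {}
    ssu_regions: List[np.ndarray] = []
    interior = np.arange(_BOUNDARY_MARGIN, len(ssu_ref) - _BOUNDARY_MARGIN)
    min_diff = cfg.inter_lineage_divergence * len(ssu_ref)
    for k in range(cfg.n_lineages):
        for _attempt in range(200):
            positions = rng.choice(interior, size=n_sub, replace=False)
            ssu = _mutate(ssu_ref, positions, rng)
            arr = np.frombuffer(ssu.encode(), dtype=np.uint8)
            ok = all((arr != prev).sum() >= min_diff for prev in ssu_regions)
            if ok:
                break
        else:
            raise ValueError("could not realise the requested inter-lineage "
                             "divergence")
        ssu_regions.append(arr)
        its_len = int(rng.integers(cfg.its_length_range[0],
                                   cfg.its_length_range[1] + 1))
        its = "".join(rng.choice(_BASES, size=its_len))
        lsu_interior = np.arange(_BOUNDARY_MARGIN, len(lsu_ref) - 15)
        lsu_pos = rng.choice(lsu_interior, size=max(1, len(lsu_ref) // 50),
                             replace=False)
        lsu = _mutate(lsu_ref, lsu_pos, rng)
        lid = f"lineage_{k + 1}"
        templates[lid] = ssu + its + lsu
        boundaries[lid] = (len(ssu), len(ssu) + its_len, len(templates[lid]))
    return templates, boundaries


def simulate_genotypes(template: str, boundaries: Tuple[int, int, int],
                       cfg: SimulationConfig, rng: np.random.Generator,
                       n_genotypes: int, lineage_id: str = "lineage"
                       ) -> List[GenotypeTruth]:
    """Distinct intra-lineage genotypes: template + k substitutions (ITS-biased)
    and optionally one 1-bp ITS indel."""
    ssu_end, lsu_start, length = boundaries
    its_positions = np.arange(ssu_end + _BOUNDARY_MARGIN,
                              lsu_start - _BOUNDARY_MARGIN)
    other_positions = np.concatenate([
        np.arange(_BOUNDARY_MARGIN, ssu_end - _BOUNDARY_MARGIN),
        np.arange(lsu_start + _BOUNDARY_MARGIN, length - 15),
    ])
    space = 4 ** max(cfg.snps_per_genotype[1], 1)
    if n_genotypes > space:
        raise ValueError(f"{n_genotypes} distinct genotypes exceed the "
                         "mutational space of the configured SNP range")
    out: List[GenotypeTruth] = []
    seen = {template}
    for g in range(n_genotypes):
        for _attempt in range(500):
            k = int(rng.integers(cfg.snps_per_genotype[0],
                                 cfg.snps_per_genotype[1] + 1))
            subs: List[Tuple[int, str, str]] = []
            arr = list(template)
            chosen = set()
            for _ in range(k):
                pool = its_positions if rng.random() < cfg.its_bias \
                    else other_positions
                pos = int(pool[rng.integers(len(pool))])
                if pos in chosen:
                    continue
                chosen.add(pos)
                old = arr[pos]
                new = [b for b in "ACGT" if b != old][rng.integers(3)]
                arr[pos] = new
                subs.append((pos, old, new))
            indel = None
            if rng.random() < cfg.indel_prob:
                pos = int(its_positions[rng.integers(len(its_positions))])
                if rng.random() < 0.5:
                    indel = ("del", pos, arr[pos])
                    del arr[pos]
                else:
                    base = str(rng.choice(_BASES))
                    indel = ("ins", pos, base)
                    arr.insert(pos, base)
            seq = "".join(arr)
            if seq not in seen:
                seen.add(seq)
                break
        else:
            raise ValueError("could not generate the requested number of "
                             "distinct genotypes")
        out.append(GenotypeTruth(f"{lineage_id}_g{g + 1}", lineage_id, seq,
                                 subs, indel, home_region="", home_layer=""))
    return out


def _lake_codes(n: int, taken: set) -> List[str]:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    codes = []
    for a in alphabet:
        for b in alphabet:
            code = a + b
            if code not in taken:
                codes.append(code)
                taken.add(code)
            if len(codes) == n:
                return codes
    raise ValueError("too many lakes")


def simulate_community(cfg: SimulationConfig
                       ) -> Tuple[AsvTable, GroundTruth]:
    """Full community: templates, genotypes, structured counts, metadata, truth.

    Genotypes with zero reads across all samples are dropped from the ASV
    table (as in any real denoised table) but retained in the truth with
    ``asv_id=None``.  ASV ids are assigned by total-abundance rank.
    """
    rng = np.random.default_rng(cfg.seed)
    templates, boundaries = simulate_templates(cfg, rng)
    genotypes: Dict[str, GenotypeTruth] = {}
    for lid, template in templates.items():
        n_g = int(rng.integers(cfg.genotypes_per_lineage[0],
                               cfg.genotypes_per_lineage[1] + 1))
        for gt in simulate_genotypes(template, boundaries[lid], cfg, rng,
                                     n_g, lineage_id=lid):
            gt.home_region = cfg.regions[rng.integers(len(cfg.regions))]
            gt.home_layer = cfg.layers[rng.integers(len(cfg.layers))]
            genotypes[gt.genotype_id] = gt
    samples: List[SampleMetadata] = []
    taken: set = set()
    for region, n_lakes in zip(cfg.regions, cfg.lakes_per_region):
        year = 2017 if region == "Europe" else 2015
        for code in _lake_codes(n_lakes, taken):
            for layer in cfg.layers:
                samples.append(SampleMetadata(code + layer[0], code, region,
                                              layer, year))
    gids = list(genotypes)
    home_region = np.array([genotypes[g].home_region for g in gids])
    home_layer = np.array([genotypes[g].home_layer for g in gids])
    log_lo, log_hi = np.log(cfg.depth_range[0]), np.log(cfg.depth_range[1])
    mixtures: Dict[str, Dict[str, float]] = {}
    depths: Dict[str, int] = {}
    count_cols: Dict[str, np.ndarray] = {}
    for s in samples:
        in_region = home_region == s.region
        include = in_region.copy()
        if cfg.dispersal > 0:
            include |= (~in_region) & (rng.random(len(gids)) < cfg.dispersal)
        weights = rng.gamma(cfg.dirichlet_alpha, size=len(gids))
        weights *= np.where(home_layer == s.layer, cfg.layer_bias,
                            1 - cfg.layer_bias)
        weights *= include
        if weights.sum() == 0:  # degenerate pool; fall back to uniform in-region
            weights = in_region.astype(float)
        p = weights / weights.sum()
        depth = int(round(np.exp(rng.uniform(log_lo, log_hi))))
        counts = rng.multinomial(depth, p)
        mixtures[s.sample_id] = {g: float(pi) for g, pi in zip(gids, p) if pi > 0}
        depths[s.sample_id] = depth
        count_cols[s.sample_id] = counts
    matrix = np.column_stack([count_cols[s.sample_id] for s in samples])
    totals = matrix.sum(axis=1)
    observed = totals > 0
    rank = np.argsort(np.argsort(-(totals + 1e-9 * rng.random(len(gids)))))
    for idx, g in enumerate(gids):
        if observed[idx]:
            genotypes[g].asv_id = f"ASV_{rank[idx] + 1}"
    obs_order = sorted((i for i in range(len(gids)) if observed[i]),
                       key=lambda i: rank[i])
    asv_ids = [genotypes[gids[i]].asv_id for i in obs_order]
    counts = pd.DataFrame(matrix[obs_order], index=asv_ids,
                          columns=[s.sample_id for s in samples])
    table = AsvTable(counts=counts, samples=samples)
    table.attach_sequences({genotypes[gids[i]].asv_id: genotypes[gids[i]].sequence
                            for i in obs_order})
    truth = GroundTruth(cfg, templates, boundaries, genotypes, mixtures, depths)
    return table, truth


def simulate_pileup(true_mixture: Dict[str, float],
                    genotype_seqs: Dict[str, str], depth: int,
                    error_rate: float = 0.0,
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None,
                    reference_id: Optional[str] = None) -> PileupTable:
    """Per-position base-count pileup sampled from a genotype mixture.

    At each reference position, ``depth`` independent draws pick a genotype
    by mixture proportion; its base (in the coordinates of the most abundant
    genotype, the reference) is flipped uniformly to another base with
    probability ``error_rate``.  Deletions relative to the reference pass
    through as ``del`` counts (errors do not apply to deletions).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    total = sum(true_mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture sums to {total}, not 1")
    gids = sorted(true_mixture, key=lambda g: (-true_mixture[g], g))
    if reference_id is None:
        reference_id = gids[0]
    reference = genotype_seqs[reference_id]
    others = [g for g in gids if g != reference_id]
    msa = anchored_msa(reference, [genotype_seqs[g] for g in others],
                       member_ids=others, reference_id=reference_id)
    rows = {reference_id: reference}
    rows.update(msa.rows)
    L = len(reference)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
    base_of = np.array([[idx[rows[g][p]] for g in gids] for p in range(L)])
    mix = np.array([true_mixture[g] for g in gids])
    per_pos = rng.multinomial(depth, mix, size=L)  # L x n_genotypes
    counts = np.zeros((L, 5), dtype=np.int64)
    for j in range(len(gids)):
        n = per_pos[:, j]
        b = base_of[:, j]
        if error_rate > 0:
            errs = rng.binomial(n, error_rate)
            errs[b == 4] = 0  # deletions are not subject to base errors
            keep = n - errs
        else:
            errs = np.zeros(L, dtype=np.int64)
            keep = n
        np.add.at(counts, (np.arange(L), b), keep)
        if error_rate > 0 and errs.any():
            for p in np.nonzero(errs)[0]:
                targets = [t for t in range(4) if t != b[p]]
                spread = rng.multinomial(errs[p], [1 / 3] * 3)
                for t, c in zip(targets, spread):
                    counts[p, t] += c
    frame = pd.DataFrame({
        "pos": np.arange(1, L + 1),
        "A": counts[:, 0], "C": counts[:, 1], "G": counts[:, 2],
        "T": counts[:, 3], "del": counts[:, 4],
    })
    frame["depth"] = frame[["A", "C", "G", "T", "del"]].sum(axis=1)
    return PileupTable(reference_id, frame)
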