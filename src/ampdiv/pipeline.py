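"""End-to-end orchestration: inputs -> clusters -> profiles -> phylogeography.

``run_pipeline`` composes the stages in order — region partitioning, greedy
clustering of 16S regions at the OTU (97%) and SSU-ASV (100%) thresholds,
consensus representatives, global re-assignment, lineage profiles and
dominance statistics, per-lineage Bray-Curtis matrices, the cross-lineage
average, Ward.D2 dendrogram and cluster cut — writing every intermediate
plus a manifest recording the full configuration, package version and input
checksums.  Identical inputs and configuration yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .align import AberrantOperonError, partition_regions
from .cluster import cluster_consensus, greedy_cluster, map_to_centroids
from .io import (AsvTable, load_bundled_references, read_count_table,
                 read_fasta, read_pileup, write_fasta, write_matrix,
                 write_newick)
from .phylogeography import (average_matrices, bray_curtis_matrix, cut_tree,
                             ward_d2_linkage)
from .profiles import (build_profiles, dominance_stats, regional_composition,
                       select_dominant_lineages)
from .snp import (DetectionThresholds, classify_concordance,
                  detected_variant_sites, expected_variant_sites)
from .align import anchored_msa

logger = logging.getLogger("ampdiv")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_HEADER = f"# ampdiv {__version__}"


@dataclass
class PipelineConfig:
    fasta: str = ""
    counts: str = ""
    metadata: str = ""
    out_dir: str = "ampdiv_out"
    pileup: Optional[str] = None  # optional SNP-concordance input
    pileup_sample: Optional[str] = None  # sample whose ASVs define expectations
    pileup_lineage: Optional[str] = None  # default: most abundant OTU
    otu_identity: float = 0.97
    ssu_identity: float = 1.00
    min_sample_reads: int = 20
    dominant_min_samples: int = 9
    dominant_min_reads: int = 301
    normalize_bc: bool = True
    min_support: int = 1
    cut_k: int = 5
    min_its: int = 1
    snp_min_count: int = 2
    snp_min_freq: float = 0.01
    snp_min_depth: int = 10
    cluster_full_length: bool = False  # sensitivity flag: cluster 16S+ITS
    seed: int = 0

    def __post_init__(self):
        for name, lo, hi in (("otu_identity", 0, 1), ("ssu_identity", 0, 1),
                             ("snp_min_freq", 0, 1)):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        for name in ("min_sample_reads", "dominant_min_samples",
                     "dominant_min_reads", "cut_k", "snp_min_count",
                     "snp_min_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    out_dir: Path
    table: AsvTable
    ssu_regions: Dict[str, str]
    otu_clusters: object
    ssu_clusters: object
    otu_map: Dict[str, str]
    profiles: Dict[str, object]
    dominant: List[str]
    averaged: object
    tree: object
    cluster_labels: Dict[str, int]
    concordance: Optional[object] = None
    manifest: Dict = field(default_factory=dict)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        df.to_csv(fh, sep="\t", float_format="%.10g",
                  index_label=index_label)


def run_pipeline(cfg: PipelineConfig,
                 table: Optional[AsvTable] = None) -> PipelineResult:
    """Run every stage; ``table`` may be passed directly (tests, simulations)
    instead of being read from the configured paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    input_hashes = {}
    stage = "input"
    try:
        if table is None:
            table = read_count_table(cfg.counts, cfg.metadata)
            table.attach_sequences(read_fasta(cfg.fasta))
            input_hashes = {p: _sha256(p) for p in
                            (cfg.fasta, cfg.counts, cfg.metadata)}
        if table.sequences is None:
            raise ValueError("ASV table has no sequences attached")

        stage = "region partitioning"
        ssu_ref, lsu_ref = load_bundled_references()
        partitions = {}
        ssu_regions = {}
        for asv, seq in table.sequences.items():
            part = partition_regions(seq, ssu_ref, lsu_ref, asv_id=asv,
                                     min_its=cfg.min_its)
            partitions[asv] = part
            ssu_regions[asv] = seq if cfg.cluster_full_length \
                else seq[part.ssu[0]:part.ssu[1]]
        _write_tsv(pd.DataFrame(
            [{"asv_id": a, "ssu_start": p.ssu[0], "ssu_end": p.ssu[1],
              "its_start": p.its[0], "its_end": p.its[1],
              "lsu_start": p.lsu[0], "lsu_end": p.lsu[1]}
             for a, p in partitions.items()]).set_index("asv_id"),
            out / "regions.tsv")

        stage = "greedy clustering"
        abund = {a: int(table.counts.loc[a].sum()) for a in table.asv_ids}
        otu_clusters = greedy_cluster(ssu_regions, abund, cfg.otu_identity,
                                      prefix="OTU_")
        ssu_clusters = greedy_cluster(ssu_regions, abund, cfg.ssu_identity,
                                      prefix="SSU_")
        logger.info("clustered %d ASVs into %d OTUs and %d SSU-ASVs",
                    len(table.asv_ids), len(otu_clusters.centroids),
                    len(ssu_clusters.centroids))

        stage = "consensus representatives"
        members = otu_clusters.members()
        consensus = {cid: cluster_consensus(
            {a: ssu_regions[a] for a in asvs}, abund)
            for cid, asvs in members.items()}
        write_fasta(consensus, out / "otu_consensus.fasta")

        stage = "re-assignment"
        otu_assign = map_to_centroids(ssu_regions, otu_clusters)
        ssu_assign = map_to_centroids(ssu_regions, ssu_clusters)
        rows = []
        for a in table.asv_ids:
            rows.append({"asv_id": a,
                         "otu": otu_assign[a][0] or "unassigned",
                         "otu_identity": otu_assign[a][1],
                         "ssu_asv": ssu_assign[a][0] or "unassigned",
                         "ssu_identity": ssu_assign[a][1]})
        _write_tsv(pd.DataFrame(rows).set_index("asv_id"), out / "cluster_map.tsv")
        otu_map = {a: (otu_assign[a][0] or otu_clusters.otu_map()[a])
                   for a in table.asv_ids}

        stage = "lineage profiles"
        profiles = build_profiles(table, otu_map, cfg.min_sample_reads)
        dominant = select_dominant_lineages(profiles, cfg.dominant_min_samples,
                                            cfg.dominant_min_reads)
        (out / "profiles").mkdir(exist_ok=True)
        for otu_id, prof in profiles.items():
            _write_tsv(prof.counts, out / "profiles" / f"{otu_id}.tsv",
                       index_label="asv_id")
        (out / "dominant_lineages.txt").write_text(
            _HEADER + "\n" + "".join(f"{o}\n" for o in dominant))
        dom_rows = []
        for otu_id in dominant:
            st = dominance_stats(profiles[otu_id])
            dom_rows.append({"otu_id": otu_id,
                             "total_reads": profiles[otu_id].total_reads,
                             "n_included_samples":
                                 len(profiles[otu_id].included_samples),
                             **{k: st.means[k] for k in st.means.index}})
        if dom_rows:
            _write_tsv(pd.DataFrame(dom_rows).set_index("otu_id"),
                       out / "dominance.tsv")

        stage = "dissimilarity"
        (out / "bc").mkdir(exist_ok=True)
        matrices = []
        for otu_id in dominant:
            prof = profiles[otu_id]
            if len(prof.included_samples) < 2:
                logger.warning("lineage %s has <2 included samples; skipped "
                               "from the average", otu_id)
                continue
            m = bray_curtis_matrix(prof, normalize=cfg.normalize_bc)
            matrices.append(m)
            write_matrix(m.sample_ids, m.values, out / "bc" / f"{otu_id}.tsv")
        if not matrices:
            raise ValueError("no lineage had >= 2 included samples")
        averaged = average_matrices(matrices, cfg.min_support)
        write_matrix(averaged.sample_ids, averaged.values,
                     out / "bc_averaged.tsv", support=averaged.support)

        stage = "hierarchical clustering"
        complete = averaged
        if not averaged.is_complete:
            import numpy as np

            # peel off the worst-covered samples until every pair has support
            keep = list(averaged.sample_ids)
            values = averaged.values.copy()
            while len(keep) > 2:
                missing = np.isnan(values).sum(axis=1)
                if missing.max() == 0:
                    break
                worst = int(np.argmax(missing))
                keep.pop(worst)
                values = np.delete(np.delete(values, worst, 0), worst, 1)
            logger.warning("averaged matrix has missing pairs; clustering %d "
                           "of %d samples", len(keep), len(averaged.sample_ids))
            complete = averaged.submatrix(keep)
        tree = ward_d2_linkage(complete)
        write_newick(tree, complete.sample_ids, out / "tree.nwk")
        k = min(cfg.cut_k, tree.n_leaves)
        leaf_labels = cut_tree(tree, k)
        cluster_labels = {complete.sample_ids[i]: lab
                          for i, lab in leaf_labels.items()}
        _write_tsv(pd.DataFrame(
            sorted(cluster_labels.items()), columns=["sample_id", "cluster"]
        ).set_index("sample_id"), out / "sample_clusters.tsv")

        concordance = None
        if cfg.pileup:
            stage = "snp concordance"
            concordance = _snp_stage(cfg, table, profiles, dominant, partitions,
                                     out)

        stage = "manifest"
        manifest = {
            "ampdiv_version": __version__,
            "config": asdict(cfg),
            "inputs_sha256": input_hashes,
            "n_asvs": len(table.asv_ids),
            "n_samples": len(table.sample_ids),
            "n_otus": len(otu_clusters.centroids),
            "n_ssu_asvs": len(ssu_clusters.centroids),
            "n_dominant": len(dominant),
            "outputs_sha256": {p.name: _sha256(p) for p in sorted(out.glob("*"))
                               if p.is_file()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return PipelineResult(out, table, ssu_regions, otu_clusters, ssu_clusters,
                          otu_map, profiles, dominant, averaged, tree,
                          cluster_labels, concordance, manifest)


def _snp_stage(cfg: PipelineConfig, table: AsvTable, profiles, dominant,
               partitions, out: Path):
    """Expected-vs-detected SNP concordance for one lineage in one sample."""
    pileup = read_pileup(cfg.pileup)
    lineage = cfg.pileup_lineage or (dominant[0] if dominant else None)
    if lineage is None or lineage not in profiles:
        raise ValueError(f"no lineage available for SNP concordance "
                         f"({cfg.pileup_lineage!r})")
    prof = profiles[lineage]
    sample = cfg.pileup_sample
    if sample is None:
        sample = prof.sample_totals().idxmax()
    col = prof.counts[sample]
    present = [a for a in prof.member_ids if col[a] > 0]
    if not present:
        raise ValueError(f"lineage {lineage} absent from sample {sample}")
    abund = {a: int(col[a]) for a in present}
    ref = max(present, key=lambda a: (abund[a], a))
    others = [a for a in present if a != ref]
    msa = anchored_msa(table.sequences[ref],
                       [table.sequences[a] for a in others],
                       member_ids=others, reference_id=ref)
    expected = expected_variant_sites(msa, abund, partitions[ref])
    thresholds = DetectionThresholds(cfg.snp_min_count, cfg.snp_min_freq,
                                     cfg.snp_min_depth)
    detected, _covered = detected_variant_sites(pileup, thresholds)
    summary = classify_concordance(expected, detected, partitions[ref],
                                   thresholds)
    props = summary.proportions()
    with open(out / "concordance.tsv", "w") as fh:
        fh.write(_HEADER + f" (lineage {lineage}, sample {sample}, "
                 f"reference {ref}, thresholds {asdict(thresholds)})\n")
        fh.write(f"# n_sites\t{summary.n_sites}\n")
        for k in ("both", "expected_only", "detected_only"):
            fh.write(f"# {k}\t{props[k]:.4f}\n")
        summary.table().to_csv(fh, sep="\t", index=False, float_format="%.6g")
    return summary
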