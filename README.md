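# ampdiv

Intra-lineage microdiversity and phylogeography analysis for long-read rRNA
amplicons.

## The problem

Near-full-length 16S rRNA + ITS amplicons (~2 kb, from circular-consensus
long reads) resolve bacterioplankton diversity below the species level: the
16S gene places an amplicon sequence variant (ASV) in a lineage, while the
hypervariable internal transcribed spacer (ITS) separates genotypes that are
identical — or nearly so — across the whole 16S gene.  Given a denoised ASV
table from lake samples spanning geographic regions and water layers
(epilimnion / hypolimnion), `ampdiv` answers three questions:

1. How much sequence-level microdiversity does each lineage harbour?
2. Do within-lineage genotype compositions show phylogeographic structure?
3. Are the variants called from ASVs real, i.e. are they re-detected in
   shotgun metagenomic reads from the same habitat?

## What it computes

* **Region partitioning** — each amplicon is split into its 16S (SSU), ITS
  and partial 23S (LSU) spans by overlap alignment against reference
  sequences (synthetic stand-ins are bundled; replaceable).
* **Dual-threshold greedy clustering** — extracted 16S regions are clustered
  greedily in (length, abundance) order at 97% identity into lineage-level
  OTUs and at 100% into SSU-ASVs, with identity defined as matching columns
  over alignment columns excluding terminal gaps; majority-rule consensus
  representatives; and a best-hit re-assignment pass.  The alignment core is
  an affine-gap Needleman–Wunsch (Gotoh) with fixed tie-breaking, so results
  are bit-reproducible.
* **Lineage profiles and dominance** — per-OTU ASV×sample count profiles
  with a per-lineage 20-read sample floor; dominant-lineage selection
  (detected in >8 samples, >300 reads); top-k ASV dominance statistics.
* **Phylogeography** — per-lineage Bray–Curtis dissimilarity
  `BC = 1 − 2·Σmin(aᵢ,bᵢ)/(Σaᵢ+Σbᵢ)` on within-lineage ASV proportions
  (equal to half the L1 distance), averaged entry-wise across dominant
  lineages with per-pair support, then Ward.D2 agglomerative clustering
  (Lance–Williams update on unsquared dissimilarities) with a deterministic
  tie rule, Newick export and a k-cluster cut.
* **SNP concordance** — abundance-weighted variant sites expected from a
  lineage's ASVs (reference-anchored MSA) versus variants detected in a
  per-position base-count pileup (TSV or SAM), each site classified as
  expected-only / detected-only / both, with total-variation distances for
  shared sites.
* **Simulation** — a ground-truthed generator of structured communities
  (diverged lineage templates, ITS-biased genotype mutations, region-private
  genotype pools with dispersal and layer bias, Dirichlet-multinomial counts
  at uneven depths, error-bearing pileups) so every stage is testable
  without downloads.

## Worked example

```python
from ampdiv.simulate import SimulationConfig, simulate_community
from ampdiv.pipeline import PipelineConfig, run_pipeline
from ampdiv.profiles import dominance_stats

cfg = SimulationConfig(seed=7, n_lineages=3, genotypes_per_lineage=(4, 8),
                       lakes_per_region=(2, 1, 1), depth_range=(150, 600))
table, truth = simulate_community(cfg)
res = run_pipeline(PipelineConfig(out_dir="example_out",
                                  dominant_min_samples=4,
                                  dominant_min_reads=50, cut_k=3), table=table)
print(f"{len(table.asv_ids)} ASVs in {len(table.sample_ids)} samples")
print(f"OTUs (97%): {len(res.otu_clusters.centroids)}   "
      f"SSU-ASVs (100%): {len(res.ssu_clusters.centroids)}")
for otu in res.dominant:
    st = dominance_stats(res.profiles[otu])
    print(f"  {otu}: {res.profiles[otu].total_reads} reads, "
          f"mean top-1 ASV share {st.means['top1']:.1%}")
```

prints

```
16 ASVs in 8 samples
OTUs (97%): 3   SSU-ASVs (100%): 11
  OTU_1: 1436 reads, mean top-1 ASV share 88.4%
  OTU_3: 1036 reads, mean top-1 ASV share 76.4%
  OTU_2: 548 reads, mean top-1 ASV share 86.2%
```

The three planted lineages are recovered exactly as the three 97% OTUs; the
11 SSU-ASVs reflect genotypes whose mutations fell in the 16S region; within
each lineage a single genotype dominates most samples (the simulated
communities are uneven), and `res.cluster_labels` holds the cut of the
averaged Bray–Curtis dendrogram.  `example_out/` contains every intermediate
(cluster map, profiles, matrices, `tree.nwk`, `manifest.json`).

The same stages are available from the shell:

```bash
ampdiv simulate --seed 7 --out sim/
ampdiv run --config pipeline.yaml
ampdiv cluster --fasta sim/asv.fa --counts sim/counts.tsv \
    --metadata sim/meta.tsv --threshold 0.97 --out otu_map.tsv
```

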