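# Methods

## Scope and data model

`ampdiv` analyses a denoised table of long amplicon sequence variants
(ASVs): near-full-length 16S rRNA gene + internal transcribed spacer (ITS) +
a short 23S fragment, primer-trimmed, with integer read counts per sample
and sample metadata (lake, region ∈ {Honshu-Kyushu, Hokkaido, Europe},
layer ∈ {epilimnion, hypolimnion}, year).  Denoising, taxonomy and read
mapping are upstream; the pipeline consumes their outputs (FASTA, TSV, SAM)
and never resamples or rarefies — uneven sequencing depth is handled by
proportion-based dissimilarities and a per-lineage read floor instead.

Coordinates: all external positions (pileups, reported SNP sites) are
1-based inclusive; all internal intervals are 0-based half-open.

## Alignment core

Pairwise alignment is an affine-gap Needleman–Wunsch (Gotoh) with defaults
match +2, mismatch −3, gap open −5, gap extend −2 (a gap of length L costs
5 + 2L).  Identity of near-identical rRNA amplicons is insensitive to the
exact scheme; the values are configurable.  Co-optimal alignments are
resolved deterministically — diagonal over gap, gap in the second sequence
over gap in the first; overlap alignments prefer the smallest terminal
overhang — so every downstream artefact is bit-reproducible.  The
`sequence_identity` convenience additionally canonicalises the argument
order before aligning, making identity exactly symmetric.

**Identity definition.**  Identity = matching columns / alignment columns
excluding terminal-gap columns; internal gaps count against identity.  This
matches the default semantics of greedy centroid clustering tools.  Two
caveats follow directly from the definition: a flush substring of a longer
sequence scores identity 1.0, and so does any perfect overlap (e.g. `ACAC`
vs `CACA`).  For the intended inputs — same-primer amplicons of similar
length — these cases do not arise, but `identity == 1` is *not* a test of
sequence equality in general.

**Region partitioning.**  The 16S span is located by overlap alignment of a
full-length 16S reference (free terminal gaps on both sequences) and clamped
to the amplicon start; the 23S span by overlap alignment of a ~110-nt 23S
5′-fragment reference against the amplicon tail, extended to the amplicon
end; the ITS is the remainder.  An empty or negative ITS, or an amplicon
shorter than 80% of the 16S reference, is flagged as a putative
unlinked/aberrant operon.  The bundled references are synthetic stand-ins
generated with a fixed seed (files `synthetic_ssu_ref.fasta`,
`synthetic_lsu_frag.fasta`); they are not biological rRNA sequences and
should be replaced with real references (e.g. a curated full-length 16S and
the 5′ end of the cognate 23S) when analysing real amplicons.  With real
references, boundary placement may differ by a few bases from extraction
based on curated-database alignment (e.g. SINA against SILVA);
region-relative SNP labels inherit that uncertainty.

## Clustering

Greedy centroid clustering processes extracted 16S regions in (length desc,
total abundance desc, ASV id asc) order; each sequence joins the *first*
centroid with identity ≥ threshold (creation order), else founds a new
centroid.  97% defines lineage-level OTUs; 100% defines SSU-ASVs.  At 100%,
identity can only reach 1.0 when one sequence is a contiguous substring of
the other, which is used as an exact shortcut.  Identical sequences provably
make identical join decisions, so they are grouped up front and decided
once.  Re-assignment (`map_to_centroids`) instead takes the *best* centroid
≥ threshold with ties to the earlier centroid, mirroring a global search
against a fixed centroid database; on well-separated lineages the two rules
agree, which the tests assert on synthetic data.  Consensus representatives
are majority-rule over a reference-anchored MSA (reference = most abundant
member): column ties break alphabetically A<C<G<T, a strict gap majority
deletes the column, and insertions are kept when more than half of all
members carry the identical inserted string.  Clustering full amplicons
(16S+ITS) is available behind a flag for sensitivity analysis.

## Lineage profiles, the read floor, dominance

For each OTU, samples contributing < 20 reads to that OTU are excluded from
its downstream analysis; inclusion is decided per lineage.  Dominant
lineages are those detected (≥ 1 read, counted *before* the floor) in at
least 9 samples with at least 301 total reads ("more than eight samples",
"more than 300 reads"); both knobs are configurable.  Dominance statistics
(top-1/2/3 ASV share) are proportions per included sample, averaged over
included samples only — excluded samples leave all subsequent analysis, so
sparse (e.g. single-region) lineages are averaged over the samples where
they actually pass the floor.

## Phylogeography

Per-lineage Bray–Curtis dissimilarity is computed on within-lineage ASV
*proportions* by default (`BC = ½·Σ|aᵢ−bᵢ|`), which removes depth effects
given the 190–4515-read depth spread; raw-count mode is retained for
sensitivity analysis.  The cross-lineage matrix averages entries over the
lineages in which *both* samples pass the floor, recording per-pair support;
pairs below `min_support` are missing.  This support mask is the
least-assumption treatment of samples absent from a lineage — the
alternative (imputing 1.0 for absent lineages) would conflate absence with
maximal turnover.  Ward.D2 linkage uses the Lance–Williams update on
unsquared dissimilarities,

    d(i∪j,k) = sqrt[((nᵢ+nₖ)d²ᵢₖ + (nⱼ+nₖ)d²ⱼₖ − nₖd²ᵢⱼ) / (nᵢ+nⱼ+nₖ)],

merging the globally minimal pair with ties broken by the smallest
(node_a, node_b) index pair.  Clustering refuses incomplete matrices; the
pipeline first peels off the worst-covered samples until the matrix is
complete and reports how many were dropped.  Newick output places each
internal node at elevation `merge height / 2` (two leaves merged at height h
appear as `(A:h/2,B:h/2);`).  Tree cutting removes the k−1 highest merges
and numbers cluster labels by first-leaf order.

## SNP concordance

Expected variant sites are the reference-anchored MSA columns (reference =
most abundant ASV of the lineage in the chosen sample) with ≥ 2 states among
members, gaps included; state proportions are abundance-weighted.  Detected
sites come from a per-position pileup: a position is variable when ≥ 2
states each reach count ≥ 2 *and* frequency ≥ 1% at depth ≥ 10.  No single
field standard exists for these thresholds — visual inspection tools do
not define one — so they were chosen to suppress singleton sequencing errors
while retaining sub-10% variants, are configurable, and are printed in every
report header.  Sites in the union are classified both / expected-only /
detected-only; shared sites get a total-variation distance between the two
distributions.  Deletions in the pileup map to the MSA gap state; ASV
insertions relative to the reference have no pileup column and are reported
via the MSA insertion records instead of being forced into the site table.
SAM tallies count primary, non-duplicate alignments by default (mapping
quality configurable), deletions as `del`, insertions ignored.

## Simulator

The generator emulates the structure the analysis assumes, with defaults set
to the study design the pipeline targets:

| parameter | default | meaning |
|---|---|---|
| `n_lineages` | 11 | dominant lineage templates |
| `inter_lineage_divergence` | 0.08 | minimum pairwise 16S divergence of templates |
| `genotypes_per_lineage` | 7–101 | intra-lineage genotypes (uniform draw) |
| `snps_per_genotype` | 1–6 | substitutions per genotype, 80% placed in ITS |
| `indel_prob` | 0.2 | chance of one extra 1-bp ITS indel |
| `regions` / `lakes_per_region` | 3 regions, (7,3,2) lakes | 24 samples with both layers |
| `dispersal` | 0.05 | per-sample leakage of out-of-region genotypes (0 = private pools) |
| `layer_bias` | 0.8 | abundance weight share of a genotype's home layer |
| `dirichlet_alpha` | 0.3 | evenness of per-sample mixtures |
| `depth_range` | 190–4515 | per-sample reads, log-uniform |
| `error_rate` | 0.005 | per-base error in pileup simulation |

Templates are the bundled 16S reference mutated at the divergence rate
(pairwise separation checked and enforced), a random 250–500-nt ITS, and a
lightly mutated 23S fragment whose primer-proximal ends are kept intact.
Genotype substitutions and indels avoid 10 bp around region boundaries and
indels are confined to the ITS — the biological reading is conserved
primer-proximal flanks; the practical consequence is that reference-anchored
partitioning recovers planted boundaries exactly, which the tests rely on.
Layer structure is an abundance tilt rather than private per-layer pools:
fully layer-private pools would make all region×layer groups mutually
dissimilarity-1 and a k = n_regions cut ill-defined.  Per-sample mixtures
are symmetric-Dirichlet draws over the sample's pool, counts are multinomial
at a log-uniform depth, and ASV ids are assigned by total-abundance rank
with unobserved genotypes kept in the ground truth only.  Everything is
deterministic under (config, seed).

What the simulator does **not** model: PCR/chimera artefacts, rate
heterogeneity beyond the ITS bias, unlinked rRNA operons, read-level errors
in the amplicon table (the table is treated as perfectly denoised), and
phylogenetic signal inside templates (they are random mutations of one
backbone).  Passing tests therefore demonstrate correctness of the
*analysis* under its stated assumptions, not robustness of the upstream
denoising, and real-data cluster counts remain sensitive to identity
definition and input-ordering choices in a way synthetic recovery cannot
probe.

## Numerical and testing conventions

Problem sizes in the test suite and acceptance script are deliberately
small-to-moderate (communities of 2–11 lineages, 8–24 samples; 500 short
alignment-oracle pairs; 100 random 8×8 linkage matrices; pileups at depth
10⁴): they are the sizes at which the independent oracles — exhaustive
alignment enumeration, an independent Ward implementation, binomial
concordance bounds — are exact or tight.  Alignment scores are integers;
linkage heights are compared to oracles at 1e-10; matrix round-trips hold to
at least 12 decimals; Bray–Curtis values are validated against the half-L1
closed form.  Degenerate inputs fail loudly: empty sequences, incomplete
dissimilarity matrices, lineages with no included samples and out-of-range
cuts are errors, and an empty pileup file is an empty (not invalid) table.
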