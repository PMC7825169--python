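"""Readers and writers for every external artifact of the pipeline.

Formats: FASTA (sequences), TSV (count tables, sample metadata, pileups,
dissimilarity matrices, reports), SAM (optional pileup source) and Newick
(dendrograms).  All writers emit a ``# ampdiv <version>`` comment line.

Coordinate conventions: external positions (pileups, reported SNP sites) are
1-based inclusive; internal intervals are 0-based half-open.  Every reader
rejects malformed input with a located error; there is no silent coercion.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

__all__ = [
    "REGIONS",
    "LAYERS",
    "SampleMetadata",
    "AsvTable",
    "PileupTable",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "read_count_table",
    "write_count_table",
    "read_pileup",
    "write_pileup",
    "pileup_from_sam",
    "read_matrix",
    "write_matrix",
    "write_newick",
    "load_bundled_references",
]

REGIONS = ("Honshu-Kyushu", "Hokkaido", "Europe")
LAYERS = ("epilimnion", "hypolimnion")

_IUPAC_EXTRA = set("RYSWKMBDHVN")
_HEADER = f"# ampdiv {__version__}"


@dataclass(frozen=True)
class SampleMetadata:
    """One sample: a lake and water layer, e.g. ``BIh`` = Lake Biwa hypolimnion."""

    sample_id: str
    lake_code: str
    region: str
    layer: str
    year: int

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"sample {self.sample_id}: unknown region "
                             f"{self.region!r} (expected one of {REGIONS})")
        if self.layer not in LAYERS:
            raise ValueError(f"sample {self.sample_id}: unknown layer "
                             f"{self.layer!r} (expected one of {LAYERS})")


@dataclass
class AsvTable:
    """ASV sequences plus an ASV x sample read-count matrix with metadata."""

    counts: pd.DataFrame  # index asv_id, columns sample_id, integer
    samples: List[SampleMetadata]
    sequences: Optional[Dict[str, str]] = None
    #: ASV ids whose sequences contained IUPAC ambiguity codes on read
    ambiguous_ids: set = field(default_factory=set)

    def __post_init__(self):
        self.validate()

    @property
    def asv_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts.columns)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.samples]).set_index("sample_id")

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate asv_id {dup!r} in count table")
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            raise ValueError("count table is not integer-valued")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts in table")
        meta_ids = [s.sample_id for s in self.samples]
        if len(set(meta_ids)) != len(meta_ids):
            raise ValueError("duplicate sample_id in metadata")
        if list(self.counts.columns) != meta_ids:
            raise ValueError("count table columns do not match metadata order")
        if self.sequences is not None:
            missing = [a for a in self.counts.index if a not in self.sequences]
            if missing:
                raise ValueError(f"no sequence for ASV(s) {missing[:5]}")
            for a in self.counts.index:
                if len(self.sequences[a]) < 1:
                    raise ValueError(f"empty sequence for ASV {a}")

    def attach_sequences(self, sequences: Dict[str, str]) -> None:
        self.sequences = {a: sequences[a] for a in self.counts.index}
        self.ambiguous_ids = {a for a, s in self.sequences.items()
                              if set(s) & _IUPAC_EXTRA}
        self.validate()


@dataclass
class PileupTable:
    """Per-position base counts {A,C,G,T,deletion} on one reference sequence."""

    reference_id: str
    rows: pd.DataFrame  # columns: pos (1-based), A, C, G, T, del, depth

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len(self.rows) == 0:
            return
        required = ["pos", "A", "C", "G", "T", "del", "depth"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise ValueError(f"pileup missing column(s) {missing}")
        sums = self.rows[["A", "C", "G", "T", "del"]].sum(axis=1)
        bad = self.rows.index[sums != self.rows["depth"]]
        if len(bad):
            pos = self.rows.loc[bad[0], "pos"]
            raise ValueError(f"pileup depth mismatch at position {pos}")
        pos = self.rows["pos"].to_numpy()
        if (np.diff(pos) <= 0).any():
            k = int(np.argmax(np.diff(pos) <= 0))
            raise ValueError(f"pileup positions not strictly increasing near "
                             f"position {pos[k]}")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> Dict[str, str]:
    """FASTA -> {id: sequence}; uppercased, U normalised to T.

    The id is the header token before the first whitespace.  Duplicate ids
    and empty records are hard errors.
    """
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = seq
    return out


def write_fasta(sequences: Dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Metadata and count tables

def read_metadata(path) -> List[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["sample_id", "lake_code", "region", "layer", "year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing column(s) {missing}")
    samples = [SampleMetadata(r.sample_id, r.lake_code, r.region, r.layer,
                              int(r.year)) for r in df.itertuples()]
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample_id in metadata")
    return samples


def write_metadata(samples: Sequence[SampleMetadata], path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        pd.DataFrame([vars(s) for s in samples]).to_csv(fh, sep="\t", index=False)


def read_count_table(path, metadata_path) -> AsvTable:
    """TSV count table (first column asv_id, columns sample_ids) + metadata TSV.

    Metadata must cover every sample column; columns are reordered to the
    metadata order (restricted to samples present in the table).  Non-integer
    cells are rejected with their row/column location.
    """
    samples = read_metadata(metadata_path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    meta_ids = [s.sample_id for s in samples]
    unknown = [c for c in df.columns if c not in meta_ids]
    if unknown:
        raise ValueError(f"{path}: sample(s) {unknown} not present in metadata")
    parsed = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            parsed[col] = df[col].astype(np.int64)
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_mask = coerced.isna() | (coerced % 1 != 0)
            bad = df.index[bad_mask][0] if bad_mask.any() else df.index[0]
            raise ValueError(f"{path}: non-integer count at row {bad!r}, "
                             f"column {col!r}") from None
    keep = [s for s in samples if s.sample_id in parsed.columns]
    parsed = parsed[[s.sample_id for s in keep]]
    return AsvTable(counts=parsed, samples=keep)


def write_count_table(table: AsvTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        table.counts.rename_axis("asv_id").to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Pileups

def read_pileup(path) -> PileupTable:
    """In-repo pileup dialect: TSV with columns ref, pos, A, C, G, T, del.

    Positions are 1-based.  An empty file yields an empty PileupTable.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["ref", "pos", "A", "C", "G", "T", "del"],
                     header=None, dtype={"ref": str})
    if df.empty:
        return PileupTable("", pd.DataFrame(
            columns=["pos", "A", "C", "G", "T", "del", "depth"]))
    first_pos = pd.to_numeric(pd.Series([df.iloc[0]["pos"]]), errors="coerce")
    if first_pos.isna().iloc[0]:  # optional header row
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            return PileupTable("", pd.DataFrame(
                columns=["pos", "A", "C", "G", "T", "del", "depth"]))
    if df["ref"].nunique() > 1:
        raise ValueError(f"{path}: pileup spans multiple references "
                         f"{sorted(df['ref'].unique())}")
    ref = df.iloc[0]["ref"]
    rows = df[["pos", "A", "C", "G", "T", "del"]].astype(np.int64)
    rows["depth"] = rows[["A", "C", "G", "T", "del"]].sum(axis=1)
    return PileupTable(ref, rows.reset_index(drop=True))


def write_pileup(pileup: PileupTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + " (positions 1-based)\n")
        out = pileup.rows[["pos", "A", "C", "G", "T", "del"]].copy()
        out.insert(0, "ref", pileup.reference_id)
        out.to_csv(fh, sep="\t", index=False, header=False)


def pileup_from_sam(sam_path, reference_id: Optional[str] = None,
                    min_mapq: int = 0, include_secondary: bool = False,
                    include_duplicates: bool = False) -> PileupTable:
    """Tally per-position base counts from a SAM file.

    Only primary, non-duplicate alignments are counted by default (mapping
    quality and those filters are configurable).  A deletion spanning a
    position counts as ``del``; insertions have no reference column and are
    ignored.  Positions are reported 1-based; zero-depth positions are
    omitted.
    """
    import pysam

    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        refs = list(sam.references)
        if reference_id is None:
            if len(refs) != 1:
                raise ValueError(f"{sam_path}: multiple references {refs}; "
                                 "specify reference_id")
            reference_id = refs[0]
        elif reference_id not in refs:
            raise ValueError(f"{sam_path}: reference {reference_id!r} not in header")
        length = sam.get_reference_length(reference_id)
        counts = np.zeros((length, 5), dtype=np.int64)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name != reference_id:
                continue
            if read.is_secondary and not include_secondary:
                continue
            if read.is_supplementary and not include_secondary:
                continue
            if read.is_duplicate and not include_duplicates:
                continue
            if read.mapping_quality < min_mapq:
                continue
            pos = read.reference_start
            qseq = read.query_sequence or ""
            qpos = 0
            for op, n in read.cigartuples or []:
                if op in (0, 7, 8):  # M, =, X
                    for k in range(n):
                        base = qseq[qpos + k].upper()
                        if base in idx:
                            counts[pos + k, idx[base]] += 1
                    pos += n
                    qpos += n
                elif op == 2:  # D
                    counts[pos:pos + n, 4] += 1
                    pos += n
                elif op == 3:  # N
                    pos += n
                elif op in (1, 4):  # I, S consume query only
                    qpos += n
    covered = counts.sum(axis=1) > 0
    rows = pd.DataFrame({
        "pos": np.nonzero(covered)[0] + 1,
        "A": counts[covered, 0], "C": counts[covered, 1],
        "G": counts[covered, 2], "T": counts[covered, 3],
        "del": counts[covered, 4],
    })
    rows["depth"] = rows[["A", "C", "G", "T", "del"]].sum(axis=1)
    return PileupTable(reference_id, rows)


# ---------------------------------------------------------------------------
# Matrices and trees

def write_matrix(sample_ids: Sequence[str], values: np.ndarray, path,
                 support: Optional[np.ndarray] = None) -> None:
    """Labeled square TSV at full precision (missing entries as NA)."""
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        pd.DataFrame(values, index=sample_ids, columns=sample_ids).to_csv(
            fh, sep="\t", float_format="%.15g", na_rep="NA")
    if support is not None:
        spath = Path(str(path)).with_suffix(".support.tsv")
        with open(spath, "w") as fh:
            fh.write(_HEADER + " (per-pair contributing lineages)\n")
            pd.DataFrame(support, index=sample_ids, columns=sample_ids).to_csv(
                fh, sep="\t")


def read_matrix(path) -> Tuple[List[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: matrix rows and columns disagree")
    return list(df.index), df.to_numpy(dtype=float)


def write_newick(tree, labels: Sequence[str], path) -> None:
    """Serialise a linkage tree as Newick with sample_ids as leaf labels.

    Each internal node sits at elevation ``merge height / 2`` (the usual
    ultrametric height-splitting convention) and branch lengths are
    elevation differences, so two leaves merged at height h appear as
    ``(A:h/2,B:h/2);``.
    """
    n = tree.n_leaves
    if len(labels) != n:
        raise ValueError("label count does not match leaf count")
    text: Dict[int, str] = {i: str(labels[i]) for i in range(n)}
    elev: Dict[int, float] = {i: 0.0 for i in range(n)}
    for k, (a, b, height, _size) in enumerate(tree.merges):
        node = n + k
        e = height / 2.0
        text[node] = (f"({text[a]}:{e - elev[a]:.10g},"
                      f"{text[b]}:{e - elev[b]:.10g})")
        elev[node] = e
    with open(path, "w") as fh:
        fh.write(text[n + len(tree.merges) - 1] + ";\n")


def load_bundled_references() -> Tuple[str, str]:
    """(16S reference, 23S 5'-fragment reference) bundled with the package.

    These are synthetic stand-in references generated with a fixed seed (not
    biological rRNA sequences); replace them with real references via the
    ``partition_regions`` arguments when analysing real amplicons.
    """
    pkg = importlib.resources.files("ampdiv") / "data"
    ssu = read_fasta(str(pkg / "synthetic_ssu_ref.fasta"))
    lsu = read_fasta(str(pkg / "synthetic_lsu_frag.fasta"))
    return next(iter(ssu.values())), next(iter(lsu.values()))
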