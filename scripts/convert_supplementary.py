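#!/usr/bin/env python
"""Convert the deposited per-ASV supplementary workbook into pipeline inputs.

The deposited dataset ships as an Excel workbook whose ``by_ASV`` sheet holds
one row per ASV with its sequence and per-sample read counts.  This script
converts it into the TSV + FASTA + metadata triple the pipeline core reads
(the core deliberately stays Excel-free):

    python scripts/convert_supplementary.py --xlsx additional_file_4.xlsx \
        --sheet by_ASV --out data/supplementary/

Expected layout of the sheet: a header row; one column holding the ASV id,
one the sequence, and 24 sample columns of integer counts whose headers are
the sample labels (lake code + ``e``/``h`` layer suffix).  Column names can
be remapped with --id-column / --seq-column if they differ.  Sample metadata
(lake, region, layer, year) is derived from the sample labels; edit the
LAKE_TABLE below if labels differ from the published ones.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from ampdiv.io import write_fasta  # noqa: E402

#: lake code -> (region, year) for the published sampling design
LAKE_TABLE = {
    "MA": ("Hokkaido", 2015), "KU": ("Hokkaido", 2015), "TO": ("Hokkaido", 2015),
    "IN": ("Honshu-Kyushu", 2015), "CH": ("Honshu-Kyushu", 2015),
    "SA": ("Honshu-Kyushu", 2015), "MO": ("Honshu-Kyushu", 2015),
    "BI": ("Honshu-Kyushu", 2015), "BI10": ("Honshu-Kyushu", 2010),
    "IK": ("Honshu-Kyushu", 2015),
    "ZU": ("Europe", 2017), "MG": ("Europe", 2017),
}
LAYERS = {"e": "epilimnion", "h": "hypolimnion"}


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--xlsx", required=True, type=Path)
    parser.add_argument("--sheet", default="by_ASV")
    parser.add_argument("--id-column", default=None,
                        help="ASV id column (default: first column)")
    parser.add_argument("--seq-column", default=None,
                        help="sequence column (default: auto-detect by content)")
    parser.add_argument("--out", required=True, type=Path)
    args = parser.parse_args()

    import pandas as pd

    df = pd.read_excel(args.xlsx, sheet_name=args.sheet)
    id_col = args.id_column or df.columns[0]
    seq_col = args.seq_column
    if seq_col is None:
        for col in df.columns:
            vals = df[col].astype(str)
            if vals.str.fullmatch("[ACGTUacgtuRYSWKMBDHVNryswkmbdhvn]+").all() \
                    and vals.str.len().median() > 100:
                seq_col = col
                break
    if seq_col is None:
        raise SystemExit("could not locate the sequence column; pass "
                         "--seq-column")
    sample_cols = [c for c in df.columns
                   if str(c)[:-1] in LAKE_TABLE and str(c)[-1] in LAYERS]
    if not sample_cols:
        raise SystemExit("no sample columns recognised; check the sheet's "
                         "sample headers against LAKE_TABLE")

    args.out.mkdir(parents=True, exist_ok=True)
    ids = df[id_col].astype(str)
    write_fasta(dict(zip(ids, df[seq_col].astype(str).str.upper())),
                args.out / "asv.fa")
    counts = df[sample_cols].astype(int)
    counts.insert(0, "asv_id", ids)
    counts.to_csv(args.out / "counts.tsv", sep="\t", index=False)
    with open(args.out / "meta.tsv", "w") as fh:
        fh.write("sample_id\tlake_code\tregion\tlayer\tyear\n")
        for c in sample_cols:
            code, layer = str(c)[:-1], str(c)[-1]
            region, year = LAKE_TABLE[code]
            fh.write(f"{c}\t{code[:2]}\t{region}\t{LAYERS[layer]}\t{year}\n")
    print(f"wrote {len(df)} ASVs x {len(sample_cols)} samples to {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
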