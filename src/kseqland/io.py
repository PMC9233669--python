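"""Readers and writers for the pipeline's tabular and FASTA formats.

Count tables are sequences-by-samples TSV/CSV with the sequence string as
the first column; sample metadata and all result tables are plain CSV.
FASTA handling goes through Biopython.  RNA input (U) is normalised to DNA
(T) on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence_space import mutation_label, normalize_sequence


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a sequences x samples count table (TSV or CSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = [normalize_sequence(s) for s in df.index]
    df.index.name = "sequence"
    return df


def write_count_table(counts: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    counts.rename_axis("sequence").to_csv(path, sep=sep)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    required = {"sample_id", "role"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    return meta


def read_sequence_counts(path: str | Path) -> pd.Series:
    """Read a two-column (sequence, count) table as produced by read joining."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    seq_col, count_col = df.columns[:2]
    s = pd.Series(
        df[count_col].to_numpy(),
        index=[normalize_sequence(x) for x in df[seq_col]],
    )
    return s.groupby(level=0).sum().sort_values(ascending=False)


def read_centers_fasta(path: str | Path) -> dict[str, str]:
    """Family-name -> center-sequence mapping from a FASTA file."""
    return {
        rec.id: normalize_sequence(str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_centers_fasta(centers: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in centers.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_pool_fasta(
    sequences: Iterable[str], center: str, path: str | Path
) -> None:
    """Write enumerated variants; record IDs encode the edits from the center."""
    records = [
        SeqRecord(Seq(seq), id=mutation_label(center, seq), description="")
        for seq in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def trim_primers(seq: str, forward: str = "", reverse: str = "") -> str:
    """Strip constant flanking regions if present (simple prefix/suffix trim)."""
    s = normalize_sequence(seq)
    f = normalize_sequence(forward) if forward else ""
    r = normalize_sequence(reverse) if reverse else ""
    if f and s.startswith(f):
        s = s[len(f):]
    if r and s.endswith(r):
        s = s[: len(s) - len(r)]
    return s
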