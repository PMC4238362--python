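"""Readers/writers for the plain-text formats used across the pipeline.

Collapsed sRNA reads use the ``>serial_count`` FASTA header dialect (one
record per distinct sequence, count encoded after the final underscore).
Everything tabular goes through pandas TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_collapsed_fasta(path: str | Path) -> dict[str, int]:
    """Read collapsed reads (``>serial_count`` headers) into sequence->count."""
    reads: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            count = int(rec.id.rsplit("_", 1)[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"collapsed-FASTA header {rec.id!r} lacks a _count suffix"
            ) from exc
        seq = str(rec.seq).upper()
        reads[seq] = reads.get(seq, 0) + count
    return reads


def write_collapsed_fasta(path: str | Path, reads: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(sorted(reads.items()), start=1):
            fh.write(f">{i}_{count}\n{seq}\n")


def read_raw_reads(path: str | Path, fmt: str | None = None) -> Iterable[str]:
    """Yield raw read sequences from FASTA or FASTQ (format guessed by suffix)."""
    if fmt is None:
        suffix = Path(path).suffix.lower()
        fmt = "fastq" if suffix in {".fq", ".fastq"} else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield str(rec.seq).upper()


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
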