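"""Core record types and plain-text I/O.

The package's in-memory containers are deliberately light: a sequencing read is a
dataclass, an abundance table is a pandas DataFrame with features on the rows and
samples on the columns (integer counts unless a transform has been applied).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class ReadRecord:
    """One sequencing read: id, nucleotides, optional Phred qualities, sample label."""

    id: str
    seq: str
    qual: Optional[Sequence[int]] = None
    sample: Optional[str] = None

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, sample: Optional[str] = None) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield ReadRecord(id=rec.id, seq=str(rec.seq).upper(), sample=sample)


def read_fastq(path: str | Path, sample: Optional[str] = None) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            id=rec.id,
            seq=str(rec.seq).upper(),
            qual=rec.letter_annotations["phred_quality"],
            sample=sample,
        )


def _to_seqrecord(read: ReadRecord) -> SeqRecord:
    rec = SeqRecord(Seq(read.seq), id=read.id, description="")
    if read.qual is not None:
        rec.letter_annotations["phred_quality"] = list(read.qual)
    return rec


def write_fasta(reads: Iterable[ReadRecord], path: str | Path) -> int:
    return SeqIO.write((_to_seqrecord(r) for r in reads), str(path), "fasta")


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    return SeqIO.write((_to_seqrecord(r) for r in reads), str(path), "fastq")


# ---------------------------------------------------------------------------
# Count matrices (features x samples)
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "feature_id"
    return df


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def validate_count_matrix(df: pd.DataFrame) -> None:
    if (df.values < 0).any():
        raise ValueError("count matrix contains negative entries")
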