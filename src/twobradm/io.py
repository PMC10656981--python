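"""File formats: FASTA/FASTQ (gzip-transparent), TSV tables, metadata.

All tabular output is TSV (taxon names can contain commas), UTF-8, with
a header row.  Sequence parsing is delegated to Biopython.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

FASTA_SUFFIXES = (".fa", ".fasta", ".fna")
FASTQ_SUFFIXES = (".fq", ".fastq")


def open_text(path, mode: str = "rt"):
    """Open a text file, transparently decompressing ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _strip_gz(path: Path) -> Path:
    return path.with_suffix("") if path.suffix == ".gz" else path


def read_fasta(path) -> list[SeqRecord]:
    """All records of a (possibly gzipped) FASTA file; empty file is an error."""
    with open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable, path) -> None:
    recs = [r if isinstance(r, SeqRecord)
            else SeqRecord(Seq(r[1]), id=r[0], description="")
            for r in records]
    with open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path) -> list[SeqRecord]:
    """All records of a (possibly gzipped) FASTQ file (validates seq/qual lengths)."""
    with open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fastq"))
    if not records:
        raise ValueError(f"{path}: no FASTQ records")
    return records


def read_reads(path) -> list[str]:
    """Read sequences from FASTA or FASTQ, by file suffix."""
    suffix = _strip_gz(Path(path)).suffix.lower()
    if suffix in FASTQ_SUFFIXES:
        return [str(r.seq) for r in read_fastq(path)]
    if suffix in FASTA_SUFFIXES:
        return [str(r.seq) for r in read_fasta(path)]
    raise ValueError(f"{path}: unrecognized reads format (use .fastq/.fq/.fasta/.fa)")


def write_fastq(sequences: Iterable[str], path, prefix: str = "read",
                quality_char: str = "I") -> None:
    """Write sequences as FASTQ with constant quality (informational only)."""
    with open_text(path, "wt") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_abundance_matrix(path) -> pd.DataFrame:
    """Species x sample TSV with species names in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate species row(s) {dup}")
    return df


def read_metadata(path) -> pd.Series:
    """Sample metadata TSV with columns ``sample`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df["sample"].duplicated().any():
        dup = sorted(set(df["sample"][df["sample"].duplicated()]))
        raise ValueError(f"{path}: duplicate sample id(s) {dup}")
    return df.set_index("sample")["group"]


def iter_genome_files(genomes) -> list[Path]:
    """Expand a directory or explicit list into genome FASTA paths."""
    p = Path(genomes) if isinstance(genomes, (str, Path)) else None
    if p is not None and p.is_dir():
        files = sorted(q for q in p.iterdir()
                       if _strip_gz(q).suffix.lower() in FASTA_SUFFIXES)
    elif p is not None:
        files = [p]
    else:
        files = [Path(q) for q in genomes]
    if not files:
        raise ValueError(f"no genome FASTA files found in {genomes}")
    return files
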