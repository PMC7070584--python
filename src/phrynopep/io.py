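"""Plain-text I/O: FASTA, expression/annotation/peptide tables, peak lists."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orfs import TranscriptContig

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_contigs",
    "read_expression_table",
    "read_annotation_table",
    "read_signal_table",
    "read_peak_list",
    "write_peak_list",
    "read_ss_table",
]


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_contigs(fasta_path, expression_path=None) -> list[TranscriptContig]:
    """Contig FASTA plus optional contig_id -> TPM table."""
    tpm = {}
    if expression_path is not None:
        tpm = read_expression_table(expression_path).set_index("contig_id")["tpm"].to_dict()
    return [
        TranscriptContig(contig_id=name, seq_nt=seq, tpm=tpm.get(name))
        for name, seq in read_fasta(fasta_path)
    ]


def read_expression_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"contig_id", "tpm"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table {path} lacks column(s) {sorted(missing)}")
    return df


def read_annotation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"contig_id", "family"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} lacks column(s) {sorted(missing)}")
    return df


def read_signal_table(path) -> dict[str, int]:
    """External signal-peptide calls: protein_id -> cleavage_pos (0-based)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"protein_id", "cleavage_pos"} - set(df.columns)
    if missing:
        raise ValueError(f"signal table {path} lacks column(s) {sorted(missing)}")
    return dict(zip(df["protein_id"], df["cleavage_pos"].astype(int)))


def read_peak_list(path) -> pd.DataFrame:
    """Delimited peak list with columns rt_min, mz, intensity (tab or comma)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"mz"} - set(df.columns)
    if missing:
        raise ValueError(f"peak list {path} lacks an mz column")
    return df


def write_peak_list(path, peaks: pd.DataFrame) -> None:
    peaks.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_ss_table(path) -> dict[str, str]:
    """Per-peptide secondary-structure strings: peptide_id -> H/E/C string."""
    df = pd.read_csv(path, sep="\t")
    missing = {"peptide_id", "ss"} - set(df.columns)
    if missing:
        raise ValueError(f"secondary-structure table {path} lacks column(s) {sorted(missing)}")
    return dict(zip(df["peptide_id"], df["ss"]))
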