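"""Open-reading-frame extraction from assembled transcript contigs.

ORFs are Met-initiated and stop-terminated, scanned on both strands in all
three frames.  The nucleotide span of an ORF *includes* its stop codon and
must be strictly greater than the configured cutoff (default 150 nt), the
convention used when screening transcriptome assemblies for short secretory
precursors.  Coordinates are 0-based half-open and always reported on the
input strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from Bio.Data import CodonTable

__all__ = [
    "TranscriptContig",
    "OpenReadingFrame",
    "translate",
    "reverse_complement",
    "find_orfs",
]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class TranscriptContig:
    """One assembled transcript: id, nucleotide sequence, optional TPM."""

    contig_id: str
    seq_nt: str
    tpm: float | None = None

    def __post_init__(self):
        if not self.seq_nt:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        seq = self.seq_nt.upper()
        for i, ch in enumerate(seq):
            if ch not in _ALPHABET:
                raise ValueError(
                    f"contig {self.contig_id!r}: non-ACGTN character {ch!r} at offset {i}"
                )
        object.__setattr__(self, "seq_nt", seq)


@dataclass(frozen=True)
class OpenReadingFrame:
    contig_id: str
    strand: str  # '+' or '-'
    frame: int  # 0|1|2 on the scanned strand
    nt_start: int  # 0-based half-open, on the input strand, stop codon included
    nt_end: int
    aa_seq: str  # stop excluded; ambiguous codons rendered X
    has_ambiguous: bool = field(default=False, compare=False)

    @property
    def orf_id(self) -> str:
        return f"{self.contig_id}|{self.strand}|{self.frame}|{self.nt_start}-{self.nt_end}"


def reverse_complement(seq_nt: str) -> str:
    return seq_nt.upper().translate(_COMPLEMENT)[::-1]


def translate(seq_nt: str) -> str:
    """Translate with the standard genetic code; stops as '*', N-codons as 'X'.

    The length must be a multiple of three.
    """
    seq = seq_nt.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not divisible by 3")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def _scan_strand(seq: str, min_nt: int, all_starts: bool):
    """Yield (frame, start, end, aa) on one strand; end includes the stop codon."""
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            aa = _CODON_TO_AA.get(codon, "X")
            if aa == "*":
                for s in starts:
                    end = pos + 3
                    if end - s > min_nt:
                        yield frame, s, end, translate(seq[s:pos])
                    if not all_starts:
                        break  # only the longest ORF per stop
                starts = []
            elif codon == "ATG" and (all_starts or not starts):
                starts.append(pos)


def find_orfs(
    contig: TranscriptContig | str,
    min_nt: int = 150,
    strands: Iterable[str] = ("+", "-"),
    all_starts: bool = False,
) -> list[OpenReadingFrame]:
    """All ATG-initiated, stop-terminated ORFs spanning more than *min_nt*.

    The span is measured including the stop codon; the cutoff is strict
    (a 150-nt ORF is rejected at the default).  By default only the longest
    ORF per (strand, frame, stop codon) is reported; ``all_starts=True``
    also emits ORFs from internal ATGs.  Codons containing N translate to X
    and the containing ORF is flagged ``has_ambiguous``.
    """
    if isinstance(contig, str):
        contig = TranscriptContig("contig", contig)
    if min_nt < 3:
        raise ValueError("min_nt must be >= 3")
    strands = set(strands)
    if not strands <= {"+", "-"}:
        raise ValueError(f"strands must be a subset of {{'+','-'}}, got {strands}")

    n = len(contig.seq_nt)
    orfs: list[OpenReadingFrame] = []
    for strand in ("+", "-"):
        if strand not in strands:
            continue
        seq = contig.seq_nt if strand == "+" else reverse_complement(contig.seq_nt)
        for frame, s, e, aa in _scan_strand(seq, min_nt, all_starts):
            if strand == "+":
                start, end = s, e
            else:
                start, end = n - e, n - s
            orfs.append(
                OpenReadingFrame(
                    contig_id=contig.contig_id,
                    strand=strand,
                    frame=frame,
                    nt_start=start,
                    nt_end=end,
                    aa_seq=aa,
                    has_ambiguous="X" in aa,
                )
            )
    orfs.sort(key=lambda o: (o.strand, o.nt_start, o.nt_end))
    return orfs
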