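"""Synthetic skin-transcriptome generator with known ground truth.

Real frog-skin sequencing data for this problem are not deposited anywhere,
so every downstream stage is exercised on generated inputs that emulate the
relevant structure: Trinity-style contig FASTA with a strongly skewed TPM
profile, a handful of embedded FSAP-like precursor transcripts (signal
peptide + acidic spacer + 1-3 tandem peptides bounded by KR/RR/RXXR motifs,
precursor length 44-110 aa, optional Gly amidation donor), three categories
of decoy contigs, and ESI+ peak lists with decoy peaks.

Everything is driven by a seeded :class:`numpy.random.Generator`; runs with
the same seed are byte-identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .chemistry import KYTE_DOOLITTLE, PROTON_MASS, monoisotopic_mass
from .orfs import TranscriptContig, find_orfs

__all__ = [
    "PrecursorArchitecture",
    "GroundTruthPrecursor",
    "SyntheticTranscriptome",
    "generate_precursor",
    "generate_transcriptome",
    "sample_tpm",
    "generate_peak_list",
    "write_transcriptome",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
_STOP_CODONS = sorted(_TABLE.stop_codons)

# Residue pools for the different precursor parts.  The signal n/h/c regions
# deliberately avoid A/G/S/C outside the c-region so the cleavage position
# is unambiguous; spacers avoid K/R so they can never harbour a cleavage
# motif; peptide composition is broad but R-poor to keep spurious motifs rare.
_SIGNAL_N = "KNQT"
_SIGNAL_H = "LIVF"
_SIGNAL_C = "AS"
_SPACER_NEUTRAL = "SNTPALVQ"
_PEPTIDE_POOL = list("GLVASTNPDEFYIKQRWMH")
_PEPTIDE_WEIGHTS = np.array(
    [0.08, 0.11, 0.09, 0.07, 0.07, 0.05, 0.07, 0.06, 0.05, 0.05,
     0.05, 0.04, 0.06, 0.05, 0.04, 0.03, 0.01, 0.01, 0.01],
    dtype=float,
)
_PEPTIDE_WEIGHTS /= _PEPTIDE_WEIGHTS.sum()

_LEN_BOUNDS = (44, 110)  # observed precursor length range


@dataclass(frozen=True)
class PrecursorArchitecture:
    """Tunable layout of a generated precursor.

    ``n_peptides`` may be an integer or an inclusive (lo, hi) range; the
    published precursors carry one to three tandem peptides, so that is the
    default.  ``min_spacer_acidity`` is the minimum Asp+Glu fraction of the
    acidic spacer.
    """

    n_peptides: int | tuple[int, int] = (1, 3)
    peptide_len: tuple[int, int] = (6, 18)
    spacer_len: tuple[int, int] = (8, 14)
    min_spacer_acidity: float = 0.5
    amidation_prob: float = 0.3
    signal_len: tuple[int, int] = (15, 25)
    terminal_motif_prob: float = 0.5
    motif_names: tuple[str, ...] = ("KR", "RR", "RXXR")
    motif_weights: tuple[float, ...] = (0.45, 0.45, 0.10)

    def n_peptide_range(self) -> tuple[int, int]:
        if isinstance(self.n_peptides, int):
            return (self.n_peptides, self.n_peptides)
        return self.n_peptides


@dataclass(frozen=True)
class GroundTruthPrecursor:
    precursor_id: str
    signal_seq: str
    spacer_seqs: tuple[str, ...]
    peptide_seqs: tuple[tuple[str, bool], ...]  # (sequence, amidated)
    cleavage_motifs: tuple[tuple[int, str], ...]  # (0-based motif start, name)
    protein_seq: str
    cds_nt: str
    tpm: float = 0.0
    contig_id: str | None = None

    @property
    def cleavage_pos(self) -> int:
        """0-based index of the first mature residue (oracle signal position)."""
        return len(self.signal_seq)


@dataclass
class SyntheticTranscriptome:
    contigs: list  # of orfs.TranscriptContig, with .family bookkeeping
    truths: list[GroundTruthPrecursor]
    families: dict[str, str | None] = field(default_factory=dict)  # contig_id -> label
    seed: int | None = None


def _rng(rng_seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(rng_seed)


def _choice(rng, pool, size=None, p=None) -> str:
    picked = rng.choice(list(pool), size=size, p=p)
    return picked if size is None else "".join(picked)


# --- independent motif resolution used only to validate generated truth ---
# (the annotator has its own scanner; keeping two implementations makes the
# generator/annotator round-trip a genuine cross-check)
_VALIDATE_RE = re.compile(r"(?=(KR|RR|R[^R]{2}R))")


def _resolve_motifs_for_validation(region: str) -> list[tuple[int, int]]:
    cands = []
    for m in _VALIDATE_RE.finditer(region):
        g = m.group(1)
        rank = 0 if len(g) == 4 else (1 if g == "KR" else 2)
        cands.append((m.start(), rank, m.start() + len(g)))
    cands.sort()
    spans, cursor = [], 0
    for start, _rank, end in cands:
        if start >= cursor:
            spans.append((start, end))
            cursor = end
    return spans


def _make_signal(rng: np.random.Generator, length: int) -> str:
    """M + polar n-region + hydrophobic core + short A/S c-region.

    The n-region is capped so the central 8-mer of the signal lies entirely
    inside the hydrophobic core, guaranteeing a detectable core.
    """
    c_len = int(rng.integers(2, 4))
    n_len = min(int(rng.integers(2, 5)), length // 2 - 5)
    h_len = length - 1 - n_len - c_len
    lo_h = 9
    if h_len < lo_h:
        n_len = max(2, length - 1 - c_len - lo_h)
        h_len = length - 1 - n_len - c_len
    sig = (
        "M"
        + _choice(rng, _SIGNAL_N, n_len)
        + _choice(rng, _SIGNAL_H, h_len)
        + _choice(rng, _SIGNAL_C, c_len)
    )
    core = sig[len(sig) // 2 - 4 : len(sig) // 2 + 4]
    assert sum(KYTE_DOOLITTLE[a] for a in core) / 8 >= 2.0, "signal core not hydrophobic"
    return sig


def _make_spacer(rng: np.random.Generator, length: int, min_acidity: float) -> str:
    n_acid = max(int(np.ceil(min_acidity * length)), 1)
    acids = _choice(rng, "DE", n_acid)
    rest = _choice(rng, _SPACER_NEUTRAL, length - n_acid)
    chars = list(acids + rest)
    rng.shuffle(chars)
    return "".join(chars)


_INTERNAL_MOTIF = re.compile(r"KR|RR|R[^R]{2}R")


def _make_peptide(rng: np.random.Generator, length: int) -> str:
    for _ in range(200):
        pep = _choice(rng, _PEPTIDE_POOL, length, p=_PEPTIDE_WEIGHTS)
        if pep.endswith("G"):
            continue
        if _INTERNAL_MOTIF.search(pep):
            continue
        de = (pep.count("D") + pep.count("E")) / length
        if de >= 0.20:  # must classify as a peptide candidate downstream
            continue
        if "R" in pep[:3] or "R" in pep[-3:] or pep[-1] == "K":
            continue  # keep junctions with flanking motifs unambiguous
        return pep
    raise RuntimeError("could not sample a valid peptide; widen the length range")


def _make_motif(rng: np.random.Generator, arch: PrecursorArchitecture) -> str:
    name = rng.choice(list(arch.motif_names), p=list(arch.motif_weights))
    if name == "KR":
        return "KR"
    if name == "RR":
        return "RR"
    mid = _choice(rng, "AVLSTNQ", 2)
    return "R" + mid + "R"


def _motif_name(motif: str) -> str:
    return motif if len(motif) == 2 else "RXXR"


def generate_precursor(
    arch: PrecursorArchitecture | None = None,
    rng_seed: int | None = None,
    rng: np.random.Generator | None = None,
    precursor_id: str = "precursor_001",
) -> GroundTruthPrecursor:
    """One FSAP-like precursor with fully known architecture.

    Raises ``ValueError`` if the architecture cannot fit inside the
    44-110 aa precursor length range, and validates on emission that the
    intended cleavage motifs are exactly the ones motif resolution finds.
    """
    arch = arch or PrecursorArchitecture()
    rng = _rng(rng_seed, rng)
    n_lo, n_hi = arch.n_peptide_range()
    if not 1 <= n_lo <= n_hi:
        raise ValueError(f"invalid peptide count range {arch.n_peptide_range()}")

    min_total = arch.signal_len[0] + arch.spacer_len[0] + 2 + n_lo * (arch.peptide_len[0] + 0) + (n_lo - 1) * 2
    max_total = (
        arch.signal_len[1] + arch.spacer_len[1] + 4 + n_hi * (arch.peptide_len[1] + 1) + n_hi * 4
    )
    if min_total > _LEN_BOUNDS[1] or max_total < _LEN_BOUNDS[0]:
        raise ValueError(
            f"architecture implies precursor lengths in [{min_total}, {max_total}], "
            f"outside the allowed {_LEN_BOUNDS[0]}-{_LEN_BOUNDS[1]} aa range"
        )

    for _attempt in range(500):
        n_pep = int(rng.integers(n_lo, n_hi + 1))
        signal = _make_signal(rng, int(rng.integers(arch.signal_len[0], arch.signal_len[1] + 1)))
        spacer = _make_spacer(
            rng, int(rng.integers(arch.spacer_len[0], arch.spacer_len[1] + 1)), arch.min_spacer_acidity
        )
        peptides: list[tuple[str, bool]] = []
        parts: list[tuple[str, str]] = [("signal", signal), ("spacer", spacer), ("motif", _make_motif(rng, arch))]
        for k in range(n_pep):
            pep = _make_peptide(rng, int(rng.integers(arch.peptide_len[0], arch.peptide_len[1] + 1)))
            amidated = bool(rng.random() < arch.amidation_prob)
            last = k == n_pep - 1
            parts.append(("peptide", pep))
            peptides.append((pep, amidated))
            if amidated:
                parts.append(("gly", "G"))
                parts.append(("motif", _make_motif(rng, arch)))
            elif not last or rng.random() < arch.terminal_motif_prob:
                parts.append(("motif", _make_motif(rng, arch)))

        protein = "".join(s for _, s in parts)
        if not _LEN_BOUNDS[0] <= len(protein) <= _LEN_BOUNDS[1]:
            continue

        # intended motif spans
        intended = []
        pos = 0
        for kind, s in parts:
            if kind == "motif":
                intended.append((pos, pos + len(s)))
            pos += len(s)
        region_off = len(signal)
        found = [
            (a + region_off, b + region_off)
            for a, b in _resolve_motifs_for_validation(protein[region_off:])
        ]
        if found != intended:
            continue  # a junction created a spurious or shifted motif; retry

        motifs = []
        pos = 0
        for kind, s in parts:
            if kind == "motif":
                motifs.append((pos, _motif_name(s)))
            pos += len(s)

        cds = "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein) + rng.choice(_STOP_CODONS)
        return GroundTruthPrecursor(
            precursor_id=precursor_id,
            signal_seq=signal,
            spacer_seqs=(spacer,),
            peptide_seqs=tuple(peptides),
            cleavage_motifs=tuple(motifs),
            protein_seq=protein,
            cds_nt=cds,
        )
    raise RuntimeError("failed to assemble a self-consistent precursor in 500 attempts")


# ---------------------------------------------------------------------------
# TPM model
# ---------------------------------------------------------------------------

def sample_tpm(
    n: int,
    rng: np.random.Generator,
    tail_prob: float = 0.005,
    threshold: float = 100.0,
    high_mass_fraction: float = 0.7,
    sigma_high: float = 1.0,
    sigma_low: float = 0.7,
    total: float = 1e6,
    n_forced_high: int = 0,
) -> tuple[np.ndarray, int]:
    """Skewed per-contig TPM values summing to *total* (transcripts per million).

    A binomially sampled highly-expressed group (plus *n_forced_high*
    contigs that are always highly expressed, e.g. embedded precursor
    transcripts) receives a fixed share of the library; log-normal weights
    spread mass within each group.  Values are kept clear of the threshold
    on both sides, so the number of contigs above *threshold* is exactly
    ``n_forced_high + Binomial(n - n_forced_high, tail_prob)``.

    Returns ``(tpm_values, n_high)``; the first *n_high* entries are the
    highly expressed group (callers may shuffle).
    """
    if n == 0:
        return np.zeros(0), 0
    k = n_forced_high + int(rng.binomial(n - n_forced_high, tail_prob))
    lo_cap = 0.8 * threshold
    hi_floor = 1.25 * threshold
    if k == 0:
        high = np.zeros(0)
        low = _allocate(rng.lognormal(0.0, sigma_low, n), total, hi=lo_cap)
        return low, 0
    if k == n:
        return _allocate(rng.lognormal(0.0, sigma_high, n), total, lo=hi_floor), n
    high = _allocate(rng.lognormal(0.0, sigma_high, k), total * high_mass_fraction, lo=hi_floor)
    low = _allocate(rng.lognormal(0.0, sigma_low, n - k), total * (1 - high_mass_fraction), hi=lo_cap)
    return np.concatenate([high, low]), k


def _allocate(weights: np.ndarray, total: float, lo: float | None = None, hi: float | None = None) -> np.ndarray:
    """Scale weights to sum to *total*, iteratively clipping to [lo, hi]."""
    values = weights / weights.sum() * total
    for _ in range(50):
        clipped = np.clip(values, lo, hi)
        residual = total - clipped.sum()
        if abs(residual) < 1e-9 * total:
            return clipped
        free = (values > (lo or -np.inf)) & (values < (hi or np.inf)) if lo or hi else np.ones_like(values, bool)
        if not free.any():
            # degenerate: spread the residual uniformly (bounds may flex by a hair)
            return clipped + residual / len(clipped)
        clipped[free] += residual * clipped[free] / clipped[free].sum()
        values = clipped
    return values


# ---------------------------------------------------------------------------
# transcriptome assembly
# ---------------------------------------------------------------------------

def _random_nt(rng: np.random.Generator, length: int) -> str:
    return _choice(rng, "ACGT", length)


def _embed_cds(rng: np.random.Generator, cds: str) -> str:
    """CDS with random UTRs; an in-frame stop just upstream blocks ATG extension."""
    for _ in range(100):
        utr5 = _random_nt(rng, int(rng.integers(20, 101))) + "TAA"
        utr3 = _random_nt(rng, int(rng.integers(20, 151)))
        contig = utr5 + cds + utr3
        if contig.count(cds) == 1:
            return contig
    raise RuntimeError("could not embed CDS uniquely")


def _decoy_noncoding(rng: np.random.Generator, min_orf_nt: int = 150) -> str:
    """Random sequence rejection-sampled to contain no ORF above the cutoff."""
    for _ in range(500):
        seq = _random_nt(rng, int(rng.integers(200, 451)))
        if not find_orfs(seq, min_nt=min_orf_nt):
            return seq
    raise RuntimeError("could not sample a non-coding decoy")


def _contig_orf_proteins(contig: str) -> list[str]:
    return [o.aa_seq for o in find_orfs(contig)]


def _decoy_orf_no_signal(rng: np.random.Generator) -> str:
    """An ORF whose N terminus is hydrophilic: never receives a signal call.

    The whole contig is rejection-sampled until none of its ORFs (on either
    strand; reverse-strand translations of a planted CDS can be spuriously
    hydrophobic) carries a detectable signal peptide, which is what defines
    this decoy category.
    """
    from .annotate import detect_signal_peptide

    for _ in range(200):
        n_aa = int(rng.integers(55, 96))
        head = "M" + _choice(rng, "DENQSKRTPG", 39)
        body = _choice(rng, "ADEFGHIKLMNPQRSTVWY", n_aa - 40)
        protein = (head + body)[:n_aa]
        cds = "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein) + rng.choice(_STOP_CODONS)
        contig = _embed_cds(rng, cds)
        if not any(detect_signal_peptide(p) for p in _contig_orf_proteins(contig)):
            return contig
    raise RuntimeError("could not sample a signal-free decoy contig")


def _decoy_orf_no_motifs(rng: np.random.Generator) -> str:
    """Signal-peptide-bearing ORF with an acidic, motif-free body.

    Rejection-sampled until no ORF of the contig yields any predicted
    peptide: the intended ORF's post-signal region is an acidic spacer and
    must stay one, and incidental ORFs must stay silent.
    """
    from .annotate import annotate_precursor, predict_mature_peptides

    for _ in range(200):
        sig = _make_signal(rng, int(rng.integers(16, 23)))
        body = _make_spacer(rng, int(rng.integers(35, 61)), 0.4)  # K/R-free by construction
        cds = "".join(rng.choice(_CODONS_FOR[aa]) for aa in sig + body) + rng.choice(_STOP_CODONS)
        contig = _embed_cds(rng, cds)
        silent = True
        for p in _contig_orf_proteins(contig):
            ann = annotate_precursor("decoy", p)
            if ann.signal is not None and predict_mature_peptides(ann):
                silent = False
                break
        if silent:
            return contig
    raise RuntimeError("could not sample a motif-free decoy contig")


def generate_transcriptome(
    n_precursors: int,
    n_decoys: int,
    rng_seed: int | None = None,
    arch: PrecursorArchitecture | None = None,
    tail_prob: float = 0.005,
    tpm_threshold: float = 100.0,
) -> SyntheticTranscriptome:
    """Contigs + TPM + ground truth for *n_precursors* FSAP-like transcripts.

    Decoys cycle through three categories: (a) random non-coding sequence,
    (b) ORFs lacking a signal peptide, (c) signal-bearing ORFs without
    cleavage motifs.  Precursor contigs are always assigned to the highly
    expressed TPM group, mirroring the consistently high expression of FSAP
    transcripts in real skin libraries.
    """
    if n_precursors < 0 or n_decoys < 0:
        raise ValueError("counts must be non-negative")
    rng = _rng(rng_seed)
    truths = [
        generate_precursor(arch, rng=rng, precursor_id=f"precursor_{i + 1:03d}")
        for i in range(n_precursors)
    ]
    contig_seqs: list[str] = [_embed_cds(rng, t.cds_nt) for t in truths]
    decoy_makers = (_decoy_noncoding, _decoy_orf_no_signal, _decoy_orf_no_motifs)
    decoy_cats = [i % 3 for i in range(n_decoys)]
    contig_seqs += [decoy_makers[c](rng) for c in decoy_cats]

    n = n_precursors + n_decoys
    tpm, n_high = sample_tpm(
        n, rng, tail_prob=tail_prob, threshold=tpm_threshold, n_forced_high=n_precursors
    ) if n else (np.zeros(0), 0)
    # first n_high TPM values are the high group; precursors take the first
    # n_precursors of them, remaining values are permuted over the decoys
    decoy_tpm = tpm[n_precursors:]
    decoy_tpm = decoy_tpm[rng.permutation(len(decoy_tpm))]

    contigs, families = [], {}
    decoy_families = ("keratin", "ribosomal protein", None, "serine protease inhibitor", None)
    for i, seq in enumerate(contig_seqs):
        cid = f"TRINITY_DN{i + 1}_c0_g1_i1"
        if i < n_precursors:
            value = float(tpm[i])
            truths[i] = replace(truths[i], tpm=value, contig_id=cid)
            families[cid] = "FSAP superfamily"
        else:
            value = float(decoy_tpm[i - n_precursors])
            families[cid] = decoy_families[(i - n_precursors) % len(decoy_families)]
        contigs.append(TranscriptContig(contig_id=cid, seq_nt=seq, tpm=value))
    return SyntheticTranscriptome(contigs=contigs, truths=truths, families=families, seed=rng_seed)


def write_transcriptome(tx: SyntheticTranscriptome, outdir: str | Path) -> dict[str, Path]:
    """Write contig FASTA, expression table, annotation table and truth sidecar."""
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": outdir / "contigs.fasta",
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    pio.write_fasta(paths["contigs"], [(c.contig_id, c.seq_nt) for c in tx.contigs])
    pd.DataFrame(
        {"contig_id": [c.contig_id for c in tx.contigs], "tpm": [c.tpm for c in tx.contigs]}
    ).to_csv(paths["expression"], sep="\t", index=False, float_format="%.6f")
    ann = pd.DataFrame(
        [(cid, fam) for cid, fam in tx.families.items() if fam is not None],
        columns=["contig_id", "family"],
    )
    ann.to_csv(paths["annotation"], sep="\t", index=False)
    rows = []
    for t in tx.truths:
        for ordinal, (seq, ami) in enumerate(t.peptide_seqs, start=1):
            rows.append(
                {
                    "precursor_id": t.precursor_id,
                    "contig_id": t.contig_id,
                    "ordinal": ordinal,
                    "sequence": seq,
                    "amidated": ami,
                    "cleavage_pos": t.cleavage_pos,
                    "protein_seq": t.protein_seq,
                    "tpm": t.tpm,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "precursor_id", "contig_id", "ordinal", "sequence",
            "amidated", "cleavage_pos", "protein_seq", "tpm",
        ],
    ).to_csv(paths["ground_truth"], sep="\t", index=False, float_format="%.6f")
    return paths


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------

def generate_peak_list(
    peptides,
    charges=(1, 2, 3),
    mz_noise_sd: float = 0.0,
    n_decoy_peaks: int = 0,
    rng_seed: int | None = None,
    rng: np.random.Generator | None = None,
    mz_window: tuple[float, float] = (100.0, 3000.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ESI+ peak list for *peptides* plus uniform decoy peaks.

    One peak per (peptide, charge) whose theoretical [M+zH]z+ m/z falls in
    the scan window, jittered by Gaussian noise (redrawn until inside the
    window).  Returns ``(peaks, truth)``: peaks with columns
    ``rt_min, mz, intensity`` and a ground-truth mapping with the generating
    peptide and charge per peak (``decoy`` rows for decoy peaks).
    """
    from .chemistry import _as_peptide_tuples  # shared peptide coercion

    if mz_noise_sd < 0:
        raise ValueError("mz_noise_sd must be >= 0")
    charges = sorted(set(int(z) for z in charges))
    if charges and not set(charges) <= set(range(1, 6)):
        raise ValueError("charges must lie in 1..5")
    rng = _rng(rng_seed, rng)
    lo, hi = mz_window
    rows, truth = [], []
    for pid, seq, ami in _as_peptide_tuples(peptides):
        m = monoisotopic_mass(seq, amidated=ami)
        for z in charges:
            theo = (m + z * PROTON_MASS) / z
            if not lo <= theo <= hi:
                continue
            mz = theo
            if mz_noise_sd > 0:
                for _ in range(100):
                    mz = theo + rng.normal(0.0, mz_noise_sd)
                    if lo <= mz <= hi:
                        break
            rows.append((float(rng.uniform(1.0, 60.0)), mz, float(10 ** rng.uniform(4, 7))))
            truth.append((pid, seq, z, theo))
    for _ in range(n_decoy_peaks):
        rows.append((float(rng.uniform(1.0, 60.0)), float(rng.uniform(lo, hi)), float(10 ** rng.uniform(3, 5))))
        truth.append(("decoy", "", 0, np.nan))
    peaks = pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"])
    truth_df = pd.DataFrame(truth, columns=["peptide_id", "sequence", "z", "theoretical_mz"])
    order = rng.permutation(len(peaks))
    return peaks.iloc[order].reset_index(drop=True), truth_df.iloc[order].reset_index(drop=True)
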