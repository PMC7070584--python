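"""Secretory precursor annotation and mature peptide prediction.

A frog-skin secretory precursor (FSAP-superfamily architecture) consists of
an N-terminal signal peptide, an acidic spacer, and one or more mature
peptides bounded by prohormone-convertase cleavage motifs (KR, RR, or the
furin-like RXXR).  This module:

* calls signal peptides with a simple, pluggable hydrophobic-window
  heuristic (an external predictor's cleavage positions always override);
* scans and resolves cleavage motifs (leftmost first; at equal start
  RXXR > KR > RR);
* splits the post-signal region into segments, classifies acidic spacers,
  and emits the remaining segments as mature peptides in N-to-C order.

Amidation follows standard prohormone biochemistry: a Gly immediately
preceding a cleavage motif (or exposed at the precursor C terminus) donates
the C-terminal amide and is removed from the mature sequence.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .chemistry import KYTE_DOOLITTLE, net_charge

__all__ = [
    "SignalPeptideCall",
    "CleavageSite",
    "Segment",
    "PrecursorAnnotation",
    "MaturePeptide",
    "detect_signal_peptide",
    "scan_cleavage_sites",
    "classify_segment",
    "annotate_precursor",
    "predict_mature_peptides",
]

# Candidate motif patterns; lookahead so overlapping candidates are all seen.
# X in RXXR is any residue except R, preventing double counting of nested RR.
_MOTIF_PATTERNS = (
    ("RXXR", re.compile(r"(?=(R[^R]{2}R))")),
    ("KR", re.compile(r"(?=(KR))")),
    ("RR", re.compile(r"(?=(RR))")),
)
_MOTIF_PRIORITY = {"RXXR": 0, "KR": 1, "RR": 2}


@dataclass(frozen=True)
class SignalPeptideCall:
    """cleavage_pos is the 0-based index of the first mature residue."""

    cleavage_pos: int
    score: float | None
    source: str  # 'builtin' | 'external'


@dataclass(frozen=True)
class CleavageSite:
    motif: str  # 'KR' | 'RR' | 'RXXR'
    start: int  # 0-based half-open span within the protein
    end: int


@dataclass(frozen=True)
class Segment:
    start: int
    end: int
    seq: str
    segment_class: str  # 'spacer' | 'peptide-candidate'


@dataclass(frozen=True)
class MaturePeptide:
    seq: str
    amidated: bool
    precursor_id: str
    ordinal: int  # 1-based, N-to-C over emitted peptides
    confidence: str = "normal"  # 'normal' | 'low'

    @property
    def peptide_id(self) -> str:
        return f"{self.precursor_id}.{self.ordinal}"


@dataclass
class PrecursorAnnotation:
    precursor_id: str
    protein: str
    signal: SignalPeptideCall | None
    sites: list[CleavageSite] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)


def detect_signal_peptide(
    protein: str,
    min_core_hydropathy: float = 2.0,
    window: int = 8,
    search_end: int = 36,
    cleavage_range: tuple[int, int] = (10, 40),
) -> SignalPeptideCall | None:
    """Built-in hydrophobic-core signal peptide heuristic.

    Finds the *window*-residue stretch within positions 1..35 with maximal
    mean Kyte-Doolittle hydropathy.  If that mean is below the threshold no
    signal is called.  The cleavage position is the first small residue
    (A/G/S/C) after the window inside the allowed range, falling back to
    window end + 5 capped at the range maximum.  Returns ``None`` for
    proteins too short to host a signal peptide (< 15 aa).
    """
    protein = protein.upper()
    if len(protein) < 15:
        return None
    if not protein.startswith("M"):
        warnings.warn(
            f"protein does not start with Met ({protein[:5]}...); "
            "signal heuristic applied anyway",
            stacklevel=2,
        )
    hi = min(len(protein), search_end)
    best_score, best_end = None, None
    for s in range(1, hi - window + 1):
        seg = protein[s : s + window]
        if any(a not in KYTE_DOOLITTLE for a in seg):
            continue  # windows with X are not scoreable
        mean = sum(KYTE_DOOLITTLE[a] for a in seg) / window
        if best_score is None or mean > best_score:
            best_score, best_end = mean, s + window
    if best_score is None or best_score < min_core_hydropathy:
        return None
    lo, hi_pos = cleavage_range
    cleavage = None
    for p in range(max(best_end, lo), min(hi_pos, len(protein) - 1) + 1):
        if protein[p] in "AGSC":
            cleavage = p
            break
    if cleavage is None:
        cleavage = min(best_end + 5, hi_pos)
    if cleavage >= len(protein):
        return None
    return SignalPeptideCall(cleavage_pos=cleavage, score=best_score, source="builtin")


def scan_cleavage_sites(protein: str) -> list[CleavageSite]:
    """All KR/RR/RXXR motifs, resolved to a non-overlapping set.

    Every candidate match is collected first; overlaps are then resolved
    greedily by leftmost start, ties by priority RXXR > KR > RR (the longer,
    more specific motif wins at equal start).
    """
    protein = protein.upper()
    candidates = []
    for name, pat in _MOTIF_PATTERNS:
        for m in pat.finditer(protein):
            candidates.append((m.start(), m.start() + len(m.group(1)), name))
    candidates.sort(key=lambda c: (c[0], _MOTIF_PRIORITY[c[2]]))
    resolved: list[CleavageSite] = []
    last_end = 0
    for start, end, name in candidates:
        if start >= last_end:
            resolved.append(CleavageSite(motif=name, start=start, end=end))
            last_end = end
    return resolved


def classify_segment(
    segment: str,
    spacer_de_fraction: float = 0.30,
    acidic_de_fraction: float = 0.20,
    acidic_net_charge: int = -2,
) -> str:
    """'spacer' or 'peptide-candidate' from acidic-residue content.

    A segment is an acidic spacer when its Asp+Glu fraction reaches
    *spacer_de_fraction*, or when it is strongly anionic (formal net charge
    at or below *acidic_net_charge*) with Asp+Glu fraction at least
    *acidic_de_fraction*.
    """
    if not segment:
        raise ValueError("empty segment")
    segment = segment.upper()
    de = sum(segment.count(a) for a in "DE") / len(segment)
    if de >= spacer_de_fraction:
        return "spacer"
    known = [a for a in segment if a != "X"]
    if known and net_charge("".join(known)) <= acidic_net_charge and de >= acidic_de_fraction:
        return "spacer"
    return "peptide-candidate"


def annotate_precursor(
    precursor_id: str,
    protein: str,
    external_cleavage_pos: int | None = None,
    **classify_kwargs,
) -> PrecursorAnnotation:
    """Signal call, cleavage sites, and classified segments for one protein.

    *external_cleavage_pos* (e.g. from a dedicated signal-peptide predictor)
    bypasses the built-in heuristic.
    """
    protein = protein.upper()
    if external_cleavage_pos is not None:
        signal = SignalPeptideCall(int(external_cleavage_pos), None, "external")
    else:
        signal = detect_signal_peptide(protein)
    ann = PrecursorAnnotation(precursor_id=precursor_id, protein=protein, signal=signal)
    if signal is None:
        return ann
    region_start = signal.cleavage_pos
    region = protein[region_start:]
    sites = [
        CleavageSite(s.motif, s.start + region_start, s.end + region_start)
        for s in scan_cleavage_sites(region)
    ]
    ann.sites = sites

    # Tile the post-signal region into segments between motifs.
    bounds = [region_start] + [b for s in sites for b in (s.start, s.end)] + [len(protein)]
    n_sites = len(sites)
    segs: list[Segment] = []
    for i in range(0, len(bounds), 2):
        a, b = bounds[i], bounds[i + 1]
        if b <= a:
            continue
        seq = protein[a:b]
        core = seq[:-1] if seq.endswith("G") and len(seq) > 1 else seq
        is_final = b == len(protein)
        if n_sites > 0 and is_final and i > 0:
            # The C-terminal segment after the last cleavage site is the
            # mature peptide of the precursor, whatever its composition.
            cls = "peptide-candidate"
        else:
            cls = classify_segment(core, **classify_kwargs)
        segs.append(Segment(start=a, end=b, seq=seq, segment_class=cls))
    ann.segments = segs
    return ann


def predict_mature_peptides(
    annotation: PrecursorAnnotation,
    min_length: int = 4,
) -> list[MaturePeptide]:
    """Mature peptides from an annotated precursor, N-to-C with ordinals.

    The post-signal region is split at cleavage motifs (motif residues are
    excised and belong to neither flank); spacer segments are dropped; a
    trailing Gly before a motif or at the precursor C terminus marks the
    peptide as amidated and is removed.  Peptides shorter than *min_length*
    after processing are discarded.  A precursor with a signal call but no
    cleavage motifs yields a single low-confidence peptide spanning the
    whole post-signal region, unless that region classifies as a spacer.
    """
    if annotation.signal is None:
        raise ValueError(
            f"precursor {annotation.precursor_id!r} has no signal-peptide call; "
            "filter such proteins out before peptide prediction"
        )
    protein = annotation.protein
    confidence = "normal" if annotation.sites else "low"
    peptides: list[MaturePeptide] = []
    ordinal = 0
    for seg in annotation.segments:
        if seg.segment_class == "spacer":
            continue
        seq = seg.seq
        followed_by_motif = any(s.start == seg.end for s in annotation.sites)
        at_c_terminus = seg.end == len(protein)
        amidated = False
        if seq.endswith("G") and (followed_by_motif or at_c_terminus):
            seq = seq[:-1]
            amidated = True
        if len(seq) < min_length:
            continue
        ordinal += 1
        peptides.append(
            MaturePeptide(
                seq=seq,
                amidated=amidated,
                precursor_id=annotation.precursor_id,
                ordinal=ordinal,
                confidence=confidence,
            )
        )
    return peptides
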