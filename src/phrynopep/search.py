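"""Exact and single-substitution peptide search in translated libraries.

Short known peptides are unlikely to reach significance in scored homology
searches, so they are screened as literal text against six-frame
translations: each query is expanded into the library of all isoforms
differing at a single position (19L variants per length-L peptide, plus the
original), and every member is matched as an exact substring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chemistry import STANDARD_AA

__all__ = ["VariantLibrary", "SearchHit", "expand_single_substitution_variants", "search_library"]

_ALPHABET = sorted(STANDARD_AA)


@dataclass
class VariantLibrary:
    query_id: str
    originals: list[str]
    sequences: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class SearchHit:
    member: str
    protein_id: str
    offset: int  # 0-based
    original: str  # the query peptide this member derives from
    n_mismatches: int  # 0 for the original itself, 1 for a variant


def expand_single_substitution_variants(
    peptides: list[str], query_id: str = "query"
) -> VariantLibrary:
    """Originals plus every sequence at Hamming distance 1.

    For a length-L peptide this adds 19*L substitution variants; for
    mutually non-overlapping originals the library size is exactly
    sum(1 + 19*L).  Variants shared between originals are stored once.
    """
    if not peptides:
        raise ValueError("no query peptides given")
    originals = []
    sequences: set[str] = set()
    for pep in peptides:
        if not pep:
            raise ValueError("empty peptide string in query list")
        pep = pep.upper()
        bad = set(pep) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residue(s) {sorted(bad)} in query {pep!r}")
        originals.append(pep)
        sequences.add(pep)
        for i, orig_aa in enumerate(pep):
            for aa in _ALPHABET:
                if aa != orig_aa:
                    sequences.add(pep[:i] + aa + pep[i + 1 :])
    return VariantLibrary(query_id=query_id, originals=originals, sequences=sequences)


def _occurrences(needle: str, haystack: str):
    start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return
        yield pos
        start = pos + 1


def search_library(
    library: VariantLibrary, proteins
) -> tuple[list[SearchHit], dict[str, dict[str, bool]]]:
    """Exact-substring search of every library member against *proteins*.

    *proteins* is an iterable of ``(protein_id, sequence)`` pairs or a
    mapping.  Matching is case-insensitive; X wildcards in proteins never
    match (strict character equality).  Returns the hit list and, per
    original, whether it was found directly and/or via a 1-mismatch variant.
    """
    if hasattr(proteins, "items"):
        proteins = proteins.items()
    items = [(pid, seq.upper()) for pid, seq in proteins]

    def nearest_original(member: str) -> tuple[str, int]:
        best = None
        for orig in library.originals:
            if len(orig) != len(member):
                continue
            d = sum(a != b for a, b in zip(orig, member))
            if best is None or d < best[1]:
                best = (orig, d)
        return best if best is not None else (member, -1)

    hits: list[SearchHit] = []
    for member in sorted(library.sequences):
        for pid, seq in items:
            for off in _occurrences(member, seq):
                orig, d = nearest_original(member)
                hits.append(SearchHit(member, pid, off, orig, d))
    summary = {
        orig: {
            "found_direct": any(h.original == orig and h.n_mismatches == 0 for h in hits),
            "found_via_variant": any(h.original == orig and h.n_mismatches == 1 for h in hits),
        }
        for orig in library.originals
    }
    return hits, summary
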