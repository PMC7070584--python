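"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's own scanning/translation code paths:
translation goes through Bio.Seq, ORF scanning is a plain linear walk, and
the variant-search oracle enumerates Hamming neighbourhoods directly.
"""

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def oracle_orfs(seq_nt: str, min_nt: int = 150):
    """Six-frame linear scan; longest ORF per stop; span includes the stop."""
    seq_nt = seq_nt.upper()
    n = len(seq_nt)
    found = set()
    for strand in ("+", "-"):
        s = seq_nt if strand == "+" else str(Seq(seq_nt).reverse_complement())
        for frame in range(3):
            start = None
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in STOPS:
                    if start is not None and (pos + 3 - start) > min_nt:
                        aa = str(Seq(s[start:pos]).translate())
                        if strand == "+":
                            coords = (start, pos + 3)
                        else:
                            coords = (n - (pos + 3), n - start)
                        found.add((strand, frame, coords[0], coords[1], aa))
                    start = None
                elif codon == "ATG" and start is None:
                    start = pos
    return found


def oracle_hamming_neighbourhood(peptide: str, alphabet: str):
    """All sequences of the same length at Hamming distance <= 1."""
    out = {peptide}
    for i in range(len(peptide)):
        for aa in alphabet:
            out.add(peptide[:i] + aa + peptide[i + 1 :])
    return out


def oracle_hamming_hits(peptide: str, protein: str, max_mismatches: int = 1):
    """Direct scan for windows within the mismatch budget."""
    hits = []
    L = len(peptide)
    for off in range(len(protein) - L + 1):
        window = protein[off : off + L]
        if "X" in window:
            continue
        d = sum(a != b for a, b in zip(peptide, window))
        if d <= max_mismatches:
            hits.append((off, d))
    return hits
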