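"""Peptide physicochemical properties and ESI+ mass arithmetic.

Computes the property panel used to characterise predicted skin peptides
(length, average and monoisotopic mass, formal net charge at pH 7,
Kyte-Doolittle GRAVY, percent helicity from an external secondary-structure
string) and the positive-mode electrospray charge-state ladder used to
confirm peptides against LC-MS peak lists.

Masses are element-based: a peptide is converted to its molecular formula
(via :mod:`pyteomics`) and averaged over natural isotopic abundances, which
is what "MW" denotes on peptide property panels. C-terminal amidation
replaces the terminal -OH with -NH2 (an average mass shift of -0.98 Da)
and removes the C-terminal carboxylate charge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import mass as _pmass

__all__ = [
    "STANDARD_AA",
    "KYTE_DOOLITTLE",
    "PROTON_MASS",
    "average_mass",
    "monoisotopic_mass",
    "net_charge",
    "gravy",
    "helicity_percent",
    "mz_ladder",
    "MassMatch",
    "match_peaks",
    "confirmed_peptides",
    "PeptideProperties",
    "peptide_properties",
    "properties_table",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Kyte & Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Mass of a proton (Da), the charge carrier in ESI+.
PROTON_MASS = 1.00728

# -OH -> -NH2 at the C terminus.
_AMIDE_DELTA = _pmass.Composition(formula="HN") - _pmass.Composition(formula="O")


def _check_sequence(seq: str) -> str:
    if not seq:
        raise ValueError("empty peptide sequence")
    seq = seq.upper()
    for ch in seq:
        if ch not in STANDARD_AA:
            raise ValueError(f"non-standard residue {ch!r} in sequence {seq!r}")
    return seq


def _composition(seq: str, amidated: bool) -> _pmass.Composition:
    comp = _pmass.Composition(sequence=_check_sequence(seq))
    if amidated:
        comp = comp + _AMIDE_DELTA
    return comp


def average_mass(seq: str, amidated: bool = False) -> float:
    """Average molecular mass in Da of the free peptide (or its C-terminal amide)."""
    return _pmass.calculate_mass(composition=_composition(seq, amidated), average=True)


def monoisotopic_mass(seq: str, amidated: bool = False) -> float:
    """Monoisotopic molecular mass in Da, used for MS matching."""
    return _pmass.calculate_mass(composition=_composition(seq, amidated))


def net_charge(seq: str, amidated: bool = False, ph: float = 7.0) -> int:
    """Formal net charge by integer counting.

    +1 per Lys/Arg, -1 per Asp/Glu; His counts +1 only below pH 6.  The free
    N and C termini cancel; an amidated C terminus removes the carboxylate,
    so the termini of an amidated peptide contribute +1 net.
    """
    seq = _check_sequence(seq)
    charge = sum(+1 if a in "KR" else -1 if a in "DE" else 0 for a in seq)
    if ph < 6.0:
        charge += seq.count("H")
    if amidated:
        charge += 1
    return charge


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle index over residues."""
    seq = _check_sequence(seq)
    return sum(KYTE_DOOLITTLE[a] for a in seq) / len(seq)


def helicity_percent(ss_string: str, peptide: str | None = None) -> float:
    """Percent residues in helical state from a per-residue H/E/C string.

    The secondary structure itself comes from an external predictor; this
    only converts the state string into the reported percentage.  If
    *peptide* is given, its length must match the state string.
    """
    if not ss_string:
        raise ValueError("empty secondary-structure string")
    ss = ss_string.upper()
    bad = set(ss) - set("HEC")
    if bad:
        raise ValueError(f"unknown secondary-structure state(s) {sorted(bad)}")
    if peptide is not None and len(peptide) != len(ss):
        raise ValueError(
            f"secondary-structure string length {len(ss)} does not match "
            f"peptide length {len(peptide)}"
        )
    return 100.0 * ss.count("H") / len(ss)


def mz_ladder(
    mass: float,
    z_min: int = 1,
    z_max: int = 5,
    mz_window: tuple[float, float] = (100.0, 3000.0),
) -> list[tuple[int, float]]:
    """Theoretical [M+zH]z+ m/z values falling inside the scan window.

    m/z(z) = (M + z * m_proton) / z.
    """
    if z_min < 1:
        raise ValueError("z_min must be >= 1")
    lo, hi = mz_window
    out = []
    for z in range(z_min, z_max + 1):
        mz = (mass + z * PROTON_MASS) / z
        if lo <= mz <= hi:
            out.append((z, mz))
    return out


@dataclass(frozen=True)
class MassMatch:
    """One observed peak explained by one (peptide, charge state)."""

    peptide_id: str
    seq: str
    z: int
    theoretical_mz: float
    observed_mz: float
    delta: float
    peak_index: int


def _as_peptide_tuples(peptides) -> list[tuple[str, str, bool]]:
    out = []
    for i, p in enumerate(peptides):
        if hasattr(p, "seq"):
            pid = getattr(p, "peptide_id", None) or f"{getattr(p, 'precursor_id', 'pep')}.{getattr(p, 'ordinal', i + 1)}"
            out.append((str(pid), p.seq, bool(getattr(p, "amidated", False))))
        elif isinstance(p, str):
            out.append((f"pep{i + 1}", p, False))
        else:
            pid, seq, ami = p
            out.append((str(pid), seq, bool(ami)))
    return out


def match_peaks(
    peptides,
    peaks,
    tol: float,
    z_range: tuple[int, int] = (1, 3),
    mass_type: str = "monoisotopic",
    mz_window: tuple[float, float] = (100.0, 3000.0),
) -> list[MassMatch]:
    """Assign observed peaks to theoretical charge-state ladders.

    Each observed peak is assigned to at most one (peptide, z): the
    candidate with the smallest |observed - theoretical|, ties broken
    towards the lower charge state (then input order).  A peptide is
    considered confirmed when at least one of its ladder entries is matched.

    *peptides* may be :class:`~phrynopep.annotate.MaturePeptide` objects,
    ``(id, seq, amidated)`` tuples, or bare sequences.  *peaks* may be a
    DataFrame with an ``mz`` column or a sequence of m/z values.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    massfn = monoisotopic_mass if mass_type.startswith("mono") else average_mass
    ladder: list[tuple[str, str, int, float]] = []
    for pid, seq, ami in _as_peptide_tuples(peptides):
        m = massfn(seq, amidated=ami)
        for z, mz in mz_ladder(m, z_range[0], z_range[1], mz_window):
            ladder.append((pid, seq, z, mz))

    if isinstance(peaks, pd.DataFrame):
        mzs = peaks["mz"].to_numpy()
    else:
        mzs = list(peaks)

    matches: list[MassMatch] = []
    for idx, obs in enumerate(mzs):
        best = None
        for order, (pid, seq, z, theo) in enumerate(ladder):
            d = abs(obs - theo)
            if d > tol:
                continue
            key = (d, z, order)
            if best is None or key < best[0]:
                best = (key, MassMatch(pid, seq, z, theo, float(obs), float(obs - theo), idx))
        if best is not None:
            matches.append(best[1])
    return matches


def confirmed_peptides(matches: Iterable[MassMatch]) -> set[str]:
    """Peptide ids with at least one matched ladder entry."""
    return {m.peptide_id for m in matches}


@dataclass(frozen=True)
class PeptideProperties:
    """Property panel for one peptide, full precision (round only on report)."""

    seq: str
    amidated: bool
    length: int
    avg_mass: float
    mono_mass: float
    net_charge: int
    gravy: float
    helicity_pct: float | None = None


def peptide_properties(seq: str, amidated: bool = False, ss_string: str | None = None) -> PeptideProperties:
    seq = _check_sequence(seq)
    hel = helicity_percent(ss_string, seq) if ss_string is not None else None
    return PeptideProperties(
        seq=seq,
        amidated=amidated,
        length=len(seq),
        avg_mass=average_mass(seq, amidated),
        mono_mass=monoisotopic_mass(seq, amidated),
        net_charge=net_charge(seq, amidated),
        gravy=gravy(seq),
        helicity_pct=hel,
    )


def properties_table(
    peptides: Sequence,
    ss_strings: dict[str, str] | None = None,
    amidation_marker: str = "a",
) -> pd.DataFrame:
    """Reporting-layer property panel, rounded like a published table.

    Sequences carrying the amidation marker as a trailing lowercase suffix
    (e.g. ``AEWRLLKNa``) are treated as C-terminally amidated.
    """
    rows = []
    for pid, seq, ami in _as_peptide_tuples(peptides):
        if amidation_marker and seq.endswith(amidation_marker) and seq[-1].islower():
            seq, ami = seq[: -len(amidation_marker)], True
        ss = (ss_strings or {}).get(pid)
        p = peptide_properties(seq, ami, ss)
        rows.append(
            {
                "peptide": pid,
                "sequence": p.seq + (amidation_marker if p.amidated else ""),
                "length": p.length,
                "mw_da": round(p.avg_mass, 1),
                "net_charge": p.net_charge,
                "gravy": round(p.gravy, 2),
                "helicity_pct": round(p.helicity_pct, 1) if p.helicity_pct is not None else None,
            }
        )
    return pd.DataFrame(rows)
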