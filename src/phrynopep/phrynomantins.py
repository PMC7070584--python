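"""The published phrynomantin peptide panel.

The 19 peptides predicted from *Phrynomantis bifasciatus* (B) and
*P. microps* (M) skin transcripts, with the physicochemical values reported
alongside them (average molecular weight in Da, formal net charge at pH 7,
Kyte-Doolittle GRAVY, percent predicted helicity).  A trailing ``a`` on a
sequence marks C-terminal amidation.  These published values serve as the
reference against which this package's property calculations are checked.

One reported GRAVY value, phrynomantin-1Ba (0.84), differs from the
Kyte-Doolittle mean (9.1/11 = 0.83) by one rounding unit; every other row
agrees with the standard scale.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PanelRow", "PHRYNOMANTIN_PANEL", "GRAVY_DISCREPANT"]


@dataclass(frozen=True)
class PanelRow:
    name: str
    seq: str
    amidated: bool
    length: int
    mw_da: float
    net_charge: int
    gravy: float
    helicity_pct: float
    ms_confirmed: bool = False


PHRYNOMANTIN_PANEL: tuple[PanelRow, ...] = (
    PanelRow("phrynomantin-1Ba", "GLVTNLLSSVR", False, 11, 1158.4, 1, 0.84, 72.7),
    PanelRow("phrynomantin-1Bb", "GLVPDLDLPVDL", False, 12, 1265.5, -3, 0.79, 0.0),
    PanelRow("phrynomantin-1Bc", "GIVNNLLSTVL", False, 11, 1142.4, 0, 1.40, 81.8),
    PanelRow("phrynomantin-1Bd", "GPVFDYLSQVYPVR", False, 14, 1639.9, 0, 0.05, 50.0),
    PanelRow("phrynomantin-1Be", "GLVKDILSLDVL", False, 12, 1284.5, -1, 1.33, 66.7),
    PanelRow("phrynomantin-1Bf", "GLVPDLDLPVDLPV", False, 14, 1461.7, -3, 0.86, 0.0),
    PanelRow("phrynomantin-1Ma", "GLVKNQDLPVDLAAVF", False, 16, 1699.0, -1, 0.66, 12.5),
    PanelRow("phrynomantin-1Mb", "GLVKNLNLPVDVPVDL", False, 16, 1705.0, -1, 0.66, 0.0, True),
    PanelRow("phrynomantin-1Mc", "GLVKDLNLPVDVPVDLPV", False, 18, 1902.2, -2, 0.73, 0.0),
    PanelRow("phrynomantin-1Md", "GLVKDLLSLDV", False, 11, 1171.4, -1, 1.05, 63.6, True),
    PanelRow("phrynomantin-2Ba", "DYEAVSL", False, 7, 795.8, -2, 0.10, 0.0),
    PanelRow("phrynomantin-2Ma", "DYEPASL", False, 7, 793.8, -2, -0.73, 0.0),
    PanelRow("phrynomantin-3Ba", "SEWPPVRGDNGEYDVEL", False, 17, 1962.0, -4, -1.19, 0.0),
    PanelRow("phrynomantin-3Ma", "SEWPPVRGDAGEYDVEL", False, 17, 1919.0, -4, -0.88, 0.0),
    PanelRow("phrynomantin-3Mb", "AEWRLL", False, 6, 786.9, 0, 0.08, 0.0),
    PanelRow("phrynomantin-3Mc", "AEWRLLKN", True, 8, 1028.2, 2, -0.86, 0.0),
    PanelRow("phrynomantin-4Ba", "NAASRLYTPYSPTK", False, 14, 1568.7, 2, -0.95, 0.0),
    PanelRow("phrynomantin-4Bb", "NARNFNSFDPFNTSD", False, 15, 1745.8, -1, -1.28, 0.0),
    PanelRow("phrynomantin-4Ma", "NTENFFNPFNPFV", False, 13, 1586.7, -1, -0.46, 0.0, True),
)

#: Panel rows whose reported GRAVY departs from the Kyte-Doolittle mean.
GRAVY_DISCREPANT = ("phrynomantin-1Ba",)
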