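import numpy as np
import pytest

from phrynopep.annotate import (
    annotate_precursor,
    classify_segment,
    detect_signal_peptide,
    predict_mature_peptides,
    scan_cleavage_sites,
)
from phrynopep.synthetic import generate_precursor

SIG = "MKKLLLLLLLLLLSA"  # 15 aa, cleavage after position 14


def test_signal_called_at_first_small_residue_after_core():
    protein = "MK" + "L" * 12 + "ASA" + "DDEEDDEE" + "KR" + "GLVTNLLSSVR"
    call = detect_signal_peptide(protein)
    assert call is not None
    assert call.source == "builtin"
    assert protein[call.cleavage_pos] in "AGSC"
    assert call.cleavage_pos == 14  # first A/G/S/C past the Leu core
    assert call.score == pytest.approx(3.8, abs=1e-9)


def test_no_signal_on_hydrophilic_or_short_proteins():
    assert detect_signal_peptide("M" + "D" * 30) is None
    assert detect_signal_peptide("MKLLLLLLLLLASA"[:14]) is None


def test_non_met_start_warns_but_proceeds():
    with pytest.warns(UserWarning, match="Met"):
        call = detect_signal_peptide("K" + SIG[1:] + "DDEEDDEE" + "KR" + "GLVTNLLSSVR")
    assert call is not None


def test_cleavage_site_scan_and_resolution():
    assert [(s.motif, s.start, s.end) for s in scan_cleavage_sites("AAKRAA")] == [("KR", 2, 4)]
    # overlapping KR/RR: leftmost wins
    assert [(s.motif, s.start, s.end) for s in scan_cleavage_sites("AAKRRAA")] == [("KR", 2, 4)]
    # furin-like RXXR
    assert [(s.motif, s.start, s.end) for s in scan_cleavage_sites("ARVVRA")] == [("RXXR", 1, 5)]
    # leftmost RXXR beats a downstream overlapping RR
    assert [(s.motif, s.start, s.end) for s in scan_cleavage_sites("RVVRR")] == [("RXXR", 0, 4)]
    assert scan_cleavage_sites("") == []


def test_resolved_sites_never_overlap(rng):
    for _ in range(200):
        s = "".join(rng.choice(list("ARKGLVDE"), size=40))
        sites = scan_cleavage_sites(s)
        for a, b in zip(sites, sites[1:]):
            assert a.end <= b.start


def test_segment_classification():
    assert classify_segment("DEEDSEE") == "spacer"  # D/E 6/7
    assert classify_segment("GLVTNLLSSVR") == "peptide-candidate"
    assert classify_segment("DLPVDL") == "spacer"  # 2/6 = 0.33
    with pytest.raises(ValueError):
        classify_segment("")


def test_predict_mature_peptides_with_amidation():
    protein = SIG + "EEDDSE" + "KR" + "AEWRLLKN" + "G" + "KR" + "DYEAVSL"
    ann = annotate_precursor("pre1", protein, external_cleavage_pos=len(SIG))
    peps = predict_mature_peptides(ann)
    assert [(p.seq, p.amidated) for p in peps] == [("AEWRLLKN", True), ("DYEAVSL", False)]
    assert [p.ordinal for p in peps] == [1, 2]
    assert all(p.confidence == "normal" for p in peps)


def test_duplicate_tandem_peptides_keep_distinct_ordinals():
    protein = SIG + "EEDDEE" + "KR" + "GLVTNLLSSVQ" + "KR" + "GLVTNLLSSVQ"
    ann = annotate_precursor("pre", protein, external_cleavage_pos=len(SIG))
    peps = predict_mature_peptides(ann)
    assert [p.seq for p in peps] == ["GLVTNLLSSVQ", "GLVTNLLSSVQ"]
    assert [p.ordinal for p in peps] == [1, 2]


def test_terminal_gly_at_c_terminus_donates_amide():
    protein = SIG + "EEDDEE" + "KR" + "AEWLLKNG"
    ann = annotate_precursor("pre", protein, external_cleavage_pos=len(SIG))
    peps = predict_mature_peptides(ann)
    assert [(p.seq, p.amidated) for p in peps] == [("AEWLLKN", True)]


def test_short_fragments_are_discarded():
    protein = SIG + "EEDDEE" + "KR" + "AVL" + "KR" + "GLVTNLLSSVQ"
    ann = annotate_precursor("pre", protein, external_cleavage_pos=len(SIG))
    assert [p.seq for p in predict_mature_peptides(ann)] == ["GLVTNLLSSVQ"]


def test_zero_motif_precursors():
    # non-acidic post-signal region: one low-confidence peptide
    ann = annotate_precursor("pre", SIG + "GLVTNLLSSVQWLK", external_cleavage_pos=len(SIG))
    peps = predict_mature_peptides(ann)
    assert len(peps) == 1 and peps[0].confidence == "low"
    # acidic region (a bare spacer): nothing
    ann = annotate_precursor("pre", SIG + "DEEDSEEDDEE", external_cleavage_pos=len(SIG))
    assert predict_mature_peptides(ann) == []


def test_missing_signal_is_an_error():
    ann = annotate_precursor("pre", "M" + "D" * 40)
    assert ann.signal is None
    with pytest.raises(ValueError, match="signal"):
        predict_mature_peptides(ann)


def test_reassembly_and_no_internal_dibasics(rng):
    """Signal + segments + motifs + donated Gly tile the protein exactly."""
    for i in range(150):
        t = generate_precursor(rng=rng, precursor_id=f"p{i}")
        ann = annotate_precursor(t.precursor_id, t.protein_seq, external_cleavage_pos=t.cleavage_pos)
        pieces = sorted(
            [(s.start, s.end, s.seq) for s in ann.segments]
            + [(s.start, s.end, t.protein_seq[s.start : s.end]) for s in ann.sites],
        )
        rebuilt = t.protein_seq[: t.cleavage_pos] + "".join(p[2] for p in pieces)
        assert rebuilt == t.protein_seq
        for p in predict_mature_peptides(ann):
            assert "KR" not in p.seq and "RR" not in p.seq


def test_signal_heuristic_recovers_synthetic_cleavage_sites(rng):
    """>=90% of generated precursors get a builtin call within +-3 of truth."""
    hits = total = 0
    for i in range(200):
        t = generate_precursor(rng=rng, precursor_id=f"p{i}")
        call = detect_signal_peptide(t.protein_seq)
        total += 1
        if call is not None and abs(call.cleavage_pos - t.cleavage_pos) <= 3:
            hits += 1
    assert hits / total >= 0.90
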