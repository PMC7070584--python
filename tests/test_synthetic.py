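import numpy as np
import pytest

from phrynopep.annotate import annotate_precursor, predict_mature_peptides
from phrynopep.chemistry import PROTON_MASS, match_peaks, confirmed_peptides, monoisotopic_mass
from phrynopep.evaluate import exact_recovery
from phrynopep.orfs import find_orfs, translate
from phrynopep.synthetic import (
    PrecursorArchitecture,
    generate_peak_list,
    generate_precursor,
    generate_transcriptome,
    sample_tpm,
    write_transcriptome,
)


def _predict_all(transcriptome):
    out = []
    for contig in transcriptome.contigs:
        for orf in find_orfs(contig):
            ann = annotate_precursor(orf.orf_id, orf.aa_seq)
            if ann.signal is not None:
                out.extend(predict_mature_peptides(ann))
    return out


def test_precursor_invariants(rng):
    arch = PrecursorArchitecture()
    for i in range(150):
        t = generate_precursor(arch, rng=rng, precursor_id=f"p{i}")
        assert 44 <= len(t.protein_seq) <= 110
        assert t.protein_seq.startswith(t.signal_seq + t.spacer_seqs[0])
        assert translate(t.cds_nt) == t.protein_seq + "*"
        for spacer in t.spacer_seqs:
            de = (spacer.count("D") + spacer.count("E")) / len(spacer)
            assert de >= arch.min_spacer_acidity
        for seq, amidated in t.peptide_seqs:
            assert arch.peptide_len[0] <= len(seq) <= arch.peptide_len[1]
            pos = t.protein_seq.find(seq)
            assert pos >= 0
            if amidated:
                # amidated peptides are followed by the Gly donor then a motif
                assert t.protein_seq[pos + len(seq)] == "G"
                assert any(m_pos == pos + len(seq) + 1 for m_pos, _ in t.cleavage_motifs)
        for m_pos, name in t.cleavage_motifs:
            span = t.protein_seq[m_pos : m_pos + (4 if name == "RXXR" else 2)]
            if name == "RXXR":
                assert span[0] == "R" and span[3] == "R"
            else:
                assert span == name


def test_peptide_count_is_forced_by_config():
    t1 = generate_precursor(PrecursorArchitecture(n_peptides=1, amidation_prob=0.0), rng_seed=1)
    assert len(t1.peptide_seqs) == 1
    first_motif = t1.cleavage_motifs[0][1]
    assert first_motif in {"KR", "RR", "RXXR"}
    t3 = generate_precursor(PrecursorArchitecture(n_peptides=3), rng_seed=7)
    assert len(t3.peptide_seqs) == 3


def test_impossible_length_configs_are_rejected():
    with pytest.raises(ValueError, match="44-110"):
        generate_precursor(PrecursorArchitecture(n_peptides=3, peptide_len=(40, 45)), rng_seed=0)


def test_precursor_round_trip_with_oracle_signal(rng):
    recovered = 0
    for i in range(200):
        t = generate_precursor(rng=rng, precursor_id=f"p{i}")
        ann = annotate_precursor(t.precursor_id, t.protein_seq, external_cleavage_pos=t.cleavage_pos)
        recovered += exact_recovery(t, predict_mature_peptides(ann))
    assert recovered / 200 >= 0.95


def test_transcriptome_embeds_each_cds_exactly_once(small_transcriptome):
    tx = small_transcriptome
    assert len(tx.truths) == 5
    for t in tx.truths:
        carriers = [c.contig_id for c in tx.contigs if t.cds_nt in c.seq_nt]
        assert carriers == [t.contig_id]


def test_seeded_runs_are_byte_identical(tmp_path):
    a = generate_transcriptome(3, 9, rng_seed=5)
    b = generate_transcriptome(3, 9, rng_seed=5)
    assert [(c.contig_id, c.seq_nt, c.tpm) for c in a.contigs] == [
        (c.contig_id, c.seq_nt, c.tpm) for c in b.contigs
    ]
    pa = write_transcriptome(a, tmp_path / "a")
    pb = write_transcriptome(b, tmp_path / "b")
    for key in pa:
        assert pa[key].read_bytes() == pb[key].read_bytes()


def test_decoy_only_transcriptome_yields_no_peptides():
    tx = generate_transcriptome(0, 10, rng_seed=1)
    assert _predict_all(tx) == []


def test_tpm_distribution_tail_and_total(rng):
    tpm, n_high = sample_tpm(10000, rng, tail_prob=0.005, threshold=100.0)
    assert tpm.sum() == pytest.approx(1e6, rel=1e-9)
    count = int((tpm > 100.0).sum())
    assert count == n_high
    # within 3 binomial standard errors of the configured expectation
    sd = np.sqrt(10000 * 0.005 * 0.995)
    assert abs(count - 50) <= 3 * sd


def test_forced_high_group_for_precursors(small_transcriptome):
    for t in small_transcriptome.truths:
        assert t.tpm > 100.0


def test_peak_list_zero_noise_is_exact():
    pep = ("p1", "GLVKNLNLPVDVPVDL", False)
    peaks, truth = generate_peak_list([pep], charges=(2,), mz_noise_sd=0.0, rng_seed=1)
    theo = (monoisotopic_mass(pep[1]) + 2 * PROTON_MASS) / 2
    assert len(peaks) == 1
    assert peaks["mz"].iloc[0] == pytest.approx(theo, abs=1e-9)
    assert truth["peptide_id"].iloc[0] == "p1"


def test_peak_list_bounds_and_decoys(rng):
    peps = [("a", "GLVTNLLSSVR", False), ("b", "AEWRLLKN", True), ("c", "DYEAVSL", False)]
    peaks, truth = generate_peak_list(peps, charges=(1, 2, 3), mz_noise_sd=0.1,
                                      n_decoy_peaks=50, rng_seed=3)
    assert ((peaks["mz"] >= 100.0) & (peaks["mz"] <= 3000.0)).all()
    assert (truth["peptide_id"] == "decoy").sum() == 50
    matches = match_peaks(peps, peaks, tol=0.5, z_range=(1, 3))
    assert confirmed_peptides(matches) >= {"a", "b", "c"}

    empty, truth0 = generate_peak_list([], charges=(1, 2), mz_noise_sd=0.1,
                                       n_decoy_peaks=7, rng_seed=2)
    assert len(empty) == 7 and (truth0["peptide_id"] == "decoy").all()


def test_peak_list_rejects_bad_charges():
    with pytest.raises(ValueError, match="1..5"):
        generate_peak_list([("a", "GLVTNLLSSVR", False)], charges=(0, 2), rng_seed=0)
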