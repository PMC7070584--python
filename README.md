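# phrynopep

Frog skin secretions are rich in short bioactive peptides that are cleaved
out of secretory precursor proteins of the FSAP ("Frog Skin Active Peptide")
superfamily. Each precursor carries an N-terminal signal peptide, an acidic
(Asp/Glu-rich) spacer, and one to three mature peptides bounded by
prohormone-convertase cleavage motifs — Lys-Arg (KR), Arg-Arg (RR), or the
furin-like R-X-X-R. `phrynopep` is a small library and CLI for mining such
precursors from assembled skin transcriptomes, written for peptide
biologists who have transcript contigs with expression estimates (TPM) and
want predicted mature peptides, their physicochemical panel, and LC-MS
confirmation by theoretical m/z matching. The phrynomantins — a structurally
diverse, mostly anionic peptide family predicted from *Phrynomantis*
(Microhylidae) skin transcripts — are the motivating use case, and the 19
published phrynomantins ship with the package as a reference panel.

## What it computes

For a translated open reading frame *P* (Met-initiated, stop-terminated,
nucleotide span > 150 bp including the stop codon, scanned on both strands):

* **Signal peptide** — a pluggable call; the built-in heuristic finds the
  8-residue window in positions 1–35 with maximal mean Kyte–Doolittle
  hydropathy ⟨h⟩ and calls a signal when ⟨h⟩ ≥ 2.0, cleaving at the first
  small residue (A/G/S/C) after the window. External predictor output
  overrides the heuristic.
* **Cleavage sites** — all KR/RR/RXXR matches, resolved leftmost-first
  (RXXR > KR > RR at equal start); motif residues are excised.
* **Mature peptides** — post-signal segments between motifs, N→C; acidic
  spacer segments (D+E fraction ≥ 0.30, or net charge ≤ −2 with D+E ≥ 0.20)
  are dropped; a Gly immediately preceding a motif (or exposed at the C
  terminus) donates a C-terminal amide and is removed.
* **Property panel** — length; average and monoisotopic mass from elemental
  composition (amidation −0.98 Da); formal net charge at pH 7
  (+1 K/R, −1 D/E, His neutral, free termini cancel, amide termini +1);
  GRAVY = mean Kyte–Doolittle hydropathy; percent helicity from an external
  secondary-structure string.
* **ESI+ confirmation** — theoretical [M+zH]ᶻ⁺ ladders,
  m/z = (M + z·1.00728)/z inside the 100–3000 scan window, greedily matched
  to observed peaks (smallest |Δm/z|, ties to lower z).
* **Variant search** — each query peptide of length L expands to 1 + 19·L
  single-substitution isoforms (two 10-mers → 382 sequences) screened as
  exact substrings of the translated library.
* **Expression report** — per-family contig counts and ΣTPM, and the count
  of contigs above a TPM threshold (strictly > 100 by default).
* **Assay arithmetic** — MIC from two-fold dilution series and cytotoxicity
  percent, 100 × (OD_obs − OD₀)/(OD₁₀₀ − OD₀).

Because no raw sequencing data are deposited for this system, the package
includes a first-class synthetic-transcriptome generator
(`phrynopep.synthetic`) that emits Trinity-style contig FASTA with a skewed
TPM profile, embedded FSAP-like precursors with known architecture, three
decoy categories, and ESI+ peak lists — so every stage is tested against
known ground truth.

## Worked example

Property panel for three published phrynomantins (the trailing `a` marks
C-terminal amidation):

```python
from phrynopep.chemistry import properties_table
print(properties_table([
    ("phrynomantin-1Ba", "GLVTNLLSSVR", False),
    ("phrynomantin-2Ba", "DYEAVSL", False),
    ("phrynomantin-3Mc", "AEWRLLKNa", False),
], ss_strings={"phrynomantin-1Ba": "CHHHHHHHHCC"}).to_string(index=False))
```

```
         peptide    sequence  length  mw_da  net_charge  gravy  helicity_pct
phrynomantin-1Ba GLVTNLLSSVR      11 1158.4           1   0.83          72.7
phrynomantin-2Ba     DYEAVSL       7  795.8          -2   0.10           NaN
phrynomantin-3Mc   AEWRLLKNa       8 1028.2           2  -0.86           NaN
```

The masses and charges match the published panel (1158.4 Da/+1,
795.8 Da/−2, 1028.2 Da/+2 for the amidated peptide); helicity is 8 helical
states out of 11 residues = 72.7%.

End-to-end on a synthetic transcriptome:

```
$ phrynopep simulate --precursors 5 --decoys 15 --seed 2 --outdir demo
20 contigs, 5 ground-truth precursors -> demo
$ phrynopep run-all --contigs demo/contigs.fasta --expression demo/expression.tsv \
      --annotation demo/annotation.tsv --peaks demo/peaks.tsv --outdir demo/run
run complete -> demo/run
$ head -3 demo/run/peptides.tsv
precursor_id	ordinal	sequence	amidated	confidence
TRINITY_DN1_c0_g1_i1|+|1|58-310	1	ISWPYSVLLDLGILT	False	normal
TRINITY_DN1_c0_g1_i1|+|1|58-310	2	ILGMTAGSSNGLVTADA	False	normal
```

`demo/run/` then contains the ORF table, peptide predictions, property
panel, m/z match report, family-level expression report and a manifest with
input checksums and the resolved configuration.

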