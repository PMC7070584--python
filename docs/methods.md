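# Methods

## The precursor model

`phrynopep` assumes the canonical FSAP-superfamily architecture for
secretory skin-peptide precursors: an N-terminal signal peptide, an acidic
spacer, and 1–3 mature peptides released at prohormone-convertase motifs
(KR, RR, furin-like RXXR). Precursors are 44–110 residues. A Gly
immediately N-terminal to a cleavage motif — or exposed at the precursor C
terminus — is the amide donor of standard prohormone biochemistry: the
mature peptide is C-terminally amidated and the Gly is removed. The
published panel marks amidation only on the final sequences, so the
generative Gly rule is this package's inference; it is applied symmetrically
in the synthetic generator and the annotator.

## ORF extraction

ORFs are ATG-initiated and stop-terminated, scanned in all six frames.
The nucleotide span *includes* the stop codon and must be **strictly**
greater than `min_nt` (default 150). Whether the conventional ">150 bp"
screen counts the stop codon is ambiguous; we include it and expose the
cutoff, so either convention is reachable. Only the longest ORF per
(strand, frame, stop) is reported by default (`all_starts=True` emits
nested ORFs). Codons containing N translate to X and the ORF is flagged
rather than dropped. Coordinates are 0-based half-open on the input strand
throughout; conversion to 1-based display is left to reporting layers.

Consequence worth knowing: a precursor shorter than 50 aa has a CDS span of
at most 150 nt and is invisible at the default cutoff. The 44–49 aa corner
of the precursor length range therefore only enters the pipeline if
`orf_min_nt` is lowered (132 nt admits every 44-aa precursor). This is the
main recall limit observed in end-to-end runs on synthetic data
(F1 ≈ 0.95–0.97 at the default cutoff versus 1.0 at the annotator level).

## Signal peptide heuristic

The built-in call is intentionally simple and pluggable: the 8-residue
window within positions 1–35 with maximal mean Kyte–Doolittle hydropathy
must reach 2.0; the cleavage position is the first A/G/S/C after the window
within positions 10–40 (fallback: window end + 5, capped at 40). Proteins
shorter than 15 aa get no call. An external predictions table
(protein_id → cleavage position) always overrides the heuristic. The
heuristic lands within ±3 residues of the true cleavage on essentially all
generated precursors; peptide predictions are insensitive to that error
because the residues it misassigns move between the signal and the acidic
spacer, which is dropped either way.

## Cleavage-site resolution

All candidate KR, RR and RXXR matches are collected (X is any residue
except R, which prevents double-counting nested RR) and resolved greedily:
leftmost start wins; at equal start the longer RXXR outranks RR. Motif
residues are excised and belong to neither flanking fragment; the
alternative convention (dibasic retained on the upstream fragment) is not
the default and deliberately not implemented until someone needs it.
RXXR excises all four residues; published processing data do not settle
whether only the terminal R should go, and the full-span choice keeps
resolution deterministic.

## Segment classification and the C-terminal rule

A segment is an acidic spacer when its D+E fraction is ≥ 0.30, or when it
is strongly anionic (formal net charge ≤ −2) with D+E ≥ 0.20; both
thresholds and the charge cutoff are configuration keys. Composition alone,
however, cannot separate spacers from strongly anionic mature peptides —
several published phrynomantins (e.g. DYEAVSL at D+E = 0.43) would classify
as spacers. The package therefore adds a positional rule reflecting the
precursor biology: the C-terminal segment after the last cleavage motif is
always a mature-peptide candidate, whatever its composition, since FSAP
mature peptides lie C-terminal to their spacers. A precursor with a signal
call but no motifs yields a single low-confidence peptide spanning the
post-signal region, unless that region itself classifies as a spacer (then
nothing is predicted). Peptides shorter than 4 residues after processing
are discarded (the shortest published phrynomantin is 6).

## Property panel conventions

* **Masses** are element-based: the peptide formula is assembled (via
  pyteomics) and averaged over natural isotopic abundances, rather than
  summed from a fixed residue-mass table. The published panel's MW column
  is reproduced within 0.1 Da on all 19 rows this way; three rows sit on a
  0.05-Da rounding edge where classical residue-mass tables round the other
  way. Amidation replaces the C-terminal OH with NH2 (−0.98 Da average).
  Monoisotopic masses use the same compositions and exist for MS matching.
* **Net charge** is the integer formal-counting model the panel prints:
  +1 per K/R, −1 per D/E, His neutral at pH 7 (counted +1 below pH 6; no
  His occurs in the published panel, so this is unconstrained there), free
  termini cancel, amidated termini net +1.
* **GRAVY** is the mean Kyte–Doolittle index. One published row
  (GLVTNLLSSVR, reported 0.84) differs from the scale mean (9.1/11 = 0.827)
  by one rounding unit; every other row agrees to 0.01. That row is treated
  as a source-side rounding discrepancy and excluded from exact GRAVY
  checks.
* **Helicity** is 100 × (#H)/length from a per-residue H/E/C string
  supplied by an external secondary-structure predictor; only the
  conversion is in scope.
* Rounding (0.1 Da, 0.01 GRAVY, 0.1% helicity) happens only in reporting
  layers; all internal comparisons use full precision.

## ESI+ matching

Theoretical ladders use m/z = (M + z·1.00728)/z for charge states whose
m/z falls inside the 100–3000 scan window. Each observed peak is assigned
to at most one (peptide, z): smallest |Δ|, ties to the lower charge state,
then input order — a deterministic stand-in for manual spectrum inspection.
A peptide is confirmed when ≥ 1 ladder entry matches within tolerance
(default 0.5 Da/e). Decoy peaks that match are reported for inspection, not
suppressed.

## Variant search

Query peptides expand to all single-substitution isoforms (1 + 19L
sequences per length-L query; duplicates arising from overlapping originals
are stored once) and every member is matched as an exact, case-insensitive
substring; X in the protein never matches. This reproduces text-editor
screening of translated libraries and equals a direct Hamming-distance-≤1
scan, which the tests verify by brute force.

## The synthetic generator

The generator emits what the analysis needs to be measurable, not a
sequencing simulator:

* **Precursors** — signal = Met + polar n-region (K/N/Q/T, 2–4) +
  hydrophobic core (L/I/V/F, ≥ 9) + small c-region (A/S, 2–3); spacer of
  length 8–14 with D+E fraction ≥ 0.5; 1–3 peptides of 6–18 residues with
  broad, R-poor composition, D+E < 0.20, never ending in Gly; amidation
  probability 0.3 adds the Gly donor plus a following motif; motifs drawn
  KR/RR/RXXR at 0.45/0.45/0.10. Assembly is rejection-sampled until the
  total length is 44–110 aa and an independent regex-based resolver finds
  exactly the intended motifs (no spurious junction motifs). Proteins are
  reverse-translated with uniformly random synonymous codons, so
  nucleotide-level tests stay non-trivial.
* **Contigs** — each CDS sits in random UTRs with an in-frame stop planted
  immediately 5' of the ATG, so the reported ORF is exactly the truth
  protein. Decoys cycle three categories: (a) random sequence
  rejection-sampled to contain no ORF above the cutoff ("non-coding" by
  construction); (b) ORFs with hydrophilic N termini, resampled until no
  ORF in the contig receives a signal call; (c) signal-bearing ORFs with
  acidic, K/R-free bodies, resampled until no ORF yields a predicted
  peptide. Sanitising decoys is what the categories mean — truth contigs
  are *not* sanitised, so incidental reverse-strand ORFs remain possible
  there and precision is measured honestly.
* **TPM** — transcripts-per-million must sum to 10⁶ while only a small
  fraction of contigs exceeds the 100-TPM screening threshold. With
  n·mean(TPM) pinned to 10⁶, a single log-normal satisfying the tail
  constraint puts nearly all library mass into a few contigs and the
  normalising sum no longer concentrates, which distorts the realised tail
  badly (simulated 142 ± 63 instead of 50 ± 7 at n = 10⁴). The model is
  therefore a two-component construction: a Binomial(n, 0.005) sample of
  highly expressed contigs receives 70% of the library, the bulk the rest,
  with log-normal within-group weights (σ = 1.0 / 0.7) and a hard
  separation band (high group ≥ 1.25×, bulk ≤ 0.8× the threshold, enforced
  by iterative clip-and-redistribute). The sum is exactly 10⁶ and the
  above-threshold count is exactly binomial. Embedded precursor contigs are
  always in the high group, mirroring the consistently high expression of
  FSAP transcripts in real skin libraries.
* **Peak lists** — one peak per (peptide, charge) inside the scan window,
  monoisotopic, Gaussian m/z jitter redrawn until inside the window,
  log-uniform intensities, uniform decoy peaks, and a peak-level
  ground-truth sidecar.

What the generator does **not** emulate: read-level errors, isoform or
assembly artefacts, chimeras, GC bias (decoy nucleotides are i.i.d.
uniform), co/post-translational chemistry beyond amidation, and real LC
retention behaviour (retention times are uniform noise). Passing recovery
tests therefore demonstrate the correctness of the inference logic on clean
precursors of the modelled architecture, not robustness to assembly noise
or to precursor architectures outside it.

## Determinism and problem sizes

All randomness flows through a seeded `numpy.random.Generator`; equal seeds
give byte-identical outputs. The test suite and the acceptance script use
500 generated precursors for recovery statistics, 1000 random contigs for
the six-frame oracle comparison, a 30-precursor/60-decoy transcriptome for
the end-to-end figure, and 10⁴ contigs for the TPM tail check; the whole
suite runs in a few seconds on one CPU.

## Known limitations

* Sub-50-aa precursors are invisible at the default ORF cutoff (above).
* The signal heuristic is a deliberately crude stand-in; real analyses
  should feed an external predictor's cleavage positions through the
  override table.
* Composition thresholds for spacers are tuned to the FSAP architecture;
  precursor families with basic spacers or internal acidic peptides would
  need the configuration keys adjusted.
* Exact per-precursor regression against the published precursor set is
  impossible — the precursor protein sequences are not available in
  machine-readable form — so recovery is validated on synthetic data and
  the published mature-peptide panel.
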