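"""End-to-end pipeline: contigs -> ORFs -> precursors -> peptides -> reports.

Every stage writes plain-text intermediates (FASTA/TSV) into the run
directory so each step can be re-run and audited independently, and a
machine-readable manifest records the resolved configuration and input
checksums.  Runs are deterministic given config + inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io as pio
from .annotate import annotate_precursor, predict_mature_peptides
from .chemistry import match_peaks, properties_table
from .expression import aggregate_family_tpm, count_above_threshold
from .orfs import find_orfs
from .search import expand_single_substitution_variants, search_library

__all__ = ["PipelineConfig", "PipelineInputs", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration for a pipeline run (serialisable to YAML)."""

    orf_min_nt: int = 150
    orf_strands: str = "both"  # 'both' | 'forward' | 'reverse'
    signal_mode: str = "builtin"  # 'builtin' or path to an external table
    spacer_de_fraction: float = 0.30
    acidic_de_fraction: float = 0.20
    acidic_net_charge: int = -2
    min_peptide_length: int = 4
    ms_tolerance: float = 0.5
    ms_z_min: int = 1
    ms_z_max: int = 3
    tpm_threshold: float = 100.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class PipelineInputs:
    contigs_fasta: str | Path
    expression_tsv: str | Path | None = None
    annotation_tsv: str | Path | None = None
    peaks: str | Path | None = None
    signal_table: str | Path | None = None
    queries: list[str] = field(default_factory=list)
    ss_table: str | Path | None = None


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _strands(cfg: PipelineConfig):
    return {"both": ("+", "-"), "forward": ("+",), "reverse": ("-",)}[cfg.orf_strands]


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs, outdir: str | Path) -> Path:
    """Run all stages and return the run directory.

    Emits ``orfs.tsv``/``proteins.faa``, ``peptides.tsv``, ``properties.tsv``,
    optionally ``matches.tsv`` and ``search_hits.tsv``, ``family_report.tsv``,
    ``summary.json`` and ``manifest.json``.  Any stage failure aborts with
    the stage name and the offending record in the message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    contigs = pio.read_contigs(inputs.contigs_fasta, inputs.expression_tsv)

    # --- ORF stage -------------------------------------------------------
    orfs = []
    for contig in contigs:
        try:
            orfs.extend(find_orfs(contig, min_nt=config.orf_min_nt, strands=_strands(config)))
        except ValueError as exc:
            raise RuntimeError(f"orf stage failed on contig {contig.contig_id!r}: {exc}") from exc
    pd.DataFrame(
        [
            {
                "orf_id": o.orf_id,
                "contig_id": o.contig_id,
                "strand": o.strand,
                "frame": o.frame,
                "nt_start": o.nt_start,
                "nt_end": o.nt_end,
                "aa_seq": o.aa_seq,
                "has_ambiguous": o.has_ambiguous,
            }
            for o in orfs
        ],
        columns=["orf_id", "contig_id", "strand", "frame", "nt_start", "nt_end", "aa_seq", "has_ambiguous"],
    ).to_csv(outdir / "orfs.tsv", sep="\t", index=False)
    pio.write_fasta(outdir / "proteins.faa", [(o.orf_id, o.aa_seq) for o in orfs])

    # --- precursor annotation and peptide prediction ---------------------
    external = {}
    if config.signal_mode != "builtin":
        external = pio.read_signal_table(config.signal_mode)
    elif inputs.signal_table is not None:
        external = pio.read_signal_table(inputs.signal_table)
    classify_kwargs = dict(
        spacer_de_fraction=config.spacer_de_fraction,
        acidic_de_fraction=config.acidic_de_fraction,
        acidic_net_charge=config.acidic_net_charge,
    )
    peptides = []
    for orf in orfs:
        try:
            ann = annotate_precursor(
                orf.orf_id,
                orf.aa_seq,
                external_cleavage_pos=external.get(orf.orf_id),
                **classify_kwargs,
            )
            if ann.signal is None:
                continue
            peptides.extend(predict_mature_peptides(ann, min_length=config.min_peptide_length))
        except ValueError as exc:
            raise RuntimeError(f"annotation stage failed on ORF {orf.orf_id!r}: {exc}") from exc
    pep_df = pd.DataFrame(
        [
            {
                "precursor_id": p.precursor_id,
                "ordinal": p.ordinal,
                "sequence": p.seq,
                "amidated": p.amidated,
                "confidence": p.confidence,
            }
            for p in peptides
        ],
        columns=["precursor_id", "ordinal", "sequence", "amidated", "confidence"],
    )
    pep_df.to_csv(outdir / "peptides.tsv", sep="\t", index=False)

    # --- property panel ---------------------------------------------------
    ss = pio.read_ss_table(inputs.ss_table) if inputs.ss_table else None
    props = properties_table(peptides, ss_strings=ss)
    props.to_csv(outdir / "properties.tsv", sep="\t", index=False)

    # --- LC-MS confirmation ----------------------------------------------
    n_confirmed = None
    if inputs.peaks is not None:
        peaks = pio.read_peak_list(inputs.peaks)
        matches = match_peaks(
            peptides, peaks, tol=config.ms_tolerance, z_range=(config.ms_z_min, config.ms_z_max)
        )
        pd.DataFrame(
            [
                {
                    "peptide_id": m.peptide_id,
                    "sequence": m.seq,
                    "z": m.z,
                    "theoretical_mz": round(m.theoretical_mz, 4),
                    "observed_mz": round(m.observed_mz, 4),
                    "delta": round(m.delta, 4),
                    "peak_index": m.peak_index,
                }
                for m in matches
            ],
            columns=["peptide_id", "sequence", "z", "theoretical_mz", "observed_mz", "delta", "peak_index"],
        ).to_csv(outdir / "matches.tsv", sep="\t", index=False)
        n_confirmed = len({m.peptide_id for m in matches})

    # --- variant search ----------------------------------------------------
    if inputs.queries:
        lib = expand_single_substitution_variants(list(inputs.queries))
        hits, summary = search_library(lib, [(o.orf_id, o.aa_seq) for o in orfs])
        pd.DataFrame(
            [
                {
                    "member": h.member,
                    "protein_id": h.protein_id,
                    "offset": h.offset,
                    "original": h.original,
                    "n_mismatches": h.n_mismatches,
                }
                for h in hits
            ],
            columns=["member", "protein_id", "offset", "original", "n_mismatches"],
        ).to_csv(outdir / "search_hits.tsv", sep="\t", index=False)
    else:
        summary = None

    # --- expression report -------------------------------------------------
    if inputs.expression_tsv is not None:
        expr = pio.read_expression_table(inputs.expression_tsv)
        if inputs.annotation_tsv is not None:
            fam = pio.read_annotation_table(inputs.annotation_tsv)
            expr = expr.merge(fam, on="contig_id", how="left")
        report = aggregate_family_tpm(expr)
        report.to_csv(outdir / "family_report.tsv", sep="\t", index=False, float_format="%.1f")
        n_above = count_above_threshold(expr, config.tpm_threshold)
    else:
        n_above = None

    summary_payload = {
        "n_contigs": len(contigs),
        "n_orfs": len(orfs),
        "n_peptides": len(peptides),
        "n_peptides_normal_confidence": int(sum(p.confidence == "normal" for p in peptides)),
        "n_ms_confirmed": n_confirmed,
        "n_contigs_above_tpm_threshold": n_above,
        "search_summary": summary,
    }
    (outdir / "summary.json").write_text(json.dumps(summary_payload, indent=2))

    input_paths = {
        "contigs_fasta": inputs.contigs_fasta,
        "expression_tsv": inputs.expression_tsv,
        "annotation_tsv": inputs.annotation_tsv,
        "peaks": inputs.peaks,
        "signal_table": inputs.signal_table,
        "ss_table": inputs.ss_table,
    }
    manifest = {
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config.to_dict(),
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in input_paths.items() if v},
        "queries": list(inputs.queries),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
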