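"""Family-level expression summaries from contig TPM tables.

Homology assignments (the protein family per contig) come from an input
annotation table; this module only aggregates.  The conventional screening
count is the number of contigs expressed above a TPM threshold (strictly
greater than, 100 TPM by default).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["aggregate_family_tpm", "count_above_threshold", "UNANNOTATED_LABEL"]

UNANNOTATED_LABEL = "(unannotated)"


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "contig_id": getattr(r, "contig_id", None) or r[0],
                    "tpm": getattr(r, "tpm", None) if hasattr(r, "tpm") else r[1],
                    "family": getattr(r, "family", None) if hasattr(r, "family") else (r[2] if len(r) > 2 else None),
                }
                for r in records
            ],
            columns=["contig_id", "tpm", "family"],
        )
    if "family" not in df.columns:
        df["family"] = None
    if (df["tpm"] < 0).any():
        raise ValueError("negative TPM value in expression records")
    return df


def aggregate_family_tpm(records) -> pd.DataFrame:
    """Per-family contig counts and summed TPM, plus an unannotated remainder row.

    One row per family with ``n_contigs`` and ``sum_tpm``; records without a
    family label are excluded from family rows but reported in a final
    remainder row so that total TPM is conserved.  Duplicate contig ids are
    an error (upstream clustering should have removed redundancy).
    """
    df = _as_frame(records)
    if df.empty:
        return pd.DataFrame(columns=["family", "n_contigs", "sum_tpm"])
    dupes = df["contig_id"][df["contig_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate contig id(s): {sorted(set(dupes))}")
    annotated = df[df["family"].notna()]
    out = (
        annotated.groupby("family", sort=False)
        .agg(n_contigs=("contig_id", "size"), sum_tpm=("tpm", "sum"))
        .reset_index()
        .sort_values("sum_tpm", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    rest = df[df["family"].isna()]
    if not rest.empty:
        out = pd.concat(
            [
                out,
                pd.DataFrame(
                    [{"family": UNANNOTATED_LABEL, "n_contigs": len(rest), "sum_tpm": rest["tpm"].sum()}]
                ),
            ],
            ignore_index=True,
        )
    return out


def count_above_threshold(records, threshold: float = 100.0) -> int:
    """Number of contigs with TPM strictly greater than *threshold*."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    df = _as_frame(records)
    return int((df["tpm"] > threshold).sum())
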