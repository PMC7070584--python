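"""Recovery metrics: predicted peptides vs synthetic ground truth."""

from __future__ import annotations

from collections import Counter
from typing import Iterable

from .annotate import MaturePeptide
from .synthetic import GroundTruthPrecursor

__all__ = ["recovery_metrics", "exact_recovery"]


def _truth_multiset(truths: Iterable[GroundTruthPrecursor]) -> Counter:
    return Counter((seq, ami) for t in truths for seq, ami in t.peptide_seqs)


def recovery_metrics(
    truths: Iterable[GroundTruthPrecursor],
    predicted: Iterable[MaturePeptide],
    min_confidence: str = "normal",
) -> dict[str, float]:
    """Peptide-level precision/recall/F1 on (sequence, amidation) multisets.

    ``min_confidence='normal'`` scores only normal-confidence predictions;
    pass ``'low'`` to include the low-confidence whole-region peptides.
    """
    truth = _truth_multiset(truths)
    pred = Counter(
        (p.seq, p.amidated)
        for p in predicted
        if min_confidence == "low" or p.confidence == "normal"
    )
    tp = sum((truth & pred).values())
    n_pred, n_true = sum(pred.values()), sum(truth.values())
    precision = tp / n_pred if n_pred else 1.0
    recall = tp / n_true if n_true else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "tp": tp, "n_pred": n_pred, "n_true": n_true}


def exact_recovery(truth: GroundTruthPrecursor, predicted: list[MaturePeptide]) -> bool:
    """True when the predicted list equals the truth exactly, in order."""
    return [(p.seq, p.amidated) for p in predicted] == list(truth.peptide_seqs)
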