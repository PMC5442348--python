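"""Evaluation: precision / recall / F1 and decile learning curves.

Comparison is at the clinical-finding level: predicted and gold value lists
are normalized through the controlled vocabulary (synonym -> canonical) and
compared as sets of canonical strings.  Micro-averaging pools true/false
positive and false negative counts across attributes and documents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .vocabulary import ControlledVocabulary, normalize_value

__all__ = ["EvalCounts", "LearningCurve", "compare_values", "compute_prf",
           "learning_curve", "evaluate_run", "write_report"]


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class LearningCurve:
    #: (group index, precision, recall) per contiguous block of documents
    points: list[tuple[int, float, float]]


def compare_values(
    predicted: list[str],
    gold: list[str],
    vocab: ControlledVocabulary | None = None,
) -> EvalCounts:
    """Set-based exact canonical matching after vocabulary normalization."""
    p = {normalize_value(v, vocab, "transform").casefold() for v in predicted}
    g = {normalize_value(v, vocab, "transform").casefold() for v in gold}
    return EvalCounts(tp=len(p & g), fp=len(p - g), fn=len(g - p))


def compute_prf(counts: EvalCounts) -> tuple[float, float, float]:
    """Precision, recall, F1.

    Conventions for empty denominators: with no predictions (tp+fp = 0),
    precision is 1.0 when nothing was missed (fn = 0) and 0.0 otherwise;
    recall mirrors this with fp.  F1 is 0 when p + r = 0.
    """
    if counts.tp + counts.fp == 0:
        precision = 1.0 if counts.fn == 0 else 0.0
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall = 1.0 if counts.fp == 0 else 0.0
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def learning_curve(per_doc_counts: list[EvalCounts], n_groups: int) -> LearningCurve:
    """Partition documents (in processing order) into ``n_groups`` contiguous
    blocks — any remainder spread over the first blocks — and compute micro
    precision/recall per block."""
    n = len(per_doc_counts)
    if not (1 <= n_groups <= n):
        raise ValueError("n_groups must be in [1, %d], got %d" % (n, n_groups))
    base, rem = divmod(n, n_groups)
    points = []
    start = 0
    for g in range(n_groups):
        size = base + (1 if g < rem else 0)
        block = per_doc_counts[start:start + size]
        start += size
        total = EvalCounts()
        for c in block:
            total = total + c
        p, r, _ = compute_prf(total)
        points.append((g, p, r))
    return LearningCurve(points)


# ---------------------------------------------------------------------------
# run-level evaluation
# ---------------------------------------------------------------------------

def evaluate_run(
    predictions: dict[str, dict[str, list[str]]],
    gold: dict[str, dict[str, list[str]]],
    vocabs: dict[str, ControlledVocabulary] | None = None,
    doc_order: list[str] | None = None,
    n_groups: int = 10,
) -> dict:
    """Pooled and per-attribute P/R/F1 plus the decile learning curve.

    ``predictions`` and ``gold`` map doc_id -> attribute -> values; documents
    are evaluated in ``doc_order`` (default: sorted doc_ids).  Documents with
    neither prediction nor gold entries still count (as vacuously correct).
    """
    vocabs = vocabs or {}
    doc_order = doc_order or sorted(set(predictions) | set(gold))
    attrs = sorted({a for d in list(predictions.values()) + list(gold.values()) for a in d})
    per_attr: dict[str, EvalCounts] = {a: EvalCounts() for a in attrs}
    per_doc: list[EvalCounts] = []
    for doc_id in doc_order:
        doc_total = EvalCounts()
        for attr in attrs:
            c = compare_values(
                predictions.get(doc_id, {}).get(attr, []),
                gold.get(doc_id, {}).get(attr, []),
                vocabs.get(attr),
            )
            per_attr[attr] = per_attr[attr] + c
            doc_total = doc_total + c
        per_doc.append(doc_total)
    pooled = EvalCounts()
    for c in per_attr.values():
        pooled = pooled + c
    p, r, f1 = compute_prf(pooled)
    result = {
        "pooled": {"tp": pooled.tp, "fp": pooled.fp, "fn": pooled.fn,
                   "precision": p, "recall": r, "f1": f1},
        "per_attribute": {
            a: dict(zip(("precision", "recall", "f1"), compute_prf(c)),
                    tp=c.tp, fp=c.fp, fn=c.fn)
            for a, c in per_attr.items()
        },
        "n_documents": len(doc_order),
    }
    if len(per_doc) >= n_groups >= 1:
        curve = learning_curve(per_doc, n_groups)
        result["learning_curve"] = [
            {"group": g, "precision": pp, "recall": rr} for g, pp, rr in curve.points
        ]
    return result


def write_report(result: dict, out_dir: str | Path, stem: str = "evaluation") -> None:
    """Write the evaluation result as JSON plus CSV tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"{stem}.json", "w", encoding="utf-8") as fh:
        json.dump(result, fh, indent=1, sort_keys=True)
    rows = [{"attribute": a, **m} for a, m in result["per_attribute"].items()]
    rows.append({"attribute": "__pooled__", **result["pooled"]})
    pd.DataFrame(rows).to_csv(out_dir / f"{stem}_metrics.csv", index=False)
    if "learning_curve" in result:
        pd.DataFrame(result["learning_curve"]).to_csv(
            out_dir / f"{stem}_curve.csv", index=False
        )
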