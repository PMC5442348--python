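"""Answer assembly: rank candidates, select per cardinality, aggregate.

Sentence and chunk scores combine linearly into a confidence; single-valued
attributes take the highest-confidence candidate above the acceptance
threshold, multi-valued attributes take everything above it.  Results from a
patient's multiple reports are normalized (synonym -> canonical, optionally
canonical -> hypernym) and deduplicated into one record per patient, with
provenance back to the contributing documents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .schema import AttributeSchema
from .vocabulary import ControlledVocabulary, normalize_value

__all__ = ["CandidateValue", "AggregatedValue", "PatientRecord",
           "score_candidate", "select_values", "aggregate_patient",
           "records_to_wide_frame", "records_to_long_frame"]


@dataclass
class CandidateValue:
    attribute: str
    surface: str
    canonical: str
    confidence: float
    doc_id: str = ""
    section_header: str = ""
    #: (sec_idx, para_idx, sent_idx, tok_start, tok_end) or None for induced values
    span: tuple[int, int, int, int, int] | None = None
    char_start: int | None = None
    char_end: int | None = None

    @property
    def position_key(self):
        # earliest-position tie-break; induced (span-less) values sort last
        return self.span if self.span is not None else (1 << 30,) * 5


@dataclass
class AggregatedValue:
    canonical: str
    confidence: float
    provenance: list[str] = field(default_factory=list)  # contributing doc_ids


@dataclass
class PatientRecord:
    patient_id: str
    values: dict[str, list[AggregatedValue]] = field(default_factory=dict)

    def value_strings(self, attribute: str) -> list[str]:
        return [v.canonical for v in self.values.get(attribute, [])]


def score_candidate(sim_score: float, chunk_score: float, w_sim: float = 0.5) -> float:
    """confidence = w_sim * sentence score + (1 - w_sim) * chunk score."""
    if not (0.0 <= sim_score <= 1.0 and 0.0 <= chunk_score <= 1.0):
        raise ValueError("scores must be in [0,1]")
    return w_sim * sim_score + (1.0 - w_sim) * chunk_score


def select_values(
    candidates: list[CandidateValue],
    cardinality: str,
    tau_conf: float = 0.5,
) -> list[CandidateValue]:
    """Accept candidates per attribute cardinality.

    single: the highest-confidence candidate (ties -> earliest document
    position), provided it reaches ``tau_conf``; multi: all candidates at or
    above ``tau_conf``, in document order.
    """
    if cardinality == "single":
        if not candidates:
            return []
        best = min(candidates, key=lambda c: (-c.confidence, c.position_key))
        return [best] if best.confidence >= tau_conf else []
    accepted = [c for c in candidates if c.confidence >= tau_conf]
    accepted.sort(key=lambda c: c.position_key)
    return accepted


def aggregate_patient(
    per_report_results: list[tuple[str, dict[str, list[CandidateValue]]]],
    vocabs: dict[str, ControlledVocabulary] | None,
    schema: AttributeSchema,
) -> PatientRecord:
    """Merge per-report accepted values into one patient record.

    Values are normalized (transform, plus generalization for attributes
    configured for it) and deduplicated by canonical (casefold).  Multi-valued
    attributes use set semantics — report order does not matter — and are
    emitted sorted by canonical.  Single-valued cross-report conflicts go to
    the highest confidence, ties to the report latest in input order.
    """
    vocabs = vocabs or {}
    patient_id = ""
    merged: dict[str, dict[str, AggregatedValue]] = {}
    single_pick: dict[str, tuple[float, int, AggregatedValue]] = {}

    for order, (doc_id, results) in enumerate(per_report_results):
        for attr, cands in results.items():
            if attr not in schema:
                continue
            spec = schema[attr]
            vocab = vocabs.get(attr)
            mode = "generalize" if spec.generalize else "transform"
            for cand in cands:
                canonical = normalize_value(cand.canonical or cand.surface, vocab, mode)
                key = canonical.casefold()
                if spec.cardinality == "single":
                    prev = single_pick.get(attr)
                    agg = AggregatedValue(canonical, cand.confidence, [doc_id])
                    if prev is None or (cand.confidence, order) >= (prev[0], prev[1]):
                        if prev is not None and prev[2].canonical.casefold() == key:
                            agg.provenance = sorted(set(prev[2].provenance + [doc_id]))
                        single_pick[attr] = (cand.confidence, order, agg)
                    elif prev[2].canonical.casefold() == key and doc_id not in prev[2].provenance:
                        prev[2].provenance = sorted(set(prev[2].provenance + [doc_id]))
                else:
                    bucket = merged.setdefault(attr, {})
                    if key in bucket:
                        agg = bucket[key]
                        agg.confidence = max(agg.confidence, cand.confidence)
                        if doc_id not in agg.provenance:
                            agg.provenance = sorted(set(agg.provenance + [doc_id]))
                    else:
                        bucket[key] = AggregatedValue(canonical, cand.confidence, [doc_id])

    record = PatientRecord(patient_id=patient_id)
    for attr in schema.names:
        if schema[attr].cardinality == "single":
            if attr in single_pick:
                record.values[attr] = [single_pick[attr][2]]
        else:
            bucket = merged.get(attr, {})
            record.values[attr] = sorted(bucket.values(), key=lambda v: v.canonical.casefold())
    return record


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def records_to_wide_frame(records: list[PatientRecord], schema: AttributeSchema) -> pd.DataFrame:
    """One row per patient, one column per attribute; multi-valued attributes
    joined with '|'. Exports cleanly to CSV/Excel/database."""
    rows = []
    for rec in records:
        row: dict[str, str] = {"patient_id": rec.patient_id}
        for attr in schema.names:
            row[attr] = "|".join(rec.value_strings(attr))
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", *schema.names])


def records_to_long_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Long format with provenance: one row per (patient, attribute, value,
    contributing document)."""
    rows = []
    for rec in records:
        for attr, vals in rec.values.items():
            for v in vals:
                for doc_id in v.provenance:
                    rows.append({
                        "patient_id": rec.patient_id,
                        "attribute": attr,
                        "value": v.canonical,
                        "doc_id": doc_id,
                        "confidence": v.confidence,
                    })
    return pd.DataFrame(rows, columns=["patient_id", "attribute", "value", "doc_id", "confidence"])
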