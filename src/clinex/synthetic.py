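"""Seeded synthetic clinical corpora with gold answers.

Real clinical reports are protected; these generators emulate the three
report forms the engine targets — semistructured attribute-value reports,
template-based narration, and complex multi-section narration — at desk
scale, emitting for each corpus the documents, a gold table at the
clinical-finding level, the attribute schema, and (for complex narration) a
complete matching controlled vocabulary.  The seed fixes every corpus
byte-exactly.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import term_bank
from .schema import AttributeSchema, AttributeSpec, ValueDomain
from .vocabulary import (ControlledVocabulary, StructuralProperties, TermEntry,
                         save_vocabulary)

__all__ = ["CorpusSpec", "SyntheticDocument", "SyntheticCorpus",
           "generate_semistructured", "generate_template_narration",
           "generate_complex_narration", "generate_corpus", "write_corpus",
           "complex_vocabulary", "strip_structure"]


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    Defaults mirror desk-scale analogues of the three report collections the
    engine is evaluated on: 100 documents per form, with noise rates chosen
    to read like real reports (about one negated mention in five, occasional
    planned-treatment and allergy-section mentions, abbreviations used about
    half the time).
    """

    n_patients: int = 100
    reports_per_patient: int = 1
    seed: int = 0
    negation_rate: float = 0.2
    uncertainty_rate: float = 0.3
    distractor_rate: float = 0.3
    synonym_rate: float = 0.5
    missing_rate: float = 0.1
    allergy_rate: float = 0.4
    trap_rate: float = 0.3

    def __post_init__(self) -> None:
        for name in ("negation_rate", "uncertainty_rate", "distractor_rate",
                     "synonym_rate", "missing_rate", "allergy_rate", "trap_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError("%s must be in [0,1], got %r" % (name, v))


@dataclass
class SyntheticDocument:
    doc_id: str
    patient_id: str
    text: str


@dataclass
class SyntheticCorpus:
    form: str
    documents: list[SyntheticDocument]
    gold: dict[str, dict[str, list[str]]]  # doc_id -> attribute -> values
    schema: AttributeSchema
    vocabs: dict[str, ControlledVocabulary] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# form 1: semistructured attribute-value reports
# ---------------------------------------------------------------------------

SEMI_SCHEMA = AttributeSchema.from_specs([
    AttributeSpec("heart_rate", "single", ValueDomain.numeric_range(0, 200)),
    AttributeSpec("ejection_fraction", "single", ValueDomain.numeric_range(0, 100)),
    AttributeSpec("access_site", "single",
                  ValueDomain.enumeration(term_bank.ACCESS_SITES)),
    AttributeSpec("diagnosis", "multi"),
    AttributeSpec("medication", "multi"),
])

_SEMI_LABELS = {
    "heart_rate": "Heart Rate",
    "ejection_fraction": "Ejection Fraction",
    "access_site": "Access Site",
}


def generate_semistructured(spec: CorpusSpec) -> SyntheticCorpus:
    """"Attribute: value" reports under header sections, with shuffled
    attribute order and occasionally missing attributes."""
    rng = random.Random(spec.seed)
    documents, gold = [], {}
    diseases = [c for c, _ in term_bank.DISEASES]
    meds = [c for c, _, _ in term_bank.MEDICATIONS]
    for i in range(spec.n_patients):
        patient_id = "P%03d" % i
        doc_id = "semi%03d" % i
        doc_gold: dict[str, list[str]] = {}
        vit_lines = []
        for attr in ("heart_rate", "ejection_fraction", "access_site"):
            if rng.random() < spec.missing_rate:
                continue
            if attr == "heart_rate":
                value = str(rng.randint(42, 178))
            elif attr == "ejection_fraction":
                value = str(rng.randint(15, 75))
            else:
                value = rng.choice(term_bank.ACCESS_SITES)
            vit_lines.append("%s: %s" % (_SEMI_LABELS[attr], value))
            doc_gold[attr] = [value]
        rng.shuffle(vit_lines)
        dx = rng.sample(diseases, rng.randint(1, 3))
        rx = rng.sample(meds, rng.randint(1, 3))
        doc_gold["diagnosis"] = list(dx)
        doc_gold["medication"] = list(rx)
        text = "CARDIAC CATHETERIZATION REPORT\n\nPROCEDURE DATA:\n"
        text += "\n".join(vit_lines) + "\n\nDIAGNOSES:\n"
        text += "\n".join("Diagnosis: %s" % d for d in dx) + "\n\nMEDICATIONS:\n"
        text += "\n".join("Medication: %s" % m for m in rx) + "\n"
        documents.append(SyntheticDocument(doc_id, patient_id, text))
        gold[doc_id] = doc_gold
    return SyntheticCorpus("semistructured", documents, gold, SEMI_SCHEMA)


# ---------------------------------------------------------------------------
# form 2: template-based narration
# ---------------------------------------------------------------------------

TEMPLATE_SCHEMA = AttributeSchema.from_specs([
    AttributeSpec("artery", "multi"),
    AttributeSpec("severity", "multi"),
])

_POSITIVE_TEMPLATES = [
    "There is {sev} stenosis of the {artery}.",
    "The {artery} has {sev} stenosis.",
    "Angiography demonstrates {sev} narrowing of the {artery}.",
]
_NEGATIVE_TEMPLATE = "There is no significant stenosis of the {artery}."
_BOILERPLATE = [
    "The procedure was well tolerated.",
    "There were no procedural complications.",
    "Hemostasis was achieved at the access site.",
]


def generate_template_narration(spec: CorpusSpec) -> SyntheticCorpus:
    """Findings prose drawn from a fixed template bank with artery/severity
    slot fillers; negated findings are gold-negative."""
    rng = random.Random(spec.seed + 1)
    documents, gold = [], {}
    for i in range(spec.n_patients):
        patient_id = "P%03d" % i
        doc_id = "angio%03d" % i
        arteries = rng.sample(term_bank.ARTERIES, rng.randint(2, 4))
        lines, pos_arteries, pos_sevs = [], [], []
        for artery in arteries:
            if rng.random() < spec.negation_rate:
                lines.append(_NEGATIVE_TEMPLATE.format(artery=artery))
            else:
                sev = rng.choice(term_bank.SEVERITIES)
                tmpl = rng.choice(_POSITIVE_TEMPLATES)
                lines.append(tmpl.format(sev=sev, artery=artery))
                pos_arteries.append(artery)
                pos_sevs.append(sev)
        if rng.random() < spec.distractor_rate:
            lines.append(rng.choice(_BOILERPLATE))
        text = "CORONARY ANGIOGRAM REPORT\n\nFINDINGS:\n" + "\n".join(lines) + "\n"
        documents.append(SyntheticDocument(doc_id, patient_id, text))
        gold[doc_id] = {
            "artery": sorted(set(pos_arteries)),
            "severity": sorted(set(pos_sevs)),
        }
    return SyntheticCorpus("template", documents, gold, TEMPLATE_SCHEMA)


# ---------------------------------------------------------------------------
# form 3: complex narration, with a matching controlled vocabulary
# ---------------------------------------------------------------------------

COMPLEX_SCHEMA = AttributeSchema.from_specs([
    AttributeSpec("disease", "multi"),
    AttributeSpec("medication", "multi"),
])


def complex_vocabulary() -> dict[str, ControlledVocabulary]:
    """The complete controlled vocabulary matching the complex-narration
    generator: full terminology plus structural properties (the Allergies
    section is negative context for medications; "intolerant" vetoes
    medication matches in its sentence)."""
    disease_entries = [
        TermEntry(canonical=c, synonyms=list(syns))
        for c, syns in term_bank.DISEASES
    ]
    med_entries = [
        TermEntry(canonical=c, hypernym=h, induces=list(ind))
        for c, h, ind in term_bank.MEDICATIONS
    ]
    med_entries += [TermEntry(canonical=t) for t in term_bank.MEDICATION_CLASS_TERMS]
    return {
        "disease": ControlledVocabulary("disease", disease_entries, StructuralProperties()),
        "medication": ControlledVocabulary(
            "medication", med_entries,
            StructuralProperties(negative_sections=["Allergies"],
                                 negative_indicators=["intolerant"]),
        ),
    }


def strip_structure(vocabs: dict[str, ControlledVocabulary]) -> dict[str, ControlledVocabulary]:
    """Terminology-only copy of a vocabulary set (structural properties
    removed) — the baseline arm of the structure-vs-terminology contrast."""
    return {
        attr: ControlledVocabulary(attr, v.entries, StructuralProperties())
        for attr, v in vocabs.items()
    }


_NEGATION_SENTENCES = [
    "The patient denies {d}.",
    "There is no history of {d}.",
    "The patient has no history of {d}.",
]

_REPORT_TITLES = ["HISTORY AND PHYSICAL", "DISCHARGE SUMMARY", "OUTPATIENT CLINIC NOTE"]


def _induced_diseases(med_names: list[str]) -> set[str]:
    out = set()
    for c, _h, ind in term_bank.MEDICATIONS:
        if c in med_names:
            out.update(v for a, v in ind if a == "disease")
    return out


def generate_complex_narration(spec: CorpusSpec) -> SyntheticCorpus:
    """Multi-section idiomatic prose (History, Medications, Allergies, Plan)
    with abbreviation usage, negated mentions, planned treatments,
    allergy-section medication mentions and disambiguation traps — all
    gold-negative.  Gold is at the clinical-finding level: abbreviations
    resolved to canonicals, inductions applied."""
    rng = random.Random(spec.seed + 2)
    documents, gold = [], {}
    disease_syn = dict(term_bank.DISEASES)
    diseases = [c for c, _ in term_bank.DISEASES]
    meds = [c for c, _, _ in term_bank.MEDICATIONS]
    for i in range(spec.n_patients):
        patient_id = "P%03d" % i
        doc_id = "note%03d" % i
        taken = rng.sample(meds, rng.randint(2, 4))
        induced = _induced_diseases(taken)
        mentioned = rng.sample(diseases, rng.randint(1, 3))
        gold_diseases = sorted(set(mentioned) | induced)
        remaining = [d for d in diseases if d not in gold_diseases]

        def render_disease(d: str) -> str:
            syns = disease_syn.get(d, [])
            if syns and rng.random() < spec.synonym_rate:
                return rng.choice(syns)
            return d

        age, sex = rng.randint(41, 88), rng.choice(["man", "woman"])
        hist = ["The patient is a %d year old %s with a history of %s." % (
            age, sex, _join([render_disease(d) for d in mentioned]))]
        if remaining and rng.random() < spec.negation_rate:
            dneg = rng.choice(remaining)
            hist.append(rng.choice(_NEGATION_SENTENCES).format(d=render_disease(dneg)))
        if rng.random() < spec.trap_rate:
            hist.append("The patient is statin intolerant.")

        med_sent = "Current medications include %s." % _join(taken)

        sections = ["%s\n\nHISTORY:\n%s" % (rng.choice(_REPORT_TITLES), "\n".join(hist)),
                    "MEDICATIONS:\n%s" % med_sent]
        not_taken = [m for m in meds if m not in taken]
        if rng.random() < spec.allergy_rate and not_taken:
            m_allergy = rng.choice(not_taken)
            not_taken = [m for m in not_taken if m != m_allergy]
            sections.append("ALLERGIES:\nAllergic to %s, which caused a rash." % m_allergy)
        if rng.random() < spec.uncertainty_rate and not_taken:
            m_plan = rng.choice(not_taken)
            sections.append("PLAN:\n%s" % rng.choice([
                "Plan to start %s at the next visit." % m_plan,
                "Will consider %s if symptoms persist." % m_plan,
            ]))
        if rng.random() < spec.distractor_rate:
            sections.append("SOCIAL HISTORY:\nThe patient works as a %s and denies tobacco use."
                            % rng.choice(term_bank.OCCUPATIONS))
        text = "\n\n".join(sections) + "\n"
        documents.append(SyntheticDocument(doc_id, patient_id, text))
        gold[doc_id] = {"disease": gold_diseases, "medication": sorted(taken)}
    return SyntheticCorpus("complex", documents, gold, COMPLEX_SCHEMA,
                           vocabs=complex_vocabulary())


def _join(items: list[str]) -> str:
    if len(items) == 1:
        return items[0]
    if len(items) == 2:
        return "%s and %s" % tuple(items)
    return "%s, and %s" % (", ".join(items[:-1]), items[-1])


# ---------------------------------------------------------------------------
# dispatch and file output
# ---------------------------------------------------------------------------

_GENERATORS = {
    "semistructured": generate_semistructured,
    "template": generate_template_narration,
    "complex": generate_complex_narration,
}


def generate_corpus(form: str, spec: CorpusSpec) -> SyntheticCorpus:
    if form not in _GENERATORS:
        raise ValueError("unknown corpus form %r (choose from %s)"
                         % (form, sorted(_GENERATORS)))
    return _GENERATORS[form](spec)


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> None:
    """Write report .txt files (``<patient_id>__<doc_id>.txt``), gold.json,
    schema.yaml, and vocabulary.yaml when the corpus carries one."""
    out = Path(out_dir)
    reports = out / "reports"
    reports.mkdir(parents=True, exist_ok=True)
    for doc in corpus.documents:
        (reports / ("%s__%s.txt" % (doc.patient_id, doc.doc_id))).write_text(
            doc.text, encoding="utf-8")
    with open(out / "gold.json", "w", encoding="utf-8") as fh:
        json.dump(corpus.gold, fh, indent=1, sort_keys=True)
    corpus.schema.save(out / "schema.yaml")
    if corpus.vocabs:
        save_vocabulary(corpus.vocabs, out / "vocabulary.yaml")
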