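"""Value normalization and per-patient aggregation across reports.

Shows the three vocabulary normalization mechanisms — transformation
(synonym to canonical), generalization (canonical to hypernym) and induction
(a medication implying a disease) — and how values extracted from two
reports of one patient merge into a single record.
"""

from clinex import (AttributeSchema, AttributeSpec, CandidateValue,
                    ControlledVocabulary, StructuralProperties, TermEntry,
                    aggregate_patient, induce_values, normalize_value)

medication = ControlledVocabulary("medication", [
    TermEntry("Lisinopril", hypernym="ACE inhibitor"),
    TermEntry("Captopril", hypernym="ACE inhibitor"),
    TermEntry("Pindolol", hypernym="beta blocker"),
    TermEntry("Metformin", induces=[("disease", "Diabetes Mellitus")]),
], StructuralProperties())
disease = ControlledVocabulary("disease", [
    TermEntry("Diabetes Mellitus", synonyms=["DM", "Diabetes"]),
], StructuralProperties())
vocabs = {"medication": medication, "disease": disease}

print("transform   DM        ->", normalize_value("DM", disease))
print("generalize  Pindolol  ->", normalize_value("Pindolol", medication, "generalize"))
print("induce      Metformin ->", induce_values(["Metformin"], vocabs))

schema = AttributeSchema.from_specs([AttributeSpec("medication", "multi", generalize=True)])
per_report = [
    ("discharge_summary", {"medication": [
        CandidateValue("medication", "lisinopril", "Lisinopril", 0.9, "discharge_summary")]}),
    ("inpatient_report", {"medication": [
        CandidateValue("medication", "captopril", "Captopril", 0.8, "inpatient_report")]}),
]
record = aggregate_patient(per_report, vocabs, schema)
for value in record.values["medication"]:
    print("aggregated: %s  (from %s)" % (value.canonical, ", ".join(value.provenance)))
# Two different ACE inhibitors found in two reports collapse into one
# generalized value with provenance back to both documents.
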