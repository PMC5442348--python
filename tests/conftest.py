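import pytest

from clinex.document import parse_document
from clinex.schema import AttributeSchema, AttributeSpec, ValueDomain
from clinex.vocabulary import (ControlledVocabulary, StructuralProperties,
                               TermEntry)

WORKED_TEXT = "HISTORY:\nThe patient reports history of diabetes and hypertension.\n"


@pytest.fixture
def worked_doc():
    """The canonical worked sentence under a HISTORY header."""
    return parse_document(WORKED_TEXT, "doc1", "P1")


@pytest.fixture
def paper_vocabs():
    """Small disease/medication vocabularies exercising every terminology
    feature: synonyms, hypernyms, inductions, negative sections and
    disambiguation indicators."""
    disease = ControlledVocabulary(
        "disease",
        [
            TermEntry("Diabetes Mellitus", synonyms=["DM", "Diabetes"]),
            TermEntry("Myocardial Infarction", synonyms=["MI"]),
            TermEntry("Hypertension", synonyms=["HTN"]),
            TermEntry("Cancer"),
        ],
        StructuralProperties(),
    )
    medication = ControlledVocabulary(
        "medication",
        [
            TermEntry("Metformin", induces=[("disease", "Diabetes Mellitus")]),
            TermEntry("Insulin", induces=[("disease", "Diabetes Mellitus")]),
            TermEntry("Pindolol", hypernym="beta blocker"),
            TermEntry("Lisinopril", hypernym="ACE inhibitor"),
            TermEntry("Captopril", hypernym="ACE inhibitor"),
            TermEntry("statin"),
        ],
        StructuralProperties(negative_sections=["Allergies"],
                             negative_indicators=["intolerant"]),
    )
    return {"disease": disease, "medication": medication}


@pytest.fixture
def mini_schema():
    return AttributeSchema.from_specs([
        AttributeSpec("disease", "multi"),
        AttributeSpec("medication", "multi", generalize=True),
        AttributeSpec("heart_rate", "single", ValueDomain.numeric_range(0, 200)),
    ])


def locate_chunk(doc, phrase):
    """(sentence, token span) of the first occurrence of ``phrase``."""
    from clinex.learning import locate_value_span
    span = locate_value_span(doc, phrase)
    assert span is not None, "fixture phrase %r not found" % phrase
    sec, para, sent, start, end = span
    return doc.get_sentence(sec, para, sent), (start, end)
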