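"""String patterns, value domains, negation/uncertainty scope, rule induction."""

import pytest

from clinex.chunking import CandidateChunk
from clinex.document import parse_document
from clinex.filtering import (DEFAULT_LEXICON, RuleModel, apply_filters,
                              candidate_predicates, classify_string_pattern,
                              detect_negation, detect_uncertainty,
                              in_value_domain)
from clinex.schema import AttributeSpec, ValueDomain


def _sentence(text):
    return list(parse_document(text, "d").sentences())[0]


def _span_of(sent, phrase):
    norms = [w for w in phrase.lower().split()]
    from clinex.document import normalize_token
    target = [normalize_token(w) for w in norms]
    sent_norms = sent.norms()
    for i in range(len(sent_norms) - len(target) + 1):
        if sent_norms[i:i + len(target)] == target:
            return (i, i + len(target))
    raise AssertionError("phrase %r not in %r" % (phrase, sent.text))


PATTERN_GOLDEN = [
    ("Diabetes Mellitus", "init_cap_all_tokens"),
    ("Beta Blocker", "init_cap_all_tokens"),
    ("Metformin", "init_cap_all_tokens"),
    ("120", "numeric"),
    ("120/80", "numeric"),
    ("-3.5", "numeric"),
    ("DM", "all_caps"),
    ("COPD", "all_caps"),
    ("aspirin", "lower"),
    ("beta-blocker", "lower"),
    ("x", "lower"),
    ("T2DM", "alnum_code"),
    ("HbA1c", "alnum_code"),
    ("HeLa", "mixed"),
    ("McDonald", "mixed"),
    ("right coronary artery", "lower"),
    ("--", "other"),
    ("", "other"),
]


@pytest.mark.parametrize("surface,expected", PATTERN_GOLDEN)
def test_string_pattern_golden(surface, expected):
    assert classify_string_pattern(surface) == expected


class TestValueDomain:
    HR = ValueDomain.numeric_range(0, 200)

    def test_heart_rate_range(self):
        assert in_value_domain("152", self.HR) is True
        assert in_value_domain("999", self.HR) is False

    def test_closed_interval_boundaries(self):
        assert in_value_domain("0", self.HR) is True
        assert in_value_domain("200", self.HR) is True

    def test_no_constraint_passes_everything(self):
        assert in_value_domain("anything", None) is True

    def test_enumeration_casefold(self):
        dom = ValueDomain.enumeration(["femoral", "radial"])
        assert in_value_domain("Femoral", dom) is True
        assert in_value_domain("jugular", dom) is False

    def test_non_numeric_fails_numeric_range(self):
        assert in_value_domain("normal", self.HR) is False


NEGATION_SUITE = [
    # (sentence, chunk phrase, negated?)
    ("The patient has no history of cancer.", "cancer", True),
    ("History of cancer.", "cancer", False),
    ("The patient denies chest pain.", "chest pain", True),
    ("No acute distress was noted.", "distress", True),
    ("The patient is not on aspirin.", "aspirin", True),
    ("Without evidence of ischemia.", "ischemia", True),
    ("Negative for tuberculosis.", "tuberculosis", True),
    ("The patient denied fevers.", "fevers", True),
    ("The patient is free of disease.", "disease", True),
    ("There is no pain but stenosis was seen.", "stenosis", False),   # "but" terminates scope
    ("He denied fevers; cough was present.", "cough", False),         # ";" terminates scope
    ("No history was obtained regarding the remote childhood measles.",
     "measles", False),                                               # beyond the 6-token window
    ("Cancer was not found.", "cancer", False),                       # trigger after the chunk
    ("The patient reports severe pain.", "pain", False),
    ("Denies any alcohol use.", "alcohol use", True),
    ("Not taking metformin currently.", "metformin", True),
    ("The exam was normal without any murmur.", "murmur", True),
    ("There is mild stenosis of the artery.", "stenosis", False),
    ("No significant stenosis of the right coronary artery.",
     "right coronary artery", True),
    ("The biopsy ruled the mass benign, no further cancer workup.", "workup", True),
]


@pytest.mark.parametrize("text,phrase,expected", NEGATION_SUITE)
def test_negation_hand_labeled_suite(text, phrase, expected):
    sent = _sentence(text)
    assert detect_negation(sent, _span_of(sent, phrase), DEFAULT_LEXICON) is expected


UNCERTAINTY_SUITE = [
    ("The patient is planned to take radiation therapy.", "radiation therapy", True),
    ("The patient completed radiation therapy.", "radiation therapy", False),
    ("Plan to start Warfarin at the next visit.", "Warfarin", True),
    ("Will consider surgery if symptoms persist.", "surgery", True),
    ("Underwent surgery last year.", "surgery", False),
    ("Scheduled for stress test.", "stress test", True),
    ("Recommend colonoscopy.", "colonoscopy", True),
    ("If needed, dialysis can be initiated.", "dialysis", True),
    ("The patient takes lisinopril.", "lisinopril", False),
    ("Currently on metformin.", "metformin", False),
]


@pytest.mark.parametrize("text,phrase,expected", UNCERTAINTY_SUITE)
def test_uncertainty_hand_labeled_suite(text, phrase, expected):
    sent = _sentence(text)
    assert detect_uncertainty(sent, _span_of(sent, phrase), DEFAULT_LEXICON) is expected


def test_detection_is_a_pure_function():
    sent = _sentence("The patient has no history of cancer.")
    span = _span_of(sent, "cancer")
    assert detect_negation(sent, span) is detect_negation(sent, span) is True


class TestApplyFilters:
    def _cand(self, sent, phrase, score=1.0):
        span = _span_of(sent, phrase)
        return CandidateChunk(span, phrase, "keyword", score)

    def test_negated_cancer_removed_regardless_of_score(self):
        sent = _sentence("the patient has no history of cancer")
        out = apply_filters([self._cand(sent, "cancer", 1.0)], sent, "HISTORY:")
        assert out == []

    def test_cold_start_passes_everything(self):
        sent = _sentence("history of cancer")
        cands = [self._cand(sent, "cancer")]
        assert apply_filters(cands, sent, "HISTORY:", RuleModel()) == cands

    def test_domain_constraint_removes_out_of_range(self):
        sent = _sentence("Heart Rate: 999")
        spec = AttributeSpec("hr", "single", ValueDomain.numeric_range(0, 200))
        assert apply_filters([self._cand(sent, "999")], sent, "VITALS:", spec=spec) == []

    def test_triggered_numeric_rule_rejects_numeric_chunks(self):
        # reference coverage calculation from a raw instance list
        instances = [("numeric", "negative")] * 6 + [("lower", "positive")] * 3
        model = RuleModel(tau=0.9, min_support=5)
        for pattern, polarity in instances:
            model.observe(["pattern=%s" % pattern], polarity)
        ref = {}
        for pattern in ("numeric", "lower"):
            neg = sum(1 for p, pol in instances if p == pattern and pol == "negative")
            tot = sum(1 for p, pol in instances if p == pattern)
            ref[pattern] = tot >= 5 and neg / tot >= 0.9
        assert model.triggered("pattern=numeric") is ref["numeric"] is True
        assert model.triggered("pattern=lower") is ref["lower"] is False

        sent = _sentence("value was 120 with aspirin given")
        numeric = self._cand(sent, "120")
        word = self._cand(sent, "aspirin")
        out = apply_filters([numeric, word], sent, "NOTE:", model)
        assert out == [word]

    def test_vocabulary_context_applied(self, paper_vocabs):
        sent = _sentence("the patient is statin intolerant")
        cand = CandidateChunk(_span_of(sent, "statin"), "statin", "keyword", 1.0,
                              canonical="statin")
        out = apply_filters([cand], sent, "HISTORY:", vocab=paper_vocabs["medication"])
        assert out == []

    def test_output_is_subsequence_of_input(self):
        sent = _sentence("no cancer but history of gout and asthma")
        cands = [self._cand(sent, p) for p in ("cancer", "gout", "asthma")]
        out = apply_filters(cands, sent, "HISTORY:")
        assert [c.surface for c in out] == ["gout", "asthma"]

    def test_rule_triggering_monotone_in_negatives(self):
        model = RuleModel(tau=0.9, min_support=5)
        model.observe(["pattern=numeric"], "negative")
        fired_states = []
        for _ in range(20):
            model.observe(["pattern=numeric"], "negative")
            fired_states.append(model.triggered("pattern=numeric"))
        # once triggered, stays triggered as negatives accumulate
        first = fired_states.index(True)
        assert all(fired_states[first:])


def test_candidate_predicates_include_section_and_pos():
    preds = candidate_predicates("Aspirin", head_pos="NNP", section_header="ALLERGIES:")
    assert "pattern=init_cap_all_tokens" in preds
    assert "pos_tag=NNP" in preds
    assert "section=allergies" in preds
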