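"""Synthetic corpus generators: determinism, gold soundness, cross-checks."""

import math
import re
from dataclasses import replace

import pytest

from clinex.synthetic import (CorpusSpec, complex_vocabulary,
                              generate_complex_narration, generate_corpus,
                              generate_semistructured,
                              generate_template_narration, strip_structure,
                              write_corpus)
from clinex import term_bank


def _dump(corpus):
    return ([(d.doc_id, d.patient_id, d.text) for d in corpus.documents], corpus.gold)


@pytest.mark.parametrize("form", ["semistructured", "template", "complex"])
def test_same_seed_is_byte_identical(form):
    spec = CorpusSpec(n_patients=12, seed=9)
    assert _dump(generate_corpus(form, spec)) == _dump(generate_corpus(form, spec))


@pytest.mark.parametrize("form", ["semistructured", "template", "complex"])
def test_different_seeds_differ(form):
    a = generate_corpus(form, CorpusSpec(n_patients=12, seed=1))
    b = generate_corpus(form, CorpusSpec(n_patients=12, seed=2))
    assert _dump(a) != _dump(b)


class TestSemistructured:
    def test_heart_rate_values_within_domain(self):
        corpus = generate_semistructured(CorpusSpec(n_patients=40, seed=4))
        for doc in corpus.documents:
            for m in re.finditer(r"Heart Rate: (\d+)", doc.text):
                assert 0 <= int(m.group(1)) <= 200

    def test_gold_matches_independent_regex_scan(self):
        corpus = generate_semistructured(CorpusSpec(n_patients=25, seed=4))
        label_to_attr = {
            "Heart Rate": "heart_rate", "Ejection Fraction": "ejection_fraction",
            "Access Site": "access_site", "Diagnosis": "diagnosis",
            "Medication": "medication",
        }
        for doc in corpus.documents:
            scanned = {}
            for m in re.finditer(r"^([A-Za-z ]+): (.+)$", doc.text, re.M):
                label, value = m.group(1), m.group(2).strip()
                if label in label_to_attr:
                    scanned.setdefault(label_to_attr[label], []).append(value)
            gold = {k: v for k, v in corpus.gold[doc.doc_id].items() if v}
            assert scanned == gold

    def test_missing_attributes_absent_from_gold(self):
        corpus = generate_semistructured(CorpusSpec(n_patients=60, seed=4))
        missing = sum(1 for d in corpus.documents
                      if "heart_rate" not in corpus.gold[d.doc_id])
        assert 0 < missing < 60  # missing_rate=0.1 produces some but not all


class TestTemplate:
    def test_zero_noise_sentences_all_from_template_bank(self):
        spec = CorpusSpec(n_patients=20, seed=5, negation_rate=0.0, distractor_rate=0.0)
        corpus = generate_template_narration(spec)
        patterns = [
            r"There is (minimal|mild|moderate|severe|critical) stenosis of the .+\.",
            r"The .+ has (minimal|mild|moderate|severe|critical) stenosis\.",
            r"Angiography demonstrates (minimal|mild|moderate|severe|critical) narrowing of the .+\.",
        ]
        for doc in corpus.documents:
            body = doc.text.split("FINDINGS:\n", 1)[1]
            for line in body.strip().splitlines():
                assert any(re.fullmatch(p, line) for p in patterns), line

    def test_gold_equals_filled_slots_at_zero_noise(self):
        spec = CorpusSpec(n_patients=20, seed=5, negation_rate=0.0, distractor_rate=0.0)
        corpus = generate_template_narration(spec)
        sev = "(minimal|mild|moderate|severe|critical)"
        patterns = [
            r"There is %s stenosis of the (.+)\." % sev,
            r"The (.+) has %s stenosis\." % sev,
            r"Angiography demonstrates %s narrowing of the (.+)\." % sev,
        ]
        for doc in corpus.documents:
            arteries, sevs = set(), set()
            body = doc.text.split("FINDINGS:\n", 1)[1]
            for line in body.strip().splitlines():
                for p in patterns:
                    m = re.fullmatch(p, line)
                    if m:
                        g1, g2 = m.groups()
                        s, a = (g1, g2) if g1 in term_bank.SEVERITIES else (g2, g1)
                        arteries.add(a)
                        sevs.add(s)
            assert set(corpus.gold[doc.doc_id]["artery"]) == arteries
            assert set(corpus.gold[doc.doc_id]["severity"]) == sevs

    def test_negated_arteries_not_in_gold(self):
        corpus = generate_template_narration(CorpusSpec(n_patients=40, seed=6,
                                                        negation_rate=0.5))
        saw_negated = False
        for doc in corpus.documents:
            for line in doc.text.splitlines():
                m = re.fullmatch(r"There is no significant stenosis of the (.+)\.", line)
                if m:
                    saw_negated = True
                    assert m.group(1) not in corpus.gold[doc.doc_id]["artery"]
        assert saw_negated

    def test_slot_distribution_uniform_within_3_sigma(self):
        corpus = generate_template_narration(CorpusSpec(n_patients=400, seed=7,
                                                        negation_rate=0.0))
        counts = {a: 0 for a in term_bank.ARTERIES}
        for doc in corpus.documents:
            for a in corpus.gold[doc.doc_id]["artery"]:
                counts[a] += 1
        n = sum(counts.values())
        k = len(term_bank.ARTERIES)
        expected = n / k
        sigma = math.sqrt(n * (1 / k) * (1 - 1 / k))
        for a, c in counts.items():
            assert abs(c - expected) <= 3 * sigma, (a, c, expected)


class TestComplex:
    def test_allergy_section_medication_absent_from_gold(self):
        corpus = generate_complex_narration(CorpusSpec(n_patients=60, seed=8,
                                                       allergy_rate=1.0))
        saw = False
        for doc in corpus.documents:
            m = re.search(r"ALLERGIES:\nAllergic to ([A-Za-z ]+),", doc.text)
            if m:
                saw = True
                assert m.group(1) not in corpus.gold[doc.doc_id]["medication"]
        assert saw

    def test_noise_free_gold_is_mentions_plus_inductions(self):
        spec = CorpusSpec(n_patients=30, seed=8, negation_rate=0.0,
                          uncertainty_rate=0.0, synonym_rate=0.0,
                          allergy_rate=0.0, trap_rate=0.0, distractor_rate=0.0)
        corpus = generate_complex_narration(spec)
        induces = {c: {v for a, v in ind if a == "disease"}
                   for c, _h, ind in term_bank.MEDICATIONS}
        for doc in corpus.documents:
            gold = corpus.gold[doc.doc_id]
            for med in gold["medication"]:
                assert med in doc.text
            induced = set().union(*(induces[m] for m in gold["medication"]))
            for disease in gold["disease"]:
                assert disease in doc.text or disease in induced

    def test_emitted_vocabulary_reproduces_gold_via_independent_matcher(self):
        """Exhaustive regex matcher + the gold-negative rules (negated or
        planned sentences, allergy sections, disambiguation traps) must
        rebuild the gold table exactly from the raw text."""
        corpus = generate_complex_narration(CorpusSpec(n_patients=40, seed=9))
        vocabs = corpus.vocabs
        surf_to_canon = {"disease": {}, "medication": {}}
        for attr in surf_to_canon:
            for entry in vocabs[attr].entries:
                for s in [entry.canonical] + list(entry.synonyms):
                    surf_to_canon[attr][s.casefold()] = entry.canonical
        neg_markers = ("denies", "no history of", "intolerant",
                       "Plan to", "Will consider")
        for doc in corpus.documents:
            found = {"disease": set(), "medication": set()}
            section = ""
            for line in doc.text.splitlines():
                if re.fullmatch(r"[A-Z ]+:?", line.strip()) and line.strip():
                    section = line.strip().rstrip(":").casefold()
                    continue
                if any(m.casefold() in line.casefold() for m in neg_markers):
                    continue
                for attr, table in surf_to_canon.items():
                    if attr == "medication" and section == "allergies":
                        continue
                    for surf, canon in table.items():
                        if re.search(r"(?<![A-Za-z])%s(?![A-Za-z])" % re.escape(surf),
                                     line, re.I):
                            found[attr].add(canon)
            # induction from accepted medications
            for c, _h, ind in term_bank.MEDICATIONS:
                if c in found["medication"]:
                    found["disease"].update(v for a, v in ind if a == "disease")
            found["medication"] -= set(term_bank.MEDICATION_CLASS_TERMS)
            assert found["disease"] == set(corpus.gold[doc.doc_id]["disease"]), doc.text
            assert found["medication"] == set(corpus.gold[doc.doc_id]["medication"]), doc.text

    def test_strip_structure_removes_all_structural_properties(self):
        stripped = strip_structure(complex_vocabulary())
        for vocab in stripped.values():
            assert vocab.structure.is_empty()


def test_write_corpus_layout(tmp_path):
    corpus = generate_corpus("complex", CorpusSpec(n_patients=3, seed=1))
    write_corpus(corpus, tmp_path)
    reports = sorted((tmp_path / "reports").glob("*.txt"))
    assert len(reports) == 3
    assert reports[0].name.count("__") == 1
    assert (tmp_path / "gold.json").exists()
    assert (tmp_path / "schema.yaml").exists()
    assert (tmp_path / "vocabulary.yaml").exists()
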