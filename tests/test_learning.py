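"""Online learning: instance derivation, feature extraction, model updates,
the interactive loop and batch mode."""

import json
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinex.config import EngineConfig
from clinex.document import parse_document
from clinex.learning import (AttributeModel, ExtractionSession, FeedbackInstance,
                             GoldFeedback, NoFeedback, derive_instances,
                             extract_features, locate_value_span, update_models)
from clinex.schema import AttributeSchema, AttributeSpec
from clinex.synthetic import CorpusSpec, generate_corpus


class TestDeriveInstances:
    def test_pure_revision_gives_one_negative(self):
        got = derive_instances({"disease": ["cancer"]}, {"disease": []})
        assert [(i.value_surface, i.polarity) for i in got] == [("cancer", "negative")]

    def test_user_fill_in_gives_one_positive(self):
        got = derive_instances({}, {"disease": ["Diabetes Mellitus"]})
        assert [(i.value_surface, i.polarity) for i in got] == \
            [("Diabetes Mellitus", "positive")]

    def test_confirmed_value_is_positive(self):
        got = derive_instances({"disease": ["Gout"]}, {"disease": ["Gout"]})
        assert [(i.value_surface, i.polarity) for i in got] == [("Gout", "positive")]

    @settings(deadline=None)
    @given(st.data())
    def test_matches_set_algebra_oracle(self, data):
        pool = ["a", "b", "c", "d", "e"]
        pre = data.draw(st.lists(st.sampled_from(pool), max_size=4, unique=True))
        fin = data.draw(st.lists(st.sampled_from(pool), max_size=4, unique=True))
        got = derive_instances({"x": pre}, {"x": fin})
        positives = {i.value_surface for i in got if i.polarity == "positive"}
        negatives = {i.value_surface for i in got if i.polarity == "negative"}
        assert positives == set(fin)
        assert negatives == set(pre) - set(fin)


class TestLocate:
    def test_value_located_in_worked_sentence(self, worked_doc):
        span = locate_value_span(worked_doc, "diabetes")
        assert span is not None
        sec, para, sent, start, end = span
        assert worked_doc.get_sentence(sec, para, sent).tokens[start].surface == "diabetes"

    def test_absent_value_unlocatable(self, worked_doc):
        assert locate_value_span(worked_doc, "xylophone") is None

    def test_first_occurrence_matches_linear_scan(self):
        doc = parse_document("aspirin daily.\nLater aspirin again.\n", "d")
        span = locate_value_span(doc, "aspirin")
        # linear-scan oracle over all tokens in document order
        expected = None
        for sent in doc.sentences():
            for tok in sent.tokens:
                if tok.norm == "aspirin":
                    expected = (tok.sec_idx, tok.para_idx, tok.sent_idx,
                                tok.tok_idx, tok.tok_idx + 1)
                    break
            if expected:
                break
        assert span == expected


class TestUpdateModels:
    def test_positive_worked_example(self, worked_doc):
        model = AttributeModel()
        span = locate_value_span(worked_doc, "diabetes")
        features = extract_features(worked_doc, span, "diabetes")
        # contextual words: stopwords and the value itself excluded
        assert features.landmarks == ["patient", "report", "history", "hypertension"]
        inst = FeedbackInstance("disease", "diabetes", "positive", span)
        update_models(model, inst, features)
        assert model.context.weights == {"patient": 1.0, "report": 1.0,
                                         "history": 1.0, "hypertension": 1.0}
        assert model.hmm.emis_counts["B"] == {"diabete": 1}
        assert "diabetes" in model.answer_keywords

    def test_negative_leaves_context_and_hmm_unchanged(self, worked_doc):
        model = AttributeModel()
        span = locate_value_span(worked_doc, "diabetes")
        features = extract_features(worked_doc, span, "diabetes")
        update_models(model, FeedbackInstance("disease", "diabetes", "negative", span),
                      features)
        assert model.context.is_empty()
        assert not model.hmm.trained
        assert model.answer_keywords == set()
        assert model.rules.counts["pattern=lower"] == [0, 1]

    def test_unlocatable_positive_skips_hmm_and_context(self):
        model = AttributeModel()
        update_models(model, FeedbackInstance("disease", "Gout", "positive", None), None)
        assert model.context.is_empty() and not model.hmm.trained
        assert "Gout" in model.answer_keywords
        assert model.rules.counts["pattern=init_cap_all_tokens"] == [1, 0]

    def test_replaying_shuffled_instances_gives_identical_counts(self, worked_doc):
        span_d = locate_value_span(worked_doc, "diabetes")
        span_h = locate_value_span(worked_doc, "hypertension")
        instances = [
            (FeedbackInstance("disease", "diabetes", "positive", span_d),
             extract_features(worked_doc, span_d, "diabetes")),
            (FeedbackInstance("disease", "hypertension", "positive", span_h),
             extract_features(worked_doc, span_h, "hypertension")),
            (FeedbackInstance("disease", "cancer", "negative", None), None),
        ] * 3
        dumps = []
        for seed in (0, 1, 2):
            model = AttributeModel()
            order = instances[:]
            random.Random(seed).shuffle(order)
            for inst, feats in order:
                update_models(model, inst, feats)
            dumps.append(json.dumps(model.to_json(), sort_keys=True))
        assert dumps[0] == dumps[1] == dumps[2]

    def test_model_serialization_round_trips_exactly(self, worked_doc):
        model = AttributeModel()
        span = locate_value_span(worked_doc, "diabetes")
        features = extract_features(worked_doc, span, "diabetes")
        update_models(model, FeedbackInstance("disease", "diabetes", "positive", span),
                      features)
        restored = AttributeModel.from_json(json.loads(json.dumps(model.to_json())))
        assert restored.to_json() == model.to_json()


def _small_session_and_docs(form="template", n=30, seed=3):
    corpus = generate_corpus(form, CorpusSpec(n_patients=n, seed=seed))
    docs = [parse_document(d.text, d.doc_id, d.patient_id)
            for d in sorted(corpus.documents, key=lambda d: d.doc_id)]
    session = ExtractionSession(corpus.schema)
    return session, docs, corpus


class TestSessionLoop:
    def test_cold_start_prediction_is_empty(self):
        session, docs, corpus = _small_session_and_docs()
        prediction, _ = session.process_document(docs[0], GoldFeedback(corpus.gold))
        assert all(v == [] for v in prediction.values())

    def test_predictions_become_nonempty_with_feedback(self):
        session, docs, corpus = _small_session_and_docs()
        feedback = GoldFeedback(corpus.gold)
        nonempty = 0
        for doc in docs:
            prediction, _ = session.process_document(doc, feedback)
            nonempty += any(prediction.values())
        assert nonempty > len(docs) // 2

    def test_confirmed_prediction_yields_positive_instances_only(self):
        prediction = {"disease": ["Gout", "Asthma"]}
        got = derive_instances(prediction, prediction)
        assert {i.polarity for i in got} == {"positive"}

    def test_batch_never_mutates_models(self):
        session, docs, corpus = _small_session_and_docs()
        feedback = GoldFeedback(corpus.gold)
        for doc in docs[:10]:
            session.process_document(doc, feedback)
        before = json.dumps({a: m.to_json() for a, m in session.models.items()},
                            sort_keys=True)
        session.run_batch(docs[10:])
        after = json.dumps({a: m.to_json() for a, m in session.models.items()},
                           sort_keys=True)
        assert before == after

    def test_batch_equals_process_document_prediction_on_frozen_models(self):
        session, docs, corpus = _small_session_and_docs()
        feedback = GoldFeedback(corpus.gold)
        for doc in docs[:10]:
            session.process_document(doc, feedback)
        target = docs[10]
        batch = session.run_batch([target])[target.doc_id]
        prediction, _ = session.process_document(target, NoFeedback())
        assert batch == prediction

    def test_batch_is_deterministic_and_order_independent(self):
        session, docs, corpus = _small_session_and_docs()
        feedback = GoldFeedback(corpus.gold)
        for doc in docs[:10]:
            session.process_document(doc, feedback)
        rest = docs[10:]
        run1 = session.run_batch(rest)
        run2 = session.run_batch(list(reversed(rest)))
        assert run1 == run2

    def test_checkpoint_round_trip(self, tmp_path):
        session, docs, corpus = _small_session_and_docs(n=10)
        feedback = GoldFeedback(corpus.gold)
        for doc in docs[:5]:
            session.process_document(doc, feedback)
        path = tmp_path / "ckpt.json"
        session.save_checkpoint(path)
        fresh = ExtractionSession(corpus.schema)
        fresh.load_checkpoint(path)
        assert {a: m.to_json() for a, m in fresh.models.items()} == \
            {a: m.to_json() for a, m in session.models.items()}
        assert fresh.run_batch(docs[5:]) == session.run_batch(docs[5:])

    def test_rolling_accuracy_reaches_high_precision(self):
        session, docs, corpus = _small_session_and_docs()
        feedback = GoldFeedback(corpus.gold)
        for doc in docs:
            session.process_document(doc, feedback)
        p, r = session.rolling_accuracy(k=10)
        assert p >= 0.9 and r >= 0.9
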