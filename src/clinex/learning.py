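"""Online learning loop: predict, take feedback, derive instances, update.

Each attribute owns one AttributeModel bundling the three statistical models
— the contextual-word vector for sentence retrieval, the O/B/I HMM for
chunking, and the rule-induction counters for filtering — plus the set of
past answer surfaces.  After every document the engine compares its
prediction with the user's final values: confirmed or user-entered values
become positive instances (they update all three models), revised-away
values become negative instances (they update only the rule counters).
Batch mode runs the same prediction pipeline with frozen models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from ._stopwords import STOPWORDS
from .assembly import CandidateValue, score_candidate, select_values
from .chunking import HmmModel, emit_key, extract_hmm_chunks, extract_keyword_chunks, merge_candidates
from .config import EngineConfig
from .document import Document, Sentence, tokenize_string
from .filtering import (DEFAULT_LEXICON, RuleModel, TriggerLexicon, apply_filters,
                        candidate_predicates)
from .retrieval import ContextVector, select_target_sentences
from .schema import AttributeSchema
from .vocabulary import ControlledVocabulary, induce_values, normalize_value

__all__ = ["AttributeModel", "FeedbackInstance", "FeatureSet",
           "derive_instances", "locate_value_span", "extract_features",
           "update_models", "ExtractionSession",
           "FeedbackSource", "GoldFeedback", "NoFeedback", "ConsoleFeedback"]


Span = tuple[int, int, int, int, int]  # sec, para, sent, tok_start, tok_end


# ---------------------------------------------------------------------------
# per-attribute model bundle
# ---------------------------------------------------------------------------

@dataclass
class AttributeModel:
    context: ContextVector = field(default_factory=ContextVector)
    hmm: HmmModel = field(default_factory=HmmModel)
    rules: RuleModel = field(default_factory=RuleModel)
    answer_keywords: set[str] = field(default_factory=set)
    docs_seen: int = 0

    def to_json(self) -> dict:
        return {
            "context": self.context.to_json(),
            "hmm": self.hmm.to_json(),
            "rules": self.rules.to_json(),
            "answer_keywords": sorted(self.answer_keywords),
            "docs_seen": self.docs_seen,
        }

    @staticmethod
    def from_json(data: dict) -> "AttributeModel":
        return AttributeModel(
            context=ContextVector.from_json(data["context"]),
            hmm=HmmModel.from_json(data["hmm"]),
            rules=RuleModel.from_json(data["rules"]),
            answer_keywords=set(data["answer_keywords"]),
            docs_seen=int(data["docs_seen"]),
        )


@dataclass
class FeedbackInstance:
    attribute: str
    value_surface: str
    polarity: str  # "positive" | "negative"
    span: Span | None = None  # None = unlocatable in the document text


@dataclass
class FeatureSet:
    """Features of one located instance, derived purely from its span."""

    section_header: str = ""
    para_idx: int = 0
    sent_idx: int = 0
    landmarks: list[str] = field(default_factory=list)
    pos_tags: list[str] = field(default_factory=list)
    value_tokens: list[str] = field(default_factory=list)
    string_pattern: str = ""
    #: emission symbols of the whole containing sentence, for the HMM update
    sentence_symbols: list[str] = field(default_factory=list)
    value_range: tuple[int, int] | None = None


# ---------------------------------------------------------------------------
# instance derivation and location
# ---------------------------------------------------------------------------

def _norm_key(value: str, vocab: ControlledVocabulary | None) -> str:
    return normalize_value(value, vocab, "transform").casefold()


def derive_instances(
    prefilled: dict[str, list[str]],
    final: dict[str, list[str]],
    vocabs: dict[str, ControlledVocabulary] | None = None,
) -> list[FeedbackInstance]:
    """Compare prefilled (predicted) and final (post-feedback) values.

    Every final value is a positive instance (confirmed or user-entered);
    every prefilled value absent from the final set was revised away and is
    a negative instance.  Comparison is on normalized surfaces.
    """
    vocabs = vocabs or {}
    instances: list[FeedbackInstance] = []
    for attr in sorted(set(prefilled) | set(final)):
        vocab = vocabs.get(attr)
        pre = {_norm_key(v, vocab): v for v in prefilled.get(attr, [])}
        fin = {_norm_key(v, vocab): v for v in final.get(attr, [])}
        for key, surface in fin.items():
            instances.append(FeedbackInstance(attr, surface, "positive"))
        for key, surface in pre.items():
            if key not in fin:
                instances.append(FeedbackInstance(attr, surface, "negative"))
    return instances


def locate_value_span(doc: Document, value_surface: str) -> Span | None:
    """First occurrence (document order) of the value's normalized token
    sequence, found through the reverse index; None when absent."""
    toks = tokenize_string(value_surface)
    if not toks:
        return None
    first = toks[0]
    for coord in doc.index.get(first, []):
        sec, para, sent, start = coord
        sentence = doc.get_sentence(sec, para, sent)
        end = start + len(toks)
        if end > len(sentence.tokens):
            continue
        if [t.norm for t in sentence.tokens[start:end]] == toks:
            return (sec, para, sent, start, end)
    return None


def extract_features(doc: Document, span: Span, surface: str) -> FeatureSet:
    """Position, landmark, POS, value and string-pattern features of a
    located instance."""
    sec, para, sent, start, end = span
    sentence = doc.get_sentence(sec, para, sent)
    value_toks = sentence.tokens[start:end]
    landmarks = [
        t.norm
        for i, t in enumerate(sentence.tokens)
        if not (start <= i < end)
        and t.norm not in STOPWORDS
        and not t.is_numeric
        and any(c.isalnum() for c in t.norm)
    ]
    return FeatureSet(
        section_header=doc.section_header(sec),
        para_idx=para,
        sent_idx=sent,
        landmarks=landmarks,
        pos_tags=[t.pos for t in value_toks],
        value_tokens=[t.norm for t in value_toks],
        string_pattern=surface,
        sentence_symbols=[emit_key(t) for t in sentence.tokens],
        value_range=(start, end),
    )


def update_models(
    model: AttributeModel,
    instance: FeedbackInstance,
    features: FeatureSet | None,
) -> AttributeModel:
    """Apply one feedback instance to the attribute's models (in place).

    Positive: landmarks feed the context vector, the labeled sentence feeds
    the HMM, the surface joins the answer keywords, and rule predicates gain
    a positive count.  Negative: rule predicates gain a negative count only.
    All updates are pure count increments, so an instance log replays to
    bit-identical models.
    """
    head_pos = features.pos_tags[-1] if features and features.pos_tags else None
    section = features.section_header if features is not None else None
    preds = candidate_predicates(instance.value_surface, head_pos, section)
    if instance.polarity == "positive":
        if features is not None and features.value_range is not None:
            model.context.update(features.landmarks)
            start, end = features.value_range
            model.hmm.observe(features.sentence_symbols, start, end)
        model.answer_keywords.add(instance.value_surface)
        model.rules.observe(preds, "positive")
    else:
        model.rules.observe(preds, "negative")
    return model


# ---------------------------------------------------------------------------
# feedback sources
# ---------------------------------------------------------------------------

class FeedbackSource:
    """Contract replacing the GUI: given a document and the prediction,
    return the final (user-approved) values per attribute."""

    def get_final(self, doc: Document, prediction: dict[str, list[str]]) -> dict[str, list[str]]:
        raise NotImplementedError


class NoFeedback(FeedbackSource):
    """Accept every prediction unchanged (yields only positive instances)."""

    def get_final(self, doc, prediction):
        return {attr: list(vals) for attr, vals in prediction.items()}


class GoldFeedback(FeedbackSource):
    """Simulate a user who fixes every error, answering from a gold table
    keyed by doc_id."""

    def __init__(self, gold: dict[str, dict[str, list[str]]]):
        self.gold = gold

    def get_final(self, doc, prediction):
        doc_gold = self.gold.get(doc.doc_id, {})
        return {attr: list(doc_gold.get(attr, [])) for attr in prediction}

    @staticmethod
    def from_file(path: str | Path) -> "GoldFeedback":
        return GoldFeedback(load_gold(path))


class ConsoleFeedback(FeedbackSource):
    """Interactive prompt: show the prediction per attribute and accept an
    edited, '|'-separated value list (empty input keeps the prediction)."""

    def get_final(self, doc, prediction):
        final = {}
        print("--- %s ---" % doc.doc_id)
        for attr, vals in prediction.items():
            shown = "|".join(vals)
            raw = input("%s [%s]: " % (attr, shown)).strip()
            if not raw:
                final[attr] = list(vals)
            elif raw == "-":
                final[attr] = []
            else:
                final[attr] = [v.strip() for v in raw.split("|") if v.strip()]
        return final


def load_gold(path: str | Path) -> dict[str, dict[str, list[str]]]:
    """Gold answers from JSON ({doc_id: {attr: [values]}}) or CSV with
    columns doc_id, attribute, value."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return {d: {a: list(vs) for a, vs in attrs.items()} for d, attrs in data.items()}
    import csv
    gold: dict[str, dict[str, list[str]]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            gold.setdefault(row["doc_id"], {}).setdefault(row["attribute"], []).append(row["value"])
    return gold


# ---------------------------------------------------------------------------
# session
# ---------------------------------------------------------------------------

class ExtractionSession:
    """Holds the per-attribute models, schema, vocabularies and config, and
    drives interactive (predict -> feedback -> update) and batch modes."""

    def __init__(
        self,
        schema: AttributeSchema,
        vocabs: dict[str, ControlledVocabulary] | None = None,
        config: EngineConfig | None = None,
        lexicon: TriggerLexicon | None = None,
    ):
        self.schema = schema
        self.vocabs = vocabs or {}
        self.config = config or EngineConfig()
        self.lexicon = (lexicon or DEFAULT_LEXICON).extended(
            self.config.extra_negation_triggers, self.config.extra_certainty_triggers
        )
        self.models: dict[str, AttributeModel] = {a: AttributeModel() for a in schema.names}
        #: (doc_id, prediction, final) history of interactive processing
        self.history: list[tuple[str, dict[str, list[str]], dict[str, list[str]]]] = []

    # -- prediction --------------------------------------------------------
    def predict_document(self, doc: Document) -> dict[str, list[CandidateValue]]:
        """Full pipeline: retrieval -> chunking -> filtering -> ranking ->
        induction.  Never mutates any model."""
        cfg = self.config
        accepted: dict[str, list[CandidateValue]] = {}
        for attr in self.schema.names:
            spec = self.schema[attr]
            model = self.models[attr]
            vocab = self.vocabs.get(attr)
            candidates: list[CandidateValue] = []
            for scored in select_target_sentences(
                doc, model.context, model.answer_keywords, vocab, spec, cfg.theta_sim
            ):
                sentence = scored.sentence
                header = doc.section_header(sentence.sec_idx)
                hmm_chunks = extract_hmm_chunks(model.hmm, sentence)
                kw_chunks = extract_keyword_chunks(sentence, model.answer_keywords, vocab)
                merged = merge_candidates(hmm_chunks, kw_chunks)
                survivors = apply_filters(
                    merged, sentence, header, model.rules, spec, vocab,
                    self.lexicon, cfg.scope_window, cfg.indicator_window,
                )
                for chunk in survivors:
                    conf = score_candidate(scored.sim_score, chunk.chunk_score, cfg.w_sim)
                    canonical = chunk.canonical or normalize_value(chunk.surface, vocab, "transform")
                    toks = sentence.tokens[chunk.span[0]:chunk.span[1]]
                    candidates.append(CandidateValue(
                        attribute=attr,
                        surface=chunk.surface,
                        canonical=canonical,
                        confidence=conf,
                        doc_id=doc.doc_id,
                        section_header=header,
                        span=(sentence.sec_idx, sentence.para_idx, sentence.sent_idx,
                              chunk.span[0], chunk.span[1]),
                        char_start=toks[0].char_start,
                        char_end=toks[-1].char_end,
                    ))
            candidates = _dedup_by_canonical(candidates)
            accepted[attr] = select_values(candidates, spec.cardinality, cfg.tau_conf)

        # vocabulary induction, on accepted (post-filter) values only
        accepted_canonicals = [cv.canonical for vals in accepted.values() for cv in vals]
        for target_attr, value in induce_values(accepted_canonicals, self.vocabs):
            if target_attr not in self.schema:
                continue
            present = {cv.canonical.casefold() for cv in accepted[target_attr]}
            if value.casefold() in present:
                continue
            spec = self.schema[target_attr]
            if spec.cardinality == "single" and accepted[target_attr]:
                continue
            accepted[target_attr].append(CandidateValue(
                attribute=target_attr, surface=value, canonical=value,
                confidence=1.0, doc_id=doc.doc_id, section_header="",
            ))
        return accepted

    def predict_values(self, doc: Document) -> dict[str, list[str]]:
        return {attr: [cv.canonical for cv in vals]
                for attr, vals in self.predict_document(doc).items()}

    # -- interactive -------------------------------------------------------
    def process_document(
        self, doc: Document, feedback: FeedbackSource
    ) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
        """One interactive step: predict, record the pre-feedback prediction,
        obtain final values, derive instances, update models."""
        predicted = self.predict_document(doc)
        prediction = {attr: [cv.canonical for cv in vals] for attr, vals in predicted.items()}
        final = feedback.get_final(doc, prediction)
        instances = derive_instances(prediction, final, self.vocabs)
        span_of = {
            (cv.attribute, cv.canonical.casefold()): cv.span
            for vals in predicted.values() for cv in vals if cv.span is not None
        }
        for inst in instances:
            self._apply_instance(doc, inst, span_of)
        for model in self.models.values():
            model.docs_seen += 1
        self.history.append((doc.doc_id, prediction, final))
        return prediction, final

    def _apply_instance(self, doc: Document, inst: FeedbackInstance, span_of: dict) -> None:
        vocab = self.vocabs.get(inst.attribute)
        key = (inst.attribute, normalize_value(inst.value_surface, vocab, "transform").casefold())
        span = span_of.get(key)
        if span is None:
            span = locate_value_span(doc, inst.value_surface)
        if span is None and vocab is not None:
            # gold values are canonical; the text may carry a synonym form
            canonical = normalize_value(inst.value_surface, vocab, "transform")
            for surf in vocab.surfaces_of(canonical):
                span = locate_value_span(doc, surf)
                if span is not None:
                    break
        inst.span = span
        features = None
        if span is not None:
            sec, para, sent, start, end = span
            sentence = doc.get_sentence(sec, para, sent)
            surface = sentence.text[
                sentence.tokens[start].char_start - sentence.char_start:
                sentence.tokens[end - 1].char_end - sentence.char_start
            ]
            features = extract_features(doc, span, surface)
        update_models(self.models[inst.attribute], inst, features)

    # -- batch -------------------------------------------------------------
    def run_batch(self, docs: list[Document]) -> dict[str, dict[str, list[str]]]:
        """Frozen-model prediction for all documents; never updates models."""
        return {doc.doc_id: self.predict_values(doc) for doc in docs}

    # -- accrued accuracy --------------------------------------------------
    def rolling_accuracy(self, k: int | None = None) -> tuple[float, float]:
        """Micro precision/recall of pre-feedback predictions against final
        values over the last ``k`` processed documents."""
        from .evaluation import EvalCounts, compare_values, compute_prf
        k = k or self.config.accuracy_window
        total = EvalCounts()
        for _doc_id, prediction, final in self.history[-k:]:
            for attr in self.schema.names:
                total = total + compare_values(
                    prediction.get(attr, []), final.get(attr, []), self.vocabs.get(attr)
                )
        p, r, _ = compute_prf(total)
        return p, r

    # -- checkpointing -----------------------------------------------------
    def save_checkpoint(self, path: str | Path) -> None:
        bundle = {
            "models": {attr: m.to_json() for attr, m in self.models.items()},
            "schema": self.schema.to_dict(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(bundle, fh, indent=1, sort_keys=True)

    def load_checkpoint(self, path: str | Path) -> None:
        with open(path, encoding="utf-8") as fh:
            bundle = json.load(fh)
        for attr, data in bundle["models"].items():
            if attr in self.models:
                self.models[attr] = AttributeModel.from_json(data)


def _dedup_by_canonical(candidates: list[CandidateValue]) -> list[CandidateValue]:
    """Keep the best-confidence (then earliest) candidate per canonical."""
    best: dict[str, CandidateValue] = {}
    for cand in candidates:
        key = cand.canonical.casefold()
        prev = best.get(key)
        if prev is None or (-cand.confidence, cand.position_key) < (-prev.confidence, prev.position_key):
            best[key] = cand
    return sorted(best.values(), key=lambda c: c.position_key)
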