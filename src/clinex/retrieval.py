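"""Target-sentence retrieval.

Two complementary searches find sentences likely to hold an attribute's
answer: (1) cosine similarity between the attribute's learned contextual-word
vector and the sentence's term-frequency vector, and (2) keyword matching of
past answer surfaces and controlled-vocabulary terms.  Section constraints
narrow the scope of both.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from ._stopwords import STOPWORDS
from .document import Document, Sentence, tokenize_string
from .schema import AttributeSpec
from .vocabulary import ControlledVocabulary, match_phrases, match_terms, section_matches

__all__ = ["ContextVector", "ScoredSentence", "cosine_similarity",
           "sentence_tf", "select_target_sentences", "section_allowed",
           "answer_keyword_phrases"]


@dataclass
class ContextVector:
    """Accumulated frequencies of contextual words (landmarks) co-occurring
    with positive answers; the weights of the vector-space model."""

    weights: dict[str, float] = field(default_factory=dict)
    total_updates: int = 0

    def update(self, landmarks: list[str]) -> None:
        for w in landmarks:
            self.weights[w] = self.weights.get(w, 0.0) + 1.0
        self.total_updates += 1

    def is_empty(self) -> bool:
        return not self.weights

    def to_json(self) -> dict:
        return {"weights": dict(sorted(self.weights.items())),
                "total_updates": self.total_updates}

    @staticmethod
    def from_json(data: dict) -> "ContextVector":
        return ContextVector(weights=dict(data["weights"]),
                             total_updates=int(data["total_updates"]))


@dataclass
class ScoredSentence:
    sentence: Sentence
    sim_score: float
    selected_by: str  # "similarity" | "keyword" | "both"


def sentence_tf(sentence: Sentence) -> dict[str, int]:
    """Term-frequency vector over normalized tokens, excluding stopwords and
    punctuation-only tokens."""
    tf: dict[str, int] = {}
    for tok in sentence.tokens:
        n = tok.norm
        if n in STOPWORDS or not any(c.isalnum() for c in n):
            continue
        tf[n] = tf.get(n, 0) + 1
    return tf


def cosine_similarity(context: ContextVector, sentence: Sentence) -> float:
    """Cosine of the learned context weights and the sentence tf vector;
    0.0 when either vector is empty."""
    tf = sentence_tf(sentence)
    if context.is_empty() or not tf:
        return 0.0
    dot = sum(w * tf[t] for t, w in context.weights.items() if t in tf)
    if dot == 0.0:
        return 0.0
    nc = math.sqrt(sum(w * w for w in context.weights.values()))
    ns = math.sqrt(sum(v * v for v in tf.values()))
    return min(1.0, dot / (nc * ns))


def answer_keyword_phrases(answer_keywords) -> dict[tuple[str, ...], str]:
    """Normalized-token phrases for learned answer surfaces.

    Purely numeric surfaces are excluded: a learned heart-rate value "72"
    identifies nothing — numeric answers are recovered by the sequence model,
    not by literal keyword search.
    """
    phrases: dict[tuple[str, ...], str] = {}
    for surf in sorted(answer_keywords):
        toks = tuple(tokenize_string(surf))
        if not toks:
            continue
        if all(t.replace(".", "").replace("-", "").isdigit() for t in toks):
            continue
        phrases.setdefault(toks, surf)
    return phrases


def section_allowed(
    section_header: str,
    spec: AttributeSpec | None,
    vocab: ControlledVocabulary | None,
) -> bool:
    """Section-level scope: schema skip/positive sections and vocabulary
    negative/positive sections both narrow the search."""
    if spec is not None:
        for name in spec.skip_sections:
            if section_matches(section_header, name):
                return False
        if spec.sections and not any(
            section_matches(section_header, name) for name in spec.sections
        ):
            return False
    if vocab is not None:
        for name in vocab.structure.negative_sections:
            if section_matches(section_header, name):
                return False
        if vocab.structure.positive_sections and not any(
            section_matches(section_header, name) for name in vocab.structure.positive_sections
        ):
            return False
    return True


def select_target_sentences(
    doc: Document,
    context: ContextVector,
    answer_keywords=(),
    vocab: ControlledVocabulary | None = None,
    spec: AttributeSpec | None = None,
    theta_sim: float = 0.25,
) -> list[ScoredSentence]:
    """Union of similarity-selected and keyword-selected sentences, in
    document order, with sentences from skipped sections removed.

    Keyword selection fires when the sentence contains any learned answer
    keyword or vocabulary term; similarity selection when the cosine against
    the context vector reaches ``theta_sim``.  A fresh model with no
    vocabulary selects nothing (cold start).
    """
    kw_phrases = answer_keyword_phrases(answer_keywords)
    out: list[ScoredSentence] = []
    for sentence in doc.sentences():
        header = doc.section_header(sentence.sec_idx)
        if not section_allowed(header, spec, vocab):
            continue
        sim = cosine_similarity(context, sentence)
        by_sim = sim >= theta_sim and not context.is_empty()
        by_kw = bool(kw_phrases and match_phrases(sentence.norms(), kw_phrases))
        if not by_kw and vocab is not None:
            by_kw = bool(match_terms(sentence, vocab))
        if by_sim and by_kw:
            out.append(ScoredSentence(sentence, sim, "both"))
        elif by_sim:
            out.append(ScoredSentence(sentence, sim, "similarity"))
        elif by_kw:
            out.append(ScoredSentence(sentence, sim, "keyword"))
    return out
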