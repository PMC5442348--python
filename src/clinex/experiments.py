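"""Desk-scale experiment analogues on the synthetic corpora.

Three reproducible studies mirror how the engine is meant to be exercised:

1. ``run_online_experiment`` — interactive online learning with simulated
   feedback on the semistructured or template-narration corpus, starting from
   an empty model; reports pooled metrics, metrics over the later half of the
   run, and the decile learning curve.
2. ``run_vocabulary_experiment`` — batch extraction on the complex-narration
   corpus guided by its complete controlled vocabulary (optionally with
   structural properties stripped).
3. ``run_combined_experiment`` — terminology-only vocabulary plus a short
   interactive phase that lets rule induction learn structural context from
   feedback, then batch extraction for the rest.
"""

from __future__ import annotations

from .config import EngineConfig
from .document import parse_document
from .evaluation import evaluate_run
from .learning import ExtractionSession, GoldFeedback
from .synthetic import (CorpusSpec, SyntheticCorpus, generate_corpus,
                        strip_structure)

__all__ = ["run_online_experiment", "run_vocabulary_experiment",
           "run_combined_experiment", "parse_corpus"]


def parse_corpus(corpus: SyntheticCorpus):
    """Parse all synthetic documents, in doc_id order (the processing order
    a filename-sorted run would use)."""
    return [
        parse_document(d.text, d.doc_id, d.patient_id)
        for d in sorted(corpus.documents, key=lambda d: d.doc_id)
    ]


def run_online_experiment(
    form: str = "semistructured",
    n_docs: int = 100,
    seed: int = 0,
    config: EngineConfig | None = None,
) -> dict:
    """Online learning from an empty model with simulated gold feedback.

    Pre-feedback predictions (including the empty ones of the first
    documents) are what gets scored, exactly as an interactive user would
    experience them.
    """
    corpus = generate_corpus(form, CorpusSpec(n_patients=n_docs, seed=seed))
    docs = parse_corpus(corpus)
    session = ExtractionSession(corpus.schema, vocabs=None, config=config)
    feedback = GoldFeedback(corpus.gold)
    predictions: dict[str, dict[str, list[str]]] = {}
    for doc in docs:
        prediction, _final = session.process_document(doc, feedback)
        predictions[doc.doc_id] = prediction
    order = [d.doc_id for d in docs]
    result = evaluate_run(predictions, corpus.gold, doc_order=order, n_groups=10)
    half = len(order) // 2
    result["second_half"] = evaluate_run(
        {d: predictions[d] for d in order[half:]},
        {d: corpus.gold[d] for d in order[half:]},
        doc_order=order[half:], n_groups=1,
    )["pooled"]
    result["form"] = form
    return result


def run_vocabulary_experiment(
    n_docs: int = 100,
    seed: int = 0,
    with_structure: bool = True,
    config: EngineConfig | None = None,
) -> dict:
    """Batch extraction on the complex corpus guided by its vocabulary;
    no online learning.  ``with_structure=False`` strips negative sections
    and disambiguation indicators (terminology-only baseline)."""
    corpus = generate_corpus("complex", CorpusSpec(n_patients=n_docs, seed=seed))
    docs = parse_corpus(corpus)
    vocabs = corpus.vocabs if with_structure else strip_structure(corpus.vocabs)
    session = ExtractionSession(corpus.schema, vocabs=vocabs, config=config)
    predictions = session.run_batch(docs)
    result = evaluate_run(predictions, corpus.gold, vocabs=vocabs,
                          doc_order=[d.doc_id for d in docs], n_groups=10)
    result["with_structure"] = with_structure
    return result


def run_combined_experiment(
    n_docs: int = 100,
    n_interactive: int = 20,
    seed: int = 0,
    config: EngineConfig | None = None,
) -> dict:
    """Terminology-only vocabulary combined with online learning.

    The first ``n_interactive`` documents are processed interactively with
    simulated feedback — negative instances teach the rule model which
    sections and contexts to reject — and the remainder run in batch.
    Metrics are over the batch documents only."""
    corpus = generate_corpus("complex", CorpusSpec(n_patients=n_docs, seed=seed))
    docs = parse_corpus(corpus)
    vocabs = strip_structure(corpus.vocabs)
    session = ExtractionSession(corpus.schema, vocabs=vocabs, config=config)
    feedback = GoldFeedback(corpus.gold)
    for doc in docs[:n_interactive]:
        session.process_document(doc, feedback)
    batch_docs = docs[n_interactive:]
    predictions = session.run_batch(batch_docs)
    result = evaluate_run(predictions,
                          {d.doc_id: corpus.gold[d.doc_id] for d in batch_docs},
                          vocabs=vocabs,
                          doc_order=[d.doc_id for d in batch_docs],
                          n_groups=1)
    result["n_interactive"] = n_interactive
    return result
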