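"""Batch extraction guided by a controlled vocabulary.

Generates a small complex-narration corpus together with its complete
vocabulary, then runs frozen-model batch extraction twice: with terminology
only, and with structural properties (negative sections, disambiguation
indicators) enabled.  Prints the precision/recall of both arms.
"""

from clinex import ExtractionSession, evaluate_run, parse_document
from clinex.synthetic import CorpusSpec, generate_corpus, strip_structure

corpus = generate_corpus("complex", CorpusSpec(n_patients=30, seed=42))
docs = [parse_document(d.text, d.doc_id, d.patient_id) for d in corpus.documents]

for label, vocabs in [("terminology only", strip_structure(corpus.vocabs)),
                      ("terminology + structure", corpus.vocabs)]:
    session = ExtractionSession(corpus.schema, vocabs=vocabs)
    predictions = session.run_batch(docs)
    pooled = evaluate_run(predictions, corpus.gold, vocabs=vocabs, n_groups=1)["pooled"]
    print("%-24s precision=%.3f recall=%.3f f1=%.3f"
          % (label, pooled["precision"], pooled["recall"], pooled["f1"]))
# Terminology alone finds every mention (recall ~1.0) but also picks up
# medications listed under Allergies and "statin intolerant" traps; the
# structural properties veto those, raising precision at no recall cost.
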