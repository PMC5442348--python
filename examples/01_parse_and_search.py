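"""Parse a clinical report into the four-layer tree and search it.

Builds a small report, parses it into sections / paragraphs / sentences /
tokens, and uses the reverse token index to locate a term.
"""

from clinex import index_lookup, parse_document

TEXT = """\
HISTORY:
The patient reports history of diabetes and hypertension.
No history of cancer.

MEDICATIONS:
Metformin 500 mg daily.
"""

doc = parse_document(TEXT, doc_id="note001", patient_id="P001")

print("sections:", [s.header for s in doc.sections])
print("sentences:", sum(1 for _ in doc.sentences()))
for coord in index_lookup(doc, "diabetes"):
    sec, para, sent, tok = coord
    token = doc.get_token(coord)
    print("found %r in section %r at offsets (%d, %d)"
          % (token.surface, doc.section_header(sec), token.char_start, token.char_end))
# The index maps a normalized token straight to its tree coordinates, so the
# engine can jump from a keyword to its section and sentence in one lookup.
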