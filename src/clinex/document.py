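"""Hierarchical document model for clinical report text.

A report is parsed into a four-layer tree — section, paragraph, sentence,
token — mirroring how clinicians structure narrative reports ("HISTORY:",
"MEDICATIONS:" ...).  Every token keeps exact character offsets into the raw
text, and a reverse index from normalized token to tree coordinates supports
the keyword searches the extraction engine performs constantly.

The part-of-speech backend is pluggable: any callable mapping a list of token
surfaces to an equal-length list of Penn-Treebank-style tags.  The bundled
default is a small lexicon + suffix-rule tagger that needs no model download.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Callable, Iterator

__all__ = [
    "Token",
    "Sentence",
    "Paragraph",
    "Section",
    "Document",
    "EmptyDocumentError",
    "parse_document",
    "normalize_token",
    "tokenize_string",
    "tag_pos",
    "index_lookup",
    "RuleLexiconTagger",
]

#: tree coordinate: (section, paragraph, sentence, token) indices
Coord = tuple[int, int, int, int]


class EmptyDocumentError(ValueError):
    """Raised when a report is empty after whitespace stripping."""


# ---------------------------------------------------------------------------
# tree node types
# ---------------------------------------------------------------------------

@dataclass
class Token:
    surface: str
    norm: str
    pos: str
    char_start: int
    char_end: int
    sec_idx: int = 0
    para_idx: int = 0
    sent_idx: int = 0
    tok_idx: int = 0
    is_numeric: bool = False

    @property
    def coord(self) -> Coord:
        return (self.sec_idx, self.para_idx, self.sent_idx, self.tok_idx)


@dataclass
class Sentence:
    tokens: list[Token]
    text: str
    sec_idx: int = 0
    para_idx: int = 0
    sent_idx: int = 0
    char_start: int = 0
    char_end: int = 0

    def norms(self) -> list[str]:
        return [t.norm for t in self.tokens]


@dataclass
class Paragraph:
    sentences: list[Sentence]
    sec_idx: int = 0
    para_idx: int = 0


@dataclass
class Section:
    header: str            # "" for the implicit preamble section
    paragraphs: list[Paragraph]
    sec_idx: int = 0

    @property
    def header_norm(self) -> str:
        return self.header.rstrip(":").strip().casefold()


@dataclass
class Document:
    doc_id: str
    patient_id: str
    raw_text: str
    sections: list[Section]
    index: dict[str, list[Coord]] = field(default_factory=dict)

    def sentences(self) -> Iterator[Sentence]:
        for sec in self.sections:
            for para in sec.paragraphs:
                yield from para.sentences

    def get_sentence(self, sec_idx: int, para_idx: int, sent_idx: int) -> Sentence:
        return self.sections[sec_idx].paragraphs[para_idx].sentences[sent_idx]

    def get_token(self, coord: Coord) -> Token:
        sec, para, sent, tok = coord
        return self.sections[sec].paragraphs[para].sentences[sent].tokens[tok]

    def section_header(self, sec_idx: int) -> str:
        return self.sections[sec_idx].header

    def to_dict(self) -> dict:
        """JSON-serializable dump of the full tree (debugging aid)."""
        return {
            "doc_id": self.doc_id,
            "patient_id": self.patient_id,
            "sections": [
                {
                    "header": sec.header,
                    "paragraphs": [
                        {
                            "sentences": [
                                {
                                    "text": s.text,
                                    "tokens": [
                                        {
                                            "surface": t.surface,
                                            "norm": t.norm,
                                            "pos": t.pos,
                                            "char_start": t.char_start,
                                            "char_end": t.char_end,
                                        }
                                        for t in s.tokens
                                    ],
                                }
                                for s in para.sentences
                            ]
                        }
                        for para in sec.paragraphs
                    ],
                }
                for sec in self.sections
            ],
        }


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

_PUNCT_ONLY_RE = re.compile(r"^[^\w]+$")
_NUMERIC_RE = re.compile(r"^[+-]?\d+(?:\.\d+)?$")


def normalize_token(surface: str) -> str:
    """Casefold and lightly stem a token surface.

    A trailing plural / third-person "s" is stripped when the remaining stem
    is alphabetic and at least three characters long ("reports" -> "report");
    "-ss" endings are left alone ("class" stays "class").  Punctuation-only
    tokens are returned unchanged.
    """
    if _PUNCT_ONLY_RE.match(surface):
        return surface
    t = surface.lower()
    if (
        t.endswith("s")
        and not t.endswith("ss")
        and len(t) >= 4
        and t[:-1].isalpha()
    ):
        t = t[:-1]
    return t


def is_numeric_surface(surface: str) -> bool:
    return bool(_NUMERIC_RE.match(surface))


# ---------------------------------------------------------------------------
# part-of-speech tagging (pluggable; bundled rule/lexicon default)
# ---------------------------------------------------------------------------

Tagger = Callable[[list[str]], list[str]]

_LEXICON = {
    "the": "DT", "a": "DT", "an": "DT", "no": "DT", "this": "DT", "that": "DT",
    "some": "DT", "any": "DT", "each": "DT", "all": "DT", "both": "DT",
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN", "for": "IN",
    "with": "IN", "without": "IN", "from": "IN", "during": "IN", "after": "IN",
    "before": "IN", "under": "IN", "over": "IN", "into": "IN", "per": "IN",
    "to": "TO", "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "not": "RB", "also": "RB", "well": "RB", "currently": "RB", "now": "RB",
    "he": "PRP", "she": "PRP", "it": "PRP", "they": "PRP", "we": "PRP",
    "his": "PRP$", "her": "PRP$", "their": "PRP$", "its": "PRP$",
    "is": "VBZ", "was": "VBD", "are": "VBP", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "am": "VBP",
    "has": "VBZ", "have": "VBP", "had": "VBD",
    "does": "VBZ", "do": "VBP", "did": "VBD",
    "will": "MD", "would": "MD", "can": "MD", "could": "MD", "may": "MD",
    "should": "MD", "must": "MD", "might": "MD",
    "reports": "VBZ", "denies": "VBZ", "presents": "VBZ", "takes": "VBZ",
    "shows": "VBZ", "demonstrates": "VBZ", "reveals": "VBZ", "includes": "VBZ",
    "include": "VBP", "taking": "VBG", "underwent": "VBD",
    "patient": "NN", "history": "NN", "report": "NN", "disease": "NN",
    "medication": "NN", "therapy": "NN", "cancer": "NN", "pain": "NN",
    "heart": "NN", "rate": "NN", "diagnosis": "NN", "section": "NN",
    "allergy": "NN", "allergies": "NNS", "medications": "NNS",
    "diseases": "NNS", "symptoms": "NNS", "findings": "NNS",
    "there": "EX", "here": "RB", "when": "WRB", "which": "WDT", "who": "WP",
    "diabetes": "NN", "stenosis": "NN", "coronary": "JJ", "artery": "NN",
    "current": "JJ", "daily": "RB", "old": "JJ",
    "new": "JJ", "mild": "JJ", "moderate": "JJ", "severe": "JJ",
    "significant": "JJ", "normal": "JJ", "abnormal": "JJ", "stable": "JJ",
    "left": "JJ", "right": "JJ", "chronic": "JJ", "acute": "JJ",
    "year": "NN", "years": "NNS", "man": "NN", "woman": "NN",
}


class RuleLexiconTagger:
    """Deterministic lexicon + suffix-rule tagger (Penn-Treebank-style tags).

    Lookup order: lexicon (casefolded surface), digit rules, suffix rules,
    capitalization, default NN.  Intentionally simple — the engine uses POS
    only as one coarse feature among several.
    """

    def __init__(self, extra_lexicon: dict[str, str] | None = None):
        self.lexicon = dict(_LEXICON)
        if extra_lexicon:
            self.lexicon.update({k.lower(): v for k, v in extra_lexicon.items()})

    def __call__(self, surfaces: list[str]) -> list[str]:
        return [self._tag_one(s) for s in surfaces]

    def _tag_one(self, surface: str) -> str:
        low = surface.lower()
        if low in self.lexicon:
            return self.lexicon[low]
        if _PUNCT_ONLY_RE.match(surface):
            return surface if surface in {",", ":", ".", "(", ")"} else "SYM"
        if any(c.isdigit() for c in surface):
            return "CD"
        if low.endswith("ly"):
            return "RB"
        if low.endswith("ing") and len(low) > 4:
            return "VBG"
        if low.endswith("ed") and len(low) > 3:
            return "VBN"
        if low.endswith(("ous", "ive", "ful", "able", "ible", "al", "ic")) and len(low) > 4:
            return "JJ"
        if surface[0].isupper():
            return "NNP" if not surface.isupper() or len(surface) <= 1 else "NNP"
        if low.endswith("s") and not low.endswith("ss") and len(low) > 3:
            return "NNS"
        return "NN"


_DEFAULT_TAGGER = RuleLexiconTagger()


def tag_pos(surfaces: list[str], tagger: Tagger | None = None) -> list[str]:
    """Tag a sentence's token surfaces; one tag per token."""
    if not surfaces:
        return []
    tagger = tagger or _DEFAULT_TAGGER
    tags = tagger(surfaces)
    if len(tags) != len(surfaces):
        raise ValueError("tagger returned %d tags for %d tokens" % (len(tags), len(surfaces)))
    return tags


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

_PUNCT = set(string.punctuation)


def _split_word(word: str, offset: int) -> list[tuple[str, int, int]]:
    """Split leading/trailing punctuation off a whitespace-delimited word.

    Internal punctuation (hyphens, slashes, decimal points) stays inside the
    core token so clinical terms like "beta-blocker" and "120/80" survive.
    Each stripped punctuation character becomes its own token.
    """
    out: list[tuple[str, int, int]] = []
    start, end = 0, len(word)
    lead: list[tuple[str, int, int]] = []
    while start < end and word[start] in _PUNCT:
        lead.append((word[start], offset + start, offset + start + 1))
        start += 1
    trail: list[tuple[str, int, int]] = []
    while end > start and word[end - 1] in _PUNCT:
        trail.append((word[end - 1], offset + end - 1, offset + end))
        end -= 1
    out.extend(lead)
    if end > start:
        out.append((word[start:end], offset + start, offset + end))
    out.extend(reversed(trail))
    return out


def _tokenize_span(text: str, base: int) -> list[tuple[str, int, int]]:
    """Tokenize ``text`` returning (surface, char_start, char_end) with offsets
    relative to the original raw text (``base`` added)."""
    toks: list[tuple[str, int, int]] = []
    for m in re.finditer(r"\S+", text):
        toks.extend(_split_word(m.group(), base + m.start()))
    return toks


def tokenize_string(text: str) -> list[str]:
    """Normalized token sequence of an arbitrary string (vocabulary terms,
    learned answer surfaces).  Punctuation-only tokens are dropped so phrase
    matching is insensitive to stray commas."""
    return [
        normalize_token(s)
        for s, _, _ in _tokenize_span(text, 0)
        if not _PUNCT_ONLY_RE.match(s)
    ]


# ---------------------------------------------------------------------------
# sentence splitting
# ---------------------------------------------------------------------------

_ABBREVS = {"dr", "mr", "mrs", "ms", "st", "mg", "ml", "dl", "hr", "min",
            "vs", "etc", "approx", "e.g", "i.e", "prn", "q.d", "b.i.d"}
_BULLET_RE = re.compile(r"^\s*(?:[-*•]|\d{1,3}[.)])\s+")


def _split_sentences_in_line(text: str, base: int) -> list[tuple[int, int]]:
    """Sentence spans (absolute char offsets) within one physical line.

    Terminal ., ! or ? followed by whitespace and an uppercase letter, digit
    or opening bracket ends a sentence, unless the preceding word is a known
    abbreviation.  Line breaks always end sentences (handled by the caller),
    so spans never cross lines.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c in ".!?":
            j = i + 1
            while j < n and text[j] in ".!?":
                j += 1
            k = j
            while k < n and text[k].isspace():
                k += 1
            if k > j and k < n and (text[k].isupper() or text[k].isdigit() or text[k] in "(["):
                word = text[:i].rstrip().rsplit(None, 1)[-1].lower() if text[:i].strip() else ""
                word = word.strip(string.punctuation.replace(".", "")).rstrip(".")
                if c != "." or word not in _ABBREVS:
                    spans.append((base + start, base + j))
                    start = k
                    i = k
                    continue
            i = j
        else:
            i += 1
    if text[start:].strip():
        spans.append((base + start, base + n))
    return spans


# ---------------------------------------------------------------------------
# section headers
# ---------------------------------------------------------------------------

_HEADER_COLON_RE = re.compile(r"^[A-Za-z][A-Za-z /&-]{1,60}:\s*$")


def _is_header_line(line: str) -> bool:
    stripped = line.strip()
    if not stripped:
        return False
    if _HEADER_COLON_RE.match(stripped):
        return True
    # all-caps line of at most 8 words
    if (
        stripped == stripped.upper()
        and any(c.isalpha() for c in stripped)
        and stripped != stripped.lower()
        and len(stripped.split()) <= 8
        and not any(c.isdigit() for c in stripped)
    ):
        return True
    return False


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_document(
    raw_text: str,
    doc_id: str,
    patient_id: str = "",
    tagger: Tagger | None = None,
) -> Document:
    """Parse raw report text into the section/paragraph/sentence/token tree.

    Sections are opened by header lines ("HISTORY:", all-caps titles); text
    before the first header lands in an implicit preamble section with an
    empty header.  Paragraphs split on blank lines, sentences on terminal
    punctuation (never crossing a line break), and tokens carry exact offsets
    into ``raw_text``.  A reverse index from token norm to tree coordinates
    is built for keyword search.
    """
    if not raw_text or not raw_text.strip():
        raise EmptyDocumentError("empty document: %r" % doc_id)
    tagger = tagger or _DEFAULT_TAGGER

    # physical lines with absolute offsets
    lines: list[tuple[int, str]] = []
    pos = 0
    for line in raw_text.splitlines(keepends=True):
        content = line.rstrip("\n\r")
        lines.append((pos, content))
        pos += len(line)

    # group lines into sections, then paragraphs
    sections: list[Section] = []
    cur_header = ""
    cur_para_lines: list[tuple[int, str]] = []
    cur_paras: list[list[tuple[int, str]]] = []

    def flush_para() -> None:
        nonlocal cur_para_lines
        if cur_para_lines:
            cur_paras.append(cur_para_lines)
            cur_para_lines = []

    def flush_section() -> None:
        nonlocal cur_paras, cur_header
        flush_para()
        if cur_paras or cur_header:
            sections.append(Section(header=cur_header, paragraphs=[], sec_idx=len(sections)))
            sections[-1].paragraphs = [_build_paragraph(p) for p in cur_paras]
        cur_paras = []

    def _build_paragraph(para_lines: list[tuple[int, str]]) -> Paragraph:
        para = Paragraph(sentences=[])
        for base, text in para_lines:
            if _BULLET_RE.match(text):
                m = _BULLET_RE.match(text)
                spans = [(base + m.end(), base + len(text))] if text[m.end():].strip() else []
            else:
                spans = _split_sentences_in_line(text, base)
            for s_start, s_end in spans:
                stext = raw_text[s_start:s_end]
                raw_toks = _tokenize_span(stext, s_start)
                if not raw_toks:
                    continue
                surfaces = [s for s, _, _ in raw_toks]
                tags = tag_pos(surfaces, tagger)
                tokens = [
                    Token(
                        surface=s,
                        norm=normalize_token(s),
                        pos=tag,
                        char_start=cs,
                        char_end=ce,
                        is_numeric=is_numeric_surface(s),
                    )
                    for (s, cs, ce), tag in zip(raw_toks, tags)
                ]
                para.sentences.append(
                    Sentence(tokens=tokens, text=stext, char_start=s_start, char_end=s_end)
                )
        return para

    for base, text in lines:
        if not text.strip():
            flush_para()
        elif _is_header_line(text):
            flush_section()
            cur_header = text.strip()
        else:
            cur_para_lines.append((base, text))
    flush_section()

    if not sections:
        raise EmptyDocumentError("empty document: %r" % doc_id)

    # assign coordinates and build the reverse index
    index: dict[str, list[Coord]] = {}
    for si, sec in enumerate(sections):
        sec.sec_idx = si
        for pi, para in enumerate(sec.paragraphs):
            para.sec_idx, para.para_idx = si, pi
            for ti, sent in enumerate(para.sentences):
                sent.sec_idx, sent.para_idx, sent.sent_idx = si, pi, ti
                for ki, tok in enumerate(sent.tokens):
                    tok.sec_idx, tok.para_idx, tok.sent_idx, tok.tok_idx = si, pi, ti, ki
                    index.setdefault(tok.norm, []).append(tok.coord)

    return Document(
        doc_id=doc_id,
        patient_id=patient_id,
        raw_text=raw_text,
        sections=sections,
        index=index,
    )


def index_lookup(doc: Document, term: str) -> list[Coord]:
    """All coordinates of tokens whose norm equals ``normalize_token(term)``."""
    return list(doc.index.get(normalize_token(term), []))
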