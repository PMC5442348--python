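"""Controlled vocabularies: terminology plus structural properties.

A vocabulary for one attribute carries the terminology — canonical values,
synonyms ("DM", "Diabetes" -> "Diabetes Mellitus"), hypernyms ("Pindolol" ->
"beta blocker") and inductions ("Metformin" implies disease "Diabetes
Mellitus") — and structural properties: sections that are positive or
negative context for the attribute (medication mentions inside "Allergies"
are skipped) and disambiguation indicators ("intolerant" vetoes "statin" in
the same sentence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .document import Sentence, tokenize_string

__all__ = [
    "TermEntry",
    "StructuralProperties",
    "ControlledVocabulary",
    "VocabularyError",
    "load_vocabulary",
    "load_vocabulary_data",
    "save_vocabulary",
    "match_terms",
    "match_phrases",
    "context_allows",
    "section_matches",
    "normalize_value",
    "induce_values",
]


class VocabularyError(ValueError):
    pass


@dataclass
class TermEntry:
    canonical: str
    synonyms: list[str] = field(default_factory=list)
    hypernym: str | None = None
    induces: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class StructuralProperties:
    positive_sections: list[str] = field(default_factory=list)
    negative_sections: list[str] = field(default_factory=list)
    negative_indicators: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.positive_sections or self.negative_sections or self.negative_indicators)


class ControlledVocabulary:
    """Terminology + structure for one attribute, with fast lookup tables."""

    def __init__(
        self,
        attribute_name: str,
        entries: list[TermEntry],
        structure: StructuralProperties | None = None,
    ):
        self.attribute_name = attribute_name
        self.entries = entries
        self.structure = structure or StructuralProperties()
        pos = {s.casefold() for s in self.structure.positive_sections}
        neg = {s.casefold() for s in self.structure.negative_sections}
        if pos & neg:
            raise VocabularyError(
                "attribute %r: sections %s are both positive and negative"
                % (attribute_name, sorted(pos & neg))
            )

        self._canon_of: dict[str, str] = {}          # casefold surface -> canonical
        self._phrases: dict[tuple[str, ...], str] = {}  # norm-token tuple -> canonical
        self._entry_of: dict[str, TermEntry] = {}    # canonical -> entry
        seen_canon: set[str] = set()
        for e in entries:
            if not e.canonical:
                raise VocabularyError("attribute %r: entry with empty canonical" % attribute_name)
            cf = e.canonical.casefold()
            if cf in seen_canon:
                raise VocabularyError(
                    "attribute %r: duplicate canonical %r" % (attribute_name, e.canonical)
                )
            seen_canon.add(cf)
            self._entry_of[e.canonical] = e
            for surf in [e.canonical, *e.synonyms]:
                if surf.casefold() == cf and surf != e.canonical and surf in e.synonyms:
                    raise VocabularyError(
                        "attribute %r: entry %r lists itself as a synonym"
                        % (attribute_name, e.canonical)
                    )
                key = surf.casefold()
                prev = self._canon_of.get(key)
                if prev is not None and prev != e.canonical:
                    raise VocabularyError(
                        "attribute %r: surface %r is ambiguous between %r and %r"
                        % (attribute_name, surf, prev, e.canonical)
                    )
                self._canon_of[key] = e.canonical
                toks = tuple(tokenize_string(surf))
                if toks:
                    tprev = self._phrases.get(toks)
                    if tprev is not None and tprev != e.canonical:
                        raise VocabularyError(
                            "attribute %r: surface %r is ambiguous between %r and %r"
                            % (attribute_name, surf, tprev, e.canonical)
                        )
                    self._phrases[toks] = e.canonical

    # -- lookups ----------------------------------------------------------
    def lookup_canonical(self, raw: str) -> str | None:
        c = self._canon_of.get(raw.casefold())
        if c is not None:
            return c
        toks = tuple(tokenize_string(raw))
        return self._phrases.get(toks) if toks else None

    def entry(self, canonical: str) -> TermEntry | None:
        return self._entry_of.get(canonical)

    def surfaces_of(self, canonical: str) -> list[str]:
        """All surface forms (canonical first) mapping to ``canonical``."""
        e = self._entry_of.get(canonical)
        if e is None:
            return [canonical]
        return [e.canonical, *e.synonyms]

    @property
    def phrase_map(self) -> dict[tuple[str, ...], str]:
        return self._phrases


# ---------------------------------------------------------------------------
# file format
# ---------------------------------------------------------------------------
#
# YAML (or JSON) mapping attribute name -> {terms: [...], structure: {...}}:
#
#   disease:
#     terms:
#       - canonical: Diabetes Mellitus
#         synonyms: [DM, Diabetes]
#     structure:
#       negative_sections: []
#   medication:
#     terms:
#       - canonical: Metformin
#         induces:
#           - {attribute: disease, value: Diabetes Mellitus}
#       - canonical: Pindolol
#         hypernym: beta blocker
#     structure:
#       negative_sections: [Allergies]
#       negative_indicators: [intolerant]


def load_vocabulary_data(data: dict, schema=None) -> dict[str, ControlledVocabulary]:
    """Build vocabularies from already-parsed mapping data (see module docs)."""
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise VocabularyError("vocabulary data must be a mapping of attributes")
    vocabs: dict[str, ControlledVocabulary] = {}
    valid_attrs = set(schema.names) if schema is not None else set(data)
    for attr, block in data.items():
        block = block or {}
        entries = []
        for raw in block.get("terms", []) or []:
            if not isinstance(raw, dict) or "canonical" not in raw:
                raise VocabularyError(
                    "attribute %r: term entry %r lacks a canonical" % (attr, raw)
                )
            induces = []
            for ind in raw.get("induces", []) or []:
                tgt, val = ind.get("attribute"), ind.get("value")
                if not tgt or not val:
                    raise VocabularyError(
                        "attribute %r: entry %r has malformed induction %r"
                        % (attr, raw["canonical"], ind)
                    )
                if tgt not in valid_attrs:
                    raise VocabularyError(
                        "attribute %r: entry %r induces unknown attribute %r"
                        % (attr, raw["canonical"], tgt)
                    )
                induces.append((tgt, val))
            entries.append(
                TermEntry(
                    canonical=str(raw["canonical"]),
                    synonyms=[str(s) for s in raw.get("synonyms", []) or []],
                    hypernym=raw.get("hypernym"),
                    induces=induces,
                )
            )
        sblock = block.get("structure", {}) or {}
        structure = StructuralProperties(
            positive_sections=[str(s) for s in sblock.get("positive_sections", []) or []],
            negative_sections=[str(s) for s in sblock.get("negative_sections", []) or []],
            negative_indicators=[str(s) for s in sblock.get("negative_indicators", []) or []],
        )
        vocabs[attr] = ControlledVocabulary(attr, entries, structure)
    return vocabs


def load_vocabulary(path: str | Path, schema=None) -> dict[str, ControlledVocabulary]:
    """Load a YAML/JSON vocabulary file; all invariants enforced at load."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return load_vocabulary_data(data, schema=schema)


def save_vocabulary(vocabs: dict[str, ControlledVocabulary], path: str | Path) -> None:
    data: dict = {}
    for attr, v in vocabs.items():
        data[attr] = {
            "terms": [
                {
                    "canonical": e.canonical,
                    **({"synonyms": e.synonyms} if e.synonyms else {}),
                    **({"hypernym": e.hypernym} if e.hypernym else {}),
                    **(
                        {"induces": [{"attribute": a, "value": val} for a, val in e.induces]}
                        if e.induces
                        else {}
                    ),
                }
                for e in v.entries
            ],
            "structure": {
                "positive_sections": v.structure.positive_sections,
                "negative_sections": v.structure.negative_sections,
                "negative_indicators": v.structure.negative_indicators,
            },
        }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_phrases(
    norms: list[str], phrases: dict[tuple[str, ...], str]
) -> list[tuple[tuple[int, int], str]]:
    """Greedy longest-match-first, non-overlapping phrase matching over a
    normalized token sequence.  Returns ((start, end), payload) pairs sorted
    by start; ``end`` is exclusive."""
    if not phrases:
        return []
    max_len = max(len(p) for p in phrases)
    out: list[tuple[tuple[int, int], str]] = []
    i = 0
    n = len(norms)
    while i < n:
        hit = None
        for length in range(min(max_len, n - i), 0, -1):
            key = tuple(norms[i:i + length])
            if key in phrases:
                hit = (length, phrases[key])
                break
        if hit:
            length, payload = hit
            out.append(((i, i + length), payload))
            i += length
        else:
            i += 1
    return out


def match_terms(
    sentence: Sentence, vocab: ControlledVocabulary
) -> list[tuple[tuple[int, int], str]]:
    """Vocabulary term matches in a sentence: case-insensitive, word-boundary
    anchored (token-level), longest-match-first, non-overlapping.  Each match
    reports the canonical value."""
    return match_phrases(sentence.norms(), vocab.phrase_map)


def section_matches(section_header: str, section_name: str) -> bool:
    """Casefold substring match: vocabulary section "Allergies" matches the
    document header "ALLERGIES AND INTOLERANCES"."""
    return section_name.casefold() in section_header.casefold()


def context_allows(
    match: tuple[tuple[int, int], str],
    sentence: Sentence,
    section_header: str,
    structure: StructuralProperties,
    indicator_window: int | None = None,
) -> bool:
    """Whether structural properties permit a vocabulary match.

    False when the section is a negative context, when positive sections are
    configured and the current section is not among them, or when a negative
    indicator occurs in the same sentence within ``indicator_window`` tokens
    of the match (None = anywhere in the sentence).
    """
    if structure is None or structure.is_empty():
        return True
    for name in structure.negative_sections:
        if section_matches(section_header, name):
            return False
    if structure.positive_sections and not any(
        section_matches(section_header, name) for name in structure.positive_sections
    ):
        return False
    if structure.negative_indicators:
        (mstart, mend), _ = match
        norms = sentence.norms()
        ind_phrases = {
            tuple(tokenize_string(ind)): ind for ind in structure.negative_indicators
        }
        for (istart, iend), _ind in match_phrases(norms, ind_phrases):
            if iend <= mstart or istart >= mend:  # indicator outside the match itself
                if indicator_window is None:
                    return False
                dist = (mstart - iend) if iend <= mstart else (istart - mend)
                if dist <= indicator_window:
                    return False
    return True


# ---------------------------------------------------------------------------
# normalization and induction
# ---------------------------------------------------------------------------

def normalize_value(
    raw: str, vocab: ControlledVocabulary | None, mode: str = "transform"
) -> str:
    """Normalize a value via the vocabulary.

    ``transform``: synonym -> canonical (identity for unknown strings).
    ``generalize``: transform, then canonical -> hypernym when one is defined.
    """
    if mode not in ("transform", "generalize"):
        raise ValueError("mode must be 'transform' or 'generalize', got %r" % mode)
    if vocab is None:
        return raw
    canonical = vocab.lookup_canonical(raw)
    if canonical is None:
        return raw
    if mode == "generalize":
        entry = vocab.entry(canonical)
        if entry is not None and entry.hypernym:
            return entry.hypernym
    return canonical


def induce_values(
    matched_canonicals: list[str],
    vocabs: dict[str, ControlledVocabulary],
) -> list[tuple[str, str]]:
    """Union of induction targets of all matched entries, deduplicated,
    in first-seen order."""
    out: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for canonical in matched_canonicals:
        for vocab in vocabs.values():
            entry = vocab.entry(canonical)
            if entry is None:
                continue
            for pair in entry.induces:
                if pair not in seen:
                    seen.add(pair)
                    out.append(pair)
    return out
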