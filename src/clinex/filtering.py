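"""Candidate filtering: hard constraints and induced If-Then reject rules.

Hard filters are applied first — value-domain membership, negation
("no history of cancer"), uncertainty/plans ("planned to take radiation
therapy"), and vocabulary context (negative sections, disambiguation
indicators).  Induced rules follow: per feature predicate (head-token POS,
string-pattern class, domain membership) the model tracks how many positive
vs negative feedback instances exhibited it, and once the negative coverage
of a predicate reaches a threshold with enough support, candidates matching
it are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .document import Sentence, tokenize_string
from .schema import AttributeSpec, ValueDomain
from .vocabulary import ControlledVocabulary, context_allows, match_phrases

__all__ = ["RuleModel", "TriggerLexicon", "DEFAULT_LEXICON",
           "classify_string_pattern", "in_value_domain",
           "detect_negation", "detect_uncertainty", "apply_filters",
           "candidate_predicates"]


# ---------------------------------------------------------------------------
# string patterns
# ---------------------------------------------------------------------------

_PATTERNS = ("all_caps", "init_cap_all_tokens", "lower", "mixed",
             "numeric", "alnum_code", "other")


def classify_string_pattern(surface: str) -> str:
    """Deterministic surface-shape class of a chunk.

    Checked in order: pure number -> ``numeric``; single token mixing letters
    and digits -> ``alnum_code``; no letters at all -> ``other``; every
    letter uppercase -> ``all_caps``; every whitespace token capitalized
    ("Diabetes Mellitus") -> ``init_cap_all_tokens``; every letter lowercase
    -> ``lower``; anything else -> ``mixed``.
    """
    s = surface.strip()
    if not s:
        return "other"
    tokens = s.split()
    import re
    if re.fullmatch(r"[+-]?\d+(?:[./]\d+)*%?", s):
        return "numeric"
    if len(tokens) == 1 and any(c.isalpha() for c in s) and any(c.isdigit() for c in s):
        return "alnum_code"
    letters = [c for c in s if c.isalpha()]
    if not letters:
        return "other"
    if all(c.isupper() for c in letters):
        return "all_caps"
    if all(t[0].isupper() and t[1:].islower() for t in tokens if any(c.isalpha() for c in t)):
        return "init_cap_all_tokens"
    if all(c.islower() for c in letters):
        return "lower"
    return "mixed"


def in_value_domain(surface: str, constraint: ValueDomain | None) -> bool:
    """Closed-interval numeric range or casefold enumeration membership;
    True when no constraint is given."""
    if constraint is None:
        return True
    return constraint.contains(surface)


# ---------------------------------------------------------------------------
# negation / uncertainty
# ---------------------------------------------------------------------------

@dataclass
class TriggerLexicon:
    """Phrase triggers for negation and uncertainty, with scope terminators.

    Defaults cover common clinical usage and are user-extensible; the scope
    window counts tokens between the trigger and the candidate chunk.
    """

    negation_triggers: list[str] = field(default_factory=lambda: [
        "no", "not", "denies", "denied", "without", "negative for",
        "no history of", "free of",
    ])
    certainty_triggers: list[str] = field(default_factory=lambda: [
        "planned", "plan to", "will", "scheduled", "consider", "considering",
        "recommend", "if needed",
    ])
    scope_terminators: list[str] = field(default_factory=lambda: [
        "but", "however", "although", ";",
    ])

    def extended(self, extra_negation=(), extra_certainty=()) -> "TriggerLexicon":
        return TriggerLexicon(
            negation_triggers=self.negation_triggers + list(extra_negation),
            certainty_triggers=self.certainty_triggers + list(extra_certainty),
            scope_terminators=list(self.scope_terminators),
        )

    @staticmethod
    def from_files(negation_path=None, certainty_path=None) -> "TriggerLexicon":
        """Load trigger phrases from plain-text files, one phrase per line."""
        lex = TriggerLexicon()
        if negation_path:
            with open(negation_path, encoding="utf-8") as fh:
                lex.negation_triggers = [ln.strip() for ln in fh if ln.strip()]
        if certainty_path:
            with open(certainty_path, encoding="utf-8") as fh:
                lex.certainty_triggers = [ln.strip() for ln in fh if ln.strip()]
        return lex


DEFAULT_LEXICON = TriggerLexicon()


def _triggered(
    sentence: Sentence,
    chunk_span: tuple[int, int],
    triggers: list[str],
    terminators: list[str],
    window: int,
) -> bool:
    norms = sentence.norms()
    start = chunk_span[0]
    trig_phrases = {tuple(tokenize_string(t)): t for t in triggers}
    trig_phrases = {k: v for k, v in trig_phrases.items() if k}
    term_set = {t.casefold() for t in terminators}
    for (tstart, tend), _ in match_phrases(norms, trig_phrases):
        if tend > start:
            continue  # trigger not before the chunk
        if start - tend > window:
            continue  # out of scope
        between = norms[tend:start]
        if any(t in term_set or t.casefold() in term_set for t in between):
            continue
        return True
    return False


def detect_negation(
    sentence: Sentence,
    chunk_span: tuple[int, int],
    lexicon: TriggerLexicon = DEFAULT_LEXICON,
    window: int = 6,
) -> bool:
    """True when a negation trigger governs the chunk: it occurs before the
    chunk, within ``window`` tokens, with no scope terminator in between."""
    return _triggered(sentence, chunk_span, lexicon.negation_triggers,
                      lexicon.scope_terminators, window)


def detect_uncertainty(
    sentence: Sentence,
    chunk_span: tuple[int, int],
    lexicon: TriggerLexicon = DEFAULT_LEXICON,
    window: int = 6,
) -> bool:
    """True when a plan/uncertainty trigger governs the chunk (same scope
    rule as negation)."""
    return _triggered(sentence, chunk_span, lexicon.certainty_triggers,
                      lexicon.scope_terminators, window)


# ---------------------------------------------------------------------------
# induced rules
# ---------------------------------------------------------------------------

@dataclass
class RuleModel:
    """Per-predicate positive/negative instance counts for rule induction.

    A reject rule triggers once the coverage of its predicate among negative
    instances — negative / (positive + negative) — reaches ``tau`` with at
    least ``min_support`` total observations.  Counts only ever increase, so
    triggering is monotone in negative evidence.
    """

    counts: dict[str, list[int]] = field(default_factory=dict)  # predicate -> [pos, neg]
    tau: float = 0.9
    min_support: int = 5

    def observe(self, predicates, polarity: str) -> None:
        idx = 0 if polarity == "positive" else 1
        for p in predicates:
            self.counts.setdefault(p, [0, 0])[idx] += 1

    def coverage(self, predicate: str) -> float | None:
        pos, neg = self.counts.get(predicate, (0, 0))
        total = pos + neg
        return (neg / total) if total else None

    def triggered(self, predicate: str) -> bool:
        pos, neg = self.counts.get(predicate, (0, 0))
        total = pos + neg
        return total >= self.min_support and (neg / total) >= self.tau

    def rejects(self, predicates) -> bool:
        return any(self.triggered(p) for p in predicates)

    def to_json(self) -> dict:
        return {"counts": {k: list(v) for k, v in sorted(self.counts.items())},
                "tau": self.tau, "min_support": self.min_support}

    @staticmethod
    def from_json(data: dict) -> "RuleModel":
        return RuleModel(counts={k: [int(a), int(b)] for k, (a, b) in data["counts"].items()},
                         tau=float(data["tau"]), min_support=int(data["min_support"]))


def candidate_predicates(
    surface: str,
    head_pos: str | None = None,
    section_header: str | None = None,
) -> list[str]:
    """Feature predicates of a candidate used by rule induction: string
    pattern class, head-token (last token) POS when a span is known, and the
    containing section (the position feature — this is how negative section
    contexts can be learned from feedback instead of being configured)."""
    preds = ["pattern=%s" % classify_string_pattern(surface)]
    if head_pos:
        preds.append("pos_tag=%s" % head_pos)
    if section_header is not None and section_header != "":
        preds.append("section=%s" % section_header.rstrip(":").strip().casefold())
    return preds


# ---------------------------------------------------------------------------
# combined filter
# ---------------------------------------------------------------------------

def apply_filters(
    candidates,
    sentence: Sentence,
    section_header: str,
    rule_model: RuleModel | None = None,
    spec: AttributeSpec | None = None,
    vocab: ControlledVocabulary | None = None,
    lexicon: TriggerLexicon = DEFAULT_LEXICON,
    scope_window: int = 6,
    indicator_window: int | None = None,
):
    """Filter candidate chunks; survivors keep their scores and order.

    Hard constraints run first (value domain, negation, certainty,
    vocabulary context), then triggered induced reject rules.
    """
    survivors = []
    for cand in candidates:
        if spec is not None and not in_value_domain(cand.surface, spec.domain):
            continue
        if detect_negation(sentence, cand.span, lexicon, scope_window):
            continue
        if detect_uncertainty(sentence, cand.span, lexicon, scope_window):
            continue
        if vocab is not None and not context_allows(
            (cand.span, cand.canonical or cand.surface),
            sentence, section_header, vocab.structure, indicator_window,
        ):
            continue
        if rule_model is not None:
            head_pos = sentence.tokens[cand.span[1] - 1].pos
            if rule_model.rejects(candidate_predicates(cand.surface, head_pos, section_header)):
                continue
        survivors.append(cand)
    return survivors
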