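"""Candidate-chunk extraction inside target sentences.

Each attribute owns a small discrete hidden Markov model over three states —
O (outside), B (begin value), I (inside value) — whose counts grow online
from confirmed answers.  Viterbi decoding marks value spans in new
sentences.  A keyword search over past answer surfaces and vocabulary terms
provides a second, exact route to candidates; the two are merged.

Numeric tokens share a single ``<num>`` emission class: numeric answers
(heart rate, ejection fraction) are open-class, so literal counts could not
generalize to unseen numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .document import Sentence, is_numeric_surface
from .retrieval import answer_keyword_phrases
from .vocabulary import ControlledVocabulary, match_phrases, match_terms

__all__ = ["HmmModel", "CandidateChunk", "viterbi_decode",
           "extract_hmm_chunks", "extract_keyword_chunks", "merge_candidates",
           "STATES", "NUM_CLASS"]

STATES = ("O", "B", "I")
NUM_CLASS = "<num>"
NEG_INF = float("-inf")

#: structurally allowed successors (an I can only continue a value)
_ALLOWED_NEXT = {"O": ("O", "B"), "B": ("O", "B", "I"), "I": ("O", "B", "I")}
_ALLOWED_START = ("O", "B")


def emit_key(token) -> str:
    """Emission symbol of a token: its norm, or the shared numeric class."""
    return NUM_CLASS if token.is_numeric else token.norm


@dataclass
class HmmModel:
    """Count-based O/B/I chunking model with add-one smoothing.

    Stores raw counts (not probabilities) so online updates are pure
    increments and serialized sessions replay exactly.
    """

    start_counts: dict[str, int] = field(default_factory=dict)
    trans_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    emis_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    vocab: set[str] = field(default_factory=set)

    # -- probabilities -----------------------------------------------------
    @property
    def trained(self) -> bool:
        return bool(self.start_counts)

    def _vocab_size(self) -> int:
        # +1 reserves mass for unseen symbols (UNK)
        return len(self.vocab) + 1

    def log_start(self, state: str) -> float:
        if state not in _ALLOWED_START:
            return NEG_INF
        total = sum(self.start_counts.get(s, 0) for s in _ALLOWED_START)
        c = self.start_counts.get(state, 0)
        return math.log((c + 1) / (total + len(_ALLOWED_START)))

    def log_trans(self, prev: str, nxt: str) -> float:
        allowed = _ALLOWED_NEXT[prev]
        if nxt not in allowed:
            return NEG_INF
        row = self.trans_counts.get(prev, {})
        total = sum(row.get(s, 0) for s in allowed)
        c = row.get(nxt, 0)
        return math.log((c + 1) / (total + len(allowed)))

    def log_emit(self, state: str, symbol: str) -> float:
        row = self.emis_counts.get(state, {})
        total = sum(row.values())
        c = row.get(symbol, 0)
        return math.log((c + 1) / (total + self._vocab_size()))

    # -- updates -----------------------------------------------------------
    def observe(self, symbols: list[str], value_start: int, value_end: int) -> None:
        """Add one labeled sentence: tokens in [value_start, value_end) are
        the value (B at the start, I after), everything else O."""
        labels = [
            "B" if i == value_start else ("I" if value_start < i < value_end else "O")
            for i in range(len(symbols))
        ]
        self.start_counts[labels[0]] = self.start_counts.get(labels[0], 0) + 1
        for a, b in zip(labels, labels[1:]):
            self.trans_counts.setdefault(a, {})[b] = self.trans_counts.get(a, {}).get(b, 0) + 1
        for lab, sym in zip(labels, symbols):
            self.emis_counts.setdefault(lab, {})[sym] = self.emis_counts.get(lab, {}).get(sym, 0) + 1
            self.vocab.add(sym)

    def path_logprob(self, symbols: list[str], states: list[str]) -> float:
        lp = self.log_start(states[0]) + self.log_emit(states[0], symbols[0])
        for i in range(1, len(symbols)):
            lp += self.log_trans(states[i - 1], states[i])
            lp += self.log_emit(states[i], symbols[i])
        return lp

    # -- serialization -----------------------------------------------------
    def to_json(self) -> dict:
        return {
            "start_counts": dict(sorted(self.start_counts.items())),
            "trans_counts": {k: dict(sorted(v.items())) for k, v in sorted(self.trans_counts.items())},
            "emis_counts": {k: dict(sorted(v.items())) for k, v in sorted(self.emis_counts.items())},
            "vocab": sorted(self.vocab),
        }

    @staticmethod
    def from_json(data: dict) -> "HmmModel":
        return HmmModel(
            start_counts={k: int(v) for k, v in data["start_counts"].items()},
            trans_counts={k: {kk: int(vv) for kk, vv in v.items()}
                          for k, v in data["trans_counts"].items()},
            emis_counts={k: {kk: int(vv) for kk, vv in v.items()}
                         for k, v in data["emis_counts"].items()},
            vocab=set(data["vocab"]),
        )


@dataclass
class CandidateChunk:
    span: tuple[int, int]  # token range within the sentence, end exclusive
    surface: str
    source: str            # "hmm" | "keyword" | "both"
    chunk_score: float
    canonical: str | None = None  # set when the chunk came from a vocabulary term


def viterbi_decode(hmm: HmmModel, symbols: list[str]) -> tuple[list[str], float]:
    """Maximum-probability state path under the smoothed model.

    Ties break toward O at every choice point (states are scanned in the
    order O, B, I with a strict improvement required), so an untrained model
    decodes everything as O.
    """
    if not symbols:
        raise ValueError("empty token list")
    n = len(symbols)
    score = [{s: NEG_INF for s in STATES} for _ in range(n)]
    back: list[dict[str, str | None]] = [{s: None for s in STATES} for _ in range(n)]
    for s in STATES:
        score[0][s] = hmm.log_start(s) + hmm.log_emit(s, symbols[0])
    for i in range(1, n):
        for s in STATES:
            best, best_prev = NEG_INF, None
            for p in STATES:
                cand = score[i - 1][p] + hmm.log_trans(p, s)
                if cand > best:
                    best, best_prev = cand, p
            score[i][s] = best + hmm.log_emit(s, symbols[i]) if best > NEG_INF else NEG_INF
            back[i][s] = best_prev
    final, final_s = NEG_INF, "O"
    for s in STATES:
        if score[n - 1][s] > final:
            final, final_s = score[n - 1][s], s
    path = [final_s]
    for i in range(n - 1, 0, -1):
        path.append(back[i][path[-1]])
    path.reverse()
    return path, final


def _chunk_score(hmm: HmmModel, symbols: list[str], lp_path: float) -> float:
    """Logistic transform of the per-token log-odds of the decoded path
    against the all-O path; comparable across sentences, in [0, 1]."""
    lp_o = hmm.path_logprob(symbols, ["O"] * len(symbols))
    z = (lp_path - lp_o) / len(symbols)
    return 1.0 / (1.0 + math.exp(-z))


def extract_hmm_chunks(hmm: HmmModel, sentence: Sentence) -> list[CandidateChunk]:
    """Maximal B I* runs of the Viterbi path, scored by path log-odds."""
    if not hmm.trained or not sentence.tokens:
        return []
    symbols = [emit_key(t) for t in sentence.tokens]
    path, lp = viterbi_decode(hmm, symbols)
    if "B" not in path:
        return []
    score = _chunk_score(hmm, symbols, lp)
    chunks: list[CandidateChunk] = []
    i = 0
    while i < len(path):
        if path[i] == "B":
            j = i + 1
            while j < len(path) and path[j] == "I":
                j += 1
            toks = sentence.tokens[i:j]
            surface = sentence.text[
                toks[0].char_start - sentence.char_start:
                toks[-1].char_end - sentence.char_start
            ]
            chunks.append(CandidateChunk(span=(i, j), surface=surface,
                                         source="hmm", chunk_score=score))
            i = j
        else:
            i += 1
    return chunks


def extract_keyword_chunks(
    sentence: Sentence,
    answer_keywords=(),
    vocab: ControlledVocabulary | None = None,
) -> list[CandidateChunk]:
    """Exact matches of past answer surfaces and vocabulary terms.

    Longest-match-first, non-overlapping; vocabulary matches win over answer
    keywords on the same span and carry their canonical.  Exact matches score
    1.0.
    """
    norms = sentence.norms()
    chunks: list[CandidateChunk] = []
    taken: set[tuple[int, int]] = set()

    def _surface(span: tuple[int, int]) -> str:
        toks = sentence.tokens[span[0]:span[1]]
        return sentence.text[
            toks[0].char_start - sentence.char_start:
            toks[-1].char_end - sentence.char_start
        ]

    if vocab is not None:
        for span, canonical in match_terms(sentence, vocab):
            chunks.append(CandidateChunk(span=span, surface=_surface(span),
                                         source="keyword", chunk_score=1.0,
                                         canonical=canonical))
            taken.add(span)
    kw_phrases = answer_keyword_phrases(answer_keywords)
    if kw_phrases:
        for span, _surf in match_phrases(norms, kw_phrases):
            if span in taken:
                continue
            if any(not (span[1] <= a or span[0] >= b) for a, b in taken):
                continue  # overlap with a vocabulary match: vocabulary wins
            chunks.append(CandidateChunk(span=span, surface=_surface(span),
                                         source="keyword", chunk_score=1.0))
    chunks.sort(key=lambda c: c.span)
    return chunks


def merge_candidates(
    hmm_chunks: list[CandidateChunk], keyword_chunks: list[CandidateChunk]
) -> list[CandidateChunk]:
    """Combine the two candidate lists for one sentence.

    Span-identical candidates collapse into one with source "both" and the
    max score; overlapping but non-identical candidates are both kept for
    filtering and ranking to sort out.  Output sorted by span.
    """
    by_span: dict[tuple[int, int], CandidateChunk] = {}
    for c in hmm_chunks:
        by_span[c.span] = c
    out: list[CandidateChunk] = []
    for c in keyword_chunks:
        prev = by_span.get(c.span)
        if prev is not None:
            by_span[c.span] = CandidateChunk(
                span=c.span, surface=c.surface, source="both",
                chunk_score=max(prev.chunk_score, c.chunk_score),
                canonical=c.canonical or prev.canonical,
            )
        else:
            by_span[c.span] = c
    out = sorted(by_span.values(), key=lambda c: c.span)
    return out
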