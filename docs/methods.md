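# Methods

This note documents the extraction engine's models, its tunable parameters,
the synthetic data it is validated on, and the design choices made where the
design space was genuinely open.

## Document model

Reports are parsed into a four-layer tree — section → paragraph → sentence →
token — with exact 0-based half-open character offsets into the raw text, so
every extracted value can be traced to its source span. A reverse index maps
each normalized token to its tree coordinates.

Design choices:

- **Section headers.** A line is a header iff it matches
  `^[A-Za-z][A-Za-z /&-]{1,60}:\s*$` (text-plus-colon with nothing after it,
  so "Heart Rate: 72" is *not* a header) or is an all-caps line of ≤ 8 words
  containing no digits. Text before the first header forms an implicit
  preamble section with an empty header. Vocabulary section names match
  document headers by casefolded substring ("Allergies" matches "ALLERGIES
  AND INTOLERANCES"), since header wording varies between reporting systems.
- **Sentences.** Rule-based splitting on `.`, `!`, `?` followed by
  whitespace and an uppercase letter/digit, with an abbreviation stop-list
  ("Dr.", "mg." etc.); bullet and numbered list lines are their own
  sentences. A line break always ends a sentence: clinical reports are
  line-oriented, and "Attribute: value" lines carry no terminal punctuation
  — without this rule a whole semistructured block would collapse into one
  sentence. Generators and corpora therefore keep one prose sentence per
  physical line.
- **Tokens.** Whitespace split, then leading/trailing punctuation split off
  as separate tokens; internal hyphens/slashes are kept so "beta-blocker"
  and "120/80" survive intact. Normalization casefolds and strips one
  trailing plural/3rd-person "s" when the remaining alphabetic stem has ≥ 3
  characters (never after "-ss"), which is deliberately lighter than a
  Porter-style stemmer: it only has to make "reports"/"report" and
  "medications"/"medication" collide, not conflate derivational forms.
- **POS tagging.** A pluggable contract (token surfaces in, equal-length
  Penn-Treebank-style tags out). The bundled default is a ~130-entry lexicon
  plus suffix/digit/capitalization rules; it is deterministic, needs no
  model download, and is accurate enough for the coarse use the engine makes
  of POS (one reject-rule predicate). Any better tagger can be dropped in.

## Retrieval, chunking, filtering, ranking

**Sentence retrieval** unions two searches: cosine similarity between the
attribute's accumulated contextual-word weights (raw frequencies, no idf —
frequencies are what the update rule accrues, and idf would add an uncited
rescaling) and the sentence tf vector over normalized non-stopword tokens;
and keyword matching of learned answer surfaces and vocabulary terms.
The union maximizes recall; the threshold `θ_sim` defaults to 0.25 and the
~120-word stopword list is fixed and shipped. With an empty model and no
vocabulary nothing is selected (cold start). Purely numeric answer surfaces
are **not** reused as keywords: a learned heart-rate "72" identifies nothing
about later sentences, and reusing it would select every sentence containing
that literal; numeric answers are recovered by the sequence model instead.

**Chunking** uses a per-attribute discrete HMM over states {O, B, I}, the
minimal topology that supports multi-token values ("myocardial
infarction"). Structural zeros forbid starting in I and the O→I transition;
transitions are smoothed uniformly over the allowed successors and emissions
with add-one over the seen vocabulary plus an unseen-symbol reserve. Numeric
tokens map to a shared `<num>` emission class — numeric fields are
open-class, so literal counts could never generalize to unseen numbers.
Viterbi decoding (ties broken toward O at every choice point, so an
untrained model decodes all-O) marks value spans; maximal B I\* runs become
candidates scored `1/(1+exp(−(ℓ_path − ℓ_O)/n))`, the logistic of the
per-token log-odds against the all-O path, giving scores comparable across
sentences of different lengths. Posterior decoding would be a defensible
alternative; Viterbi was chosen for determinism and trivial replay. Keyword
candidates (past answers, vocabulary terms) match longest-first,
non-overlapping, and score 1.0; span-identical candidates from the two
routes merge (source "both", max score), overlapping non-identical ones are
both kept for filtering and ranking to adjudicate.

**Filtering** applies hard constraints first — value domain (closed numeric
interval or casefold enumeration), negation, uncertainty, vocabulary context
— then induced reject rules. The trigger lexicons default to
negation = {no, not, denies, denied, without, negative for, no history of,
free of} and certainty = {planned, plan to, will, scheduled, consider,
considering, recommend, if needed}, with scope terminators {but, however,
although, ";"} and a 6-token scope window before the candidate; all are
user-overridable and loadable from plain-text lists. A trigger *after* the
chunk never fires ("Cancer was not found." is a documented false negative of
the scope rule). Induced rules are reject rules: per predicate
(string-pattern class, head-token POS, containing section) the rule model
counts positive and negative instances; a predicate with negative coverage
≥ `τ_rule` = 0.9 and support ≥ `min_support` = 5 rejects matching
candidates. Reject polarity was chosen because acceptance is already handled
by confidence scoring; the section predicate is what lets the engine *learn*
negative section contexts (e.g. Allergies) from feedback when the vocabulary
does not state them.

**Ranking and assembly.** Confidence is the linear combination
`w·sim + (1−w)·chunk`, `w = 0.5` by default — the simplest combination rule
with interpretable weights. Single-valued attributes accept the argmax if it
reaches `τ_conf` = 0.5 (ties → earliest document position); multi-valued
attributes accept everything at or above it. Accepted values are normalized
(synonym → canonical; canonical → hypernym only for attributes configured
with `generalize`, since drug-class rollup is wanted for some studies and
wrong for others), inductions fire **only on accepted post-filter values**
(a negated "not on metformin" mention induces nothing), and per-patient
aggregation deduplicates by canonical with set semantics for multi-valued
attributes (report order is irrelevant; output sorted by canonical) and
confidence-then-recency resolution for single-valued conflicts.

## Online learning

After each document the engine compares its pre-feedback prediction with the
final values: every final value is a positive instance (confirmed or
user-entered), every revised-away prediction a negative one. Positive
instances located in the text (first occurrence of the normalized token
sequence, trying vocabulary synonym surfaces when the gold value is a
canonical) update the context vector with the sentence's non-stopword,
non-numeric landmarks, add the labeled sentence to the HMM counts, add the
surface to the answer keywords, and increment the rule model's positive
counts. Negative instances update only the rule counters — the learning
contract scopes landmark updates to positives, and a negative HMM update has
no natural count semantics. Unlocatable positives update keywords and rule
counters only. All updates are pure count increments, so serializing the
instance log and replaying it in any order reconstructs bit-identical
models; batch mode runs the identical prediction pipeline and never mutates
counts. A rolling micro precision/recall over the last 10 documents gives
the user the accrued-accuracy signal for deciding when to switch to batch.

## Synthetic corpora

The generators emulate the three report forms at desk scale (default 100
documents per form, seeded and byte-reproducible) from a cardiology-flavored
term bank (25 diseases with abbreviations, 38 medications with drug classes
and two disease inductions, 12 coronary artery phrases):

- **Semistructured**: "Attribute: value" lines under header sections,
  shuffled attribute order, 10% missing-attribute rate; heart rate sampled
  in [42, 178] against a declared [0, 200] domain.
- **Template narration**: findings sentences from a fixed three-template
  bank with artery/severity slots, a 20% negated-finding rate and
  boilerplate distractor lines; gold is the filled slots of positive
  sentences.
- **Complex narration**: History / Medications / Allergies / Plan sections
  with abbreviation usage (50%), negated disease mentions (20%), planned
  medications (30%), allergy-section medications (40%) and "statin
  intolerant" disambiguation traps (30%), all gold-negative; gold is at the
  clinical-finding level (abbreviations resolved, inductions applied) and a
  complete matching vocabulary file is emitted.

These rates were fixed once as plausible clinical-text proportions and are
the corpus spec's study conditions. What the synthetic corpora deliberately
do **not** model: misspellings, OCR noise, cross-sentence coreference,
temporal qualification, hedging beyond the trigger lexicon, and the lexical
diversity of real dictation. Passing the synthetic studies therefore
demonstrates that the machinery works as specified under its stated
assumptions — not that real-corpus accuracy would match; the real-data
headline numbers in the literature come from protected hospital corpora that
cannot ship with a test suite.

## Numerical and degenerate-input conventions

- Precision is 1.0 when nothing was predicted and nothing was missed, 0.0
  when nothing was predicted but gold values exist; recall mirrors this; F1
  is 0 when p + r = 0. Learning curves partition documents into contiguous
  blocks in processing order, remainder spread over the first blocks, with
  per-block (not cumulative) micro scores.
- Value-range constraints are closed intervals; domain checks parse the
  first number in the candidate surface.
- Empty documents are a hard error; empty vocabularies are valid and empty;
  ambiguous synonyms (one surface under two canonicals) are a load error
  rather than last-writer-wins, because silent misnormalization is worse
  than a loud failure.
- Evaluation compares normalized canonical value sets, not character spans —
  extraction quality is judged at the clinical-finding level.

## Known limitations

Negation/uncertainty scope is window-based, not syntactic; post-posed
triggers are missed. The bundled tagger is intentionally small. Rule
induction can only reject, never force-accept. The HMM's unseen-token
emission reserve slightly favors B/I for out-of-vocabulary tokens inside
selected sentences, which is what lets it propose genuinely new values but
can also propose noise early in a session — the interactive loop exists
precisely to correct those cheaply.
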