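# Methods

This note documents the model behind `radex`: how queries are compiled and
evaluated, the preprocessing and negation conventions, what the synthetic
corpus generator does and does not emulate, and the design choices made
where more than one reading was defensible.

## Query model and compilation

A search expression parses to a small AST: keyword terms (with `*` = zero
or more word characters, `?` = zero or one), proximity nodes, boolean
connectives, and quoted references to earlier class labels. Precedence is
NOT > AND > OR; proximity binds tighter than NOT (it is part of a
term-level pattern); `EXCEPT` desugars to `AND NOT` at parse time so the
evaluator never sees it. Adjacent bare words form an exact-adjacency
phrase — strategies routinely use multiword operands
("thyroglossal cyst") with no operator, so this is the natural reading.
Double quotes are reserved for class references. Proximity operands are
restricted to terms (not arbitrary subtrees): only term-level proximity
compiles to a single regular expression, and chained `a~1b~2c` is rejected
rather than silently grouped.

Compilation: each atom becomes `\b…\b` with `*` → `\w*` and `?` → `\w?`;
phrase atoms are joined by exactly one non-word-character run (`\W+`).
`?` means zero-**or**-one rather than exactly-one so that `h?emoglobin`
covers both British and American spellings; the side effect is that
`wom?n` also matches the typo "womn", which is accepted and tested.
`THEN/X` compiles to `left(?:\W+\w+){0,X}?\W+right` — 0..X intervening
words, with a lazy quantifier so highlighted spans are minimal — and
`NEAR/X` is the alternation of both orders. Word characters are the regex
`\w` class; hyphen and slash are separators, so after punctuation
standardisation clinical compounds like `u2/u3` behave as two words and
patterns like `u2~1?3` (at most one word between `u2` and a `?3`-shaped
token) match them predictably.

Evaluation is recursive. Term and proximity leaves match within single
sentences (proximity never crosses a sentence boundary). AND combines
evidence at **section scope** by default — its operands may match in
different sentences, which is needed for concept-level conjunctions such
as "surgery mentioned anywhere, except near 'referred'" — and can be
switched to sentence scope. NOT contributes presence only, never spans. A
span filter hook lets the engine drop negated matches at the leaves, so a
class whose only mention is negated is absent, inside exclusions as well
as positive branches.

## Preprocessing

Reports are split at configured literal headers (case-insensitive,
optional colon); text before the first header is section `body`, and a
class whose configured section is missing falls back to `body` so
unstructured reports still classify. Standardisation lowercases, maps
punctuation (including `/ - ( )`) to spaces, preserves decimal points
inside numbers, collapses whitespace, and splits sentences at `. ! ?` and
blank lines with an abbreviation guard (single-letter tokens and
measurement units). Every standardised character keeps its raw-text
offset, so all evidence spans are reported in raw coordinates (0-based,
half-open) and highlighting never drifts.

Stopword removal is **off by default**: proximity gaps count intervening
words, and "thyroid contains multiple nodules" is a NEAR/2 hit only
because "contains" counts — silently stripping stopwords would change
proximity semantics. The flag remains available; when on, gaps count the
surviving tokens, and negation cues (no, not, without…) are never treated
as stopwords. Which behaviour the original workflow used is not
documented; the default here is a choice, not a claim.

## Negation

Negation follows the NegEx scheme: pre-triggers within a bounded token
window before the match, post-triggers after it, pseudo-triggers that
never negate, and scope terminators (`but`, `however`, …). The default
scope is 5 tokens, the classic NegEx convention. The packaged lexicon
(`data/negex_triggers.txt`, editable plain text) is seeded with the
standard NegEx trigger set. Where several triggers could apply, the
longest wins ("no abnormal" over "no"). Hypothetical/uncertain phrasings
(`possible`, `query`, `cannot be excluded`) are deliberately *not*
negation: they flag a match for review without suppressing it, mirroring
how hedged sentences behave as a false-positive mode rather than a
negation mode.

Negation applies per class. The packaged strategy disables it for the two
examination-performed classes (thyroid examination, lymph node
examination): "no abnormal cervical lymph nodes" negates the finding but
still proves the nodes were examined. All finding classes keep it on. For
such negation-off classes, a negated mention may legitimately be the sole
evidence for a positive label; the negation verdict is still recorded and
highlighted.

## Engine

Non-derived classes are evaluated over their configured sections; derived
classes (solitary nodule, normal thyroid) are boolean logic over earlier
labels, written in the same query grammar with quoted class references —
one grammar, one evaluator. Post-processing rules fire last, in file
order; because a fired rule can change a derived class's inputs, derived
classes are re-evaluated and rules re-applied until labels stabilise,
asserted to happen within two passes. The packaged rules are the grading
implications (U2–U5 ⇒ nodule) plus multiple-nodules ⇒ nodule(s), which the
class definitions entail but the nodule query alone does not (an
MNG-only report would otherwise be labelled multiple-but-not-nodule).
Rule-forced labels carry their rule as provenance instead of a text span.

Evidence records every positive-polarity leaf match with its section, raw
span, and negation verdict — including matches for leaves whose enclosing
conjunction failed, since those are exactly what one inspects when
refining a strategy. Highlighting renders one colour per class over merged
spans with negation cues marked distinctly, and stripping the markup
reproduces the raw text byte-for-byte.

## Strategy transcription notes

The packaged `thyroid_us.yaml` carries query strings whose printed source
is typographically inconsistent; each normalisation is commented in the
file: spacing normalised to `u2~1?3` (intended to catch `u2/u3` and
"u2 or 3" after standardisation); the class name unified to
"Thyroid nodule(s)"; the `~2` gaps of the plural cyst exclusions kept as
printed even though the singular row uses `~1`. The proximity gap for
NEAR/X is 0..X intervening words (the displayed `{0,3}` variant for a
NEAR/2 example is treated as a typo for `{0,2}`). Previous-surgery
searches include the clinical history section in addition to the report
body; all other primary classes search the body/findings sections.

## Synthetic corpus generator

The generator composes reports from section skeletons and phrase banks:
an examination base, solitary/multiple nodule findings with BTA grading
sentences, goitre and echotexture findings, surgery history, lymph-node
comments, distractors (parotid/salivary/thyroglossal cysts, cervical
nodes), and keyword-free filler sentences to reach a target length. Every
report carries a full 14-class ground-truth vector that satisfies the
derived-class identities and post-rules by construction. Defaults: mean
report length 93 words (the study-corpus mean), negation on ~30% of
normal-scenario nodule mentions, 15% distractor-only neck examinations,
5% ambiguous templates, metadata (2015–2019 exam dates, ages 18–90,
UNECK/UTHYD/UTHPY codes) matching the study population. Rates without a
documented value are set to what a mixed thyroid referral stream
plausibly produces and are configurable.

Ambiguous templates are the generator's deliberate failure modes: hedged
enlargement wording ("the thyroid gland appears slightly enlarged", a
literal `enlarged~2gland` hit that reference readers call normal) and
hypothetical findings. Their ground truth records the *reference* reading,
so they surface as false positives in evaluation and discrepancy review;
the deterministic 100%-agreement property is defined over the unambiguous
remainder. Typo noise is confined to keyword-free filler so it can never
flip a label.

What the generator does **not** emulate: reporter-to-reporter style
variation beyond phrase-bank sampling, out-of-vocabulary synonyms,
misspelled keywords, truly novel negation constructions, or institutional
header conventions beyond clinical history/findings. A perfect score on
the synthetic corpus therefore demonstrates that the engine implements
the strategy's semantics exactly — not that the packaged strategy would
achieve the same figures on real hospital reports, where missing keywords
and semantic context errors dominate.

## Metrics

Per-class metrics come from 2×2 counts: precision TP/(TP+FP), sensitivity
TP/(TP+FN), specificity TN/(TN+FP), F1 computed as 2TP/(2TP+FP+FN).
Micro averages apply the same formulas to summed counts (asserted as an
identity in the tests); macro averages are unweighted class means.
Undefined ratios (0/0) are reported as NaN with a warning and excluded
from macro averages — coercing them to 0 or 1 would silently bias the
average. Hamming loss is the fraction of wrong (report, class) cells;
exact match ratio the fraction of reports with all labels correct;
cardinality and label density are computed on the reference matrix.
Cohen's kappa uses the two-rater marginal chance-agreement form and is
undefined (NaN, with a warning) when both raters are constant. Class
groups let the nine main classes be scored separately from the five BTA
gradings, since pooling the rarely-positive gradings into the micro
average is a reporting choice, not a fact of the data. All metrics are
cross-checked against scikit-learn to 1e-12 in the test suite;
scikit-learn is used only as the independent oracle, never as the
implementation.

## Problem sizes and determinism

The test suite uses 1,000-case generated suites for the parser and
evaluator properties, a 200-report corpus for the end-to-end agreement
check, and a 10,000-report corpus for the scalability exercise (runtime
is logged, not asserted; ~3 ms/report in development). The acceptance
script uses a 2,000-report corpus. Every random draw — corpus generation,
random queries, random label matrices — is seeded, and the generator is a
pure function of its seed, so identical seeds yield byte-identical
corpora and identical outputs.

## Known limitations

Proximity cannot be applied to boolean subexpressions; `?` cannot be made
exactly-one per-pattern; negation scope is token-count based, not
syntactic; sentence splitting is rule-based and will merge sentences
after unit abbreviations ("… 4 cm. The left lobe …"); uncertainty is
flagged but not quantified; and the strategy language has no ontology
expansion — synonyms must be enumerated by the strategy author.
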