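"""Negation detection on clinical phrasings.

Runs the NegEx-style detector over matches of a nodule query: a finding
mention is suppressed when a negation trigger lies within a five-token
scope, pseudo-triggers never negate, and uncertainty cues flag a match for
review without suppressing it.
"""

from radex import default_lexicon, detect_negation, evaluate, parse_query

lexicon = default_lexicon()
query = parse_query("thyroid nodule? | nodul* | lymph node?")

SENTENCES = (
    "there are no thyroid nodules",           # pre-trigger 'no'
    "thyroid nodules were not observed",      # post-trigger
    "no abnormal lymph nodes",                # longest trigger wins
    "no change in the thyroid nodule",        # pseudo-trigger: NOT negated
    "a malignant nodule cannot be excluded",  # uncertainty, not negation
    "no cysts but a nodule is seen",          # 'but' terminates the scope
)

for sentence in SENTENCES:
    _, spans = evaluate(query, sentence)
    for verdict in detect_negation(sentence, spans, lexicon):
        state = "NEGATED " if verdict.negated else \
                ("uncertain" if verdict.uncertain else "asserted")
        trig = f" (trigger: {verdict.trigger!r})" if verdict.trigger else ""
        print(f"  {state:9} {verdict.span.text!r:20} in {sentence!r}{trig}")

# Negated matches are excluded from a class's positive evidence; uncertain
# ones count but carry a review flag.
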