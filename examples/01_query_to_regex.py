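"""From a high-level search expression to regular expressions and matches.

Parses a query written in the search-strategy syntax, shows the compiled
word-boundary regular expressions for each keyword leaf, and evaluates the
query against a few sentences.
"""

from radex import evaluate, parse_query, query_regex, to_string

QUERY = "thyroid NEAR/2 *nodul* OR (node? EXCEPT lymph node?)"

node = parse_query(QUERY)
print("query:   ", QUERY)
print("parsed:  ", to_string(node))
print("\ncompiled leaf patterns:")
print(query_regex(node))

print("\nevaluation (presence + character spans of the evidence):")
for sentence in (
    "thyroid contains multiple nodules",
    "multinodular thyroid",
    "a node is seen in level iv",        # node without 'lymph' -> positive
    "lymph nodes are normal",            # excluded by EXCEPT -> negative
    "thyroid gland with three nodules",  # 3 intervening words > NEAR/2
):
    present, spans = evaluate(node, sentence)
    marks = ", ".join(f"[{s.start}:{s.end}]={s.text!r}" for s in spans) or "-"
    print(f"  {present!s:5}  {sentence!r}  {marks}")

# The presence flag drives classification; the spans drive highlighting.
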