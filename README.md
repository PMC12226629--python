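# radex

Rule-based information extraction and multi-label classification for
free-text clinical reports, demonstrated on thyroid/neck ultrasound.

Radiology reports bury findings in unstructured prose. Researchers and
clinicians running audits, building cohorts, or labelling imaging datasets
need those findings as structured columns — without a labelled training
set, specialist NLP expertise, or opaque models. `radex` lets a domain
expert write a **search strategy** in a high-level query syntax (in the
spirit of PubMed/Ovid advanced search), compiles it to word-boundary-aware
regular expressions, and applies it to a corpus with sectioning, text
standardisation, NegEx-style negation detection, derived-class logic, and
span-level evidence for every decision.

## The query language

| Construct | Meaning |
|---|---|
| `thyr*` | `*` = any run of word characters → `\bthyr\w*\b` (thyroid, thyroidectomy, thyroiditis…) |
| `wom?n` | `?` = zero or one word character (woman, women) |
| `a NEAR/2 b` (`a~2b`) | a and b in either order with ≤ 2 intervening words |
| `a THEN/2 b` | same, but a before b |
| `AND` `OR` `NOT` `EXCEPT` (`&` `\|` `¬`) | boolean connectives, precedence NOT > AND > OR; `EXCEPT` ≡ `AND NOT` |
| `"Class name"` | derived class: boolean logic over earlier labels |

`thyroid NEAR/2 nodules OR multinodular` compiles to
`\bthyroid\b(?:\W+\w+){0,2}?\W+\bnodules\b` (both orders) alternated with
`\bmultinodular\b` — but reads like the clinical concept it encodes.

A strategy is an ordered YAML list of named classes, each with a query and
target report sections, plus post-processing implications (e.g. *a BTA
U2–U5 grading implies a thyroid nodule*). The packaged
`thyroid_us.yaml` classifies 14 findings: thyroid/lymph-node examination,
thyroid nodule(s), multiple/solitary nodules, altered echotexture, goitre,
previous surgery, BTA U1–U5 gradings, and normal thyroid (derived as
examination with no abnormality).

A match is suppressed when a negation trigger (`no`, `without`,
`not seen`, …) falls within a five-token scope without an intervening
terminator (`but`, `however`); pseudo-triggers (`no change`) never negate,
and uncertainty cues (`possible`, `cannot be excluded`) flag a match for
review without suppressing it.

## Worked example

```bash
python examples/03_classify_reports.py
```

classifies the eight packaged demo reports and prints the label matrix:

```
id                           D001  D002  D003  D004  D005  D006  D007  D008
Thyroid examination             1     1     1     1     1     1     1     1
Lymph node examination          1     0     1     0     1     0     0     0
Thyroid nodule(s)               0     1     1     0     0     0     1     0
Multiple thyroid nodules        0     0     1     0     0     0     0     0
Altered thyroid echotexture     0     0     0     1     0     0     0     1
Goitre                          0     0     1     0     0     0     0     1
Previous thyroid surgery        0     0     0     0     1     0     0     0
BTA U3                          0     1     0     0     0     0     0     0
Solitary thyroid nodule         0     1     0     0     0     0     1     0
Normal thyroid                  1     0     0     0     0     1     0     0
```

(rows for U1/U2/U4/U5 are all zero here). Reading the columns: D001 is a
normal examination — "There are no thyroid nodules" is matched but negated,
so the nodule class stays false and the derived *Normal thyroid* label
fires. D002 carries a solitary nodule graded U3; its evidence spans are
`'nodule'` at characters 97–103 and `'u3'` at 146–148 of the raw text, so
a reviewer can audit the decision in place. D006 has a parotid cyst: the
exclusion window `cyst*~2parotid` keeps it out of the thyroid-nodule class.
D007's hedged `u2/u3` grading asserts *no* single BTA grade, by the
strategy's own exclusion terms.

The other example scripts show the query-to-regex compilation
(`01_query_to_regex.py`), negation verdicts on clinical phrasings
(`02_negation.py`), and a full evaluation — per-class and micro/macro
precision, sensitivity, specificity, F1, Hamming loss, exact match ratio,
cardinality, label density, Cohen's kappa — of the packaged strategy
against the synthetic generator's ground truth (`04_evaluate_strategy.py`).

The same pipeline is available from the shell:

```bash
radex synth --n 200 --seed 7 --out corpus.csv --labels ref.csv
radex run   --strategy src/radex/data/thyroid_us.yaml \
            --input corpus.csv --output labels.csv --highlight html/
radex eval  --pred labels.csv --ref ref.csv --out metrics.json
radex review --pred labels.csv --ref ref.csv --out discrepancies.csv
```

`run` writes one boolean column per class plus a JSON evidence column, and
a provenance header with the strategy file's SHA-256; `review` lists every
false positive (with the offending spans) and false negative for the
iterative refine-and-re-run loop.

## Synthetic corpus

Real thyroid ultrasound reports cannot be redistributed, so
`radex.synth` generates labelled reports from a template grammar:
sectioned skeletons (clinical history / findings), phrase banks for each
finding with negated and hypothetical variants, distractors (parotid and
salivary cysts, thyroglossal cysts, cervical lymph nodes), British
spellings, the MNG abbreviation, BTA grading tokens including the
ambiguous `u2/u3`, and typo noise — with a complete ground-truth label
vector per report, consistent with the derived-class and post-rule logic
by construction. Deliberately ambiguous templates (hedged "appears
slightly enlarged" phrasing, hypothetical findings) carry the reference
reader's label and are tagged, emulating the false-positive modes seen in
practice. See `docs/methods.md` for what this generator does and does not
emulate.

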