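# Search strategy for neck/thyroid ultrasound reports: 14 classes covering
# common diffuse and focal thyroid pathology plus British Thyroid
# Association (BTA) U1-U5 nodule gradings.
#
# Query syntax: '*' = any run of word characters, '?' = zero-or-one word
# character, '~X' = bidirectional proximity (NEAR/X, at most X intervening
# words), '&' = AND, '|' = OR, '¬' = NOT, double-quoted names reference an
# earlier class (derived classes).
#
# Transcription notes (normalisations of typographically corrupted source
# strings, documented in docs/methods.md):
#   - 'u2 ~ 1 ?3' and kin normalised to 'u2~1?3' (matches 'u2/u3' or
#     'u2 or 3' phrasings once punctuation is standardised: '?3' matches a
#     word like 'u3' or bare '3' at most one word after 'u2').
#   - class-name spelling unified to "Thyroid nodule(s)" (the source mixes
#     "Thyroid nodules(s)" and "Thyroid nodule(s)").
#   - the '~2' gaps of the sebaceous/inclusion/lymph/node cyst exclusions in
#     'Multiple thyroid nodules' are kept as printed even though the
#     singular row uses '~1' for the same exclusions.

name: thyroid_ultrasound
description: Multi-label classification of thyroid/neck ultrasound reports.

# Reports carry "Clinical history:" / "Findings:" headers; unheaded text is
# section 'body'. Classes search the report body and findings unless stated.
default_sections: [body, findings]

# The two examination classes record that an examination was performed, so
# a negated finding mention ("no abnormal lymph nodes") still counts as
# evidence the structure was examined: negation detection is disabled for
# them (per-class setting; all finding classes keep it on).
classes:
  - name: Thyroid examination
    query: 'thyroid*'
    negation: false

  - name: Lymph node examination
    query: 'lymph* | (node & ¬thyroid* node)'
    negation: false

  - name: Thyroid nodule(s)
    query: >-
      (nodul* & ¬(nodul*~2cartilage | nodul*~2parotid | nodule*~2salivary |
      nodul*~2submandibular)) | (cyst* & ¬(thyroglossal cyst | cyst*~2parotid |
      cyst*~2salivary | cyst*~2submandibular | cyst*~1sebaceous |
      cyst*~1inclusion | cyst*~1lymph* | cyst*~1node)) | thyroid~4lesion* |
      thyroid~1node* | adenoma

  - name: Multiple thyroid nodules
    query: >-
      (nodules & ¬(nodules~2cartilage | nodules~2parotid | nodules~2salivary |
      nodules~2submandibular)) | (cysts & ¬(thyroglossal cysts |
      cysts~2parotid | cysts~2salivary | cysts~2submandibular |
      cysts~2sebaceous | cysts~2inclusion | cysts~2lymph* | cysts~2node)) |
      thyroid~4lesions | thyroid~1nodes | multi?nodul* | nodul*~2both |
      other~2nodul* | second*~2nodul* | (superior~3nodul* & inferior~3nodul*) |
      (nodule*~3left & nodule*~3right) | (nodule*~3left & nodule*~3isthmus) |
      (nodule*~3right & nodule*~3isthmus) | mng

  - name: Altered thyroid echotexture
    query: >-
      thyroiditis | grav?s | heterogen*~2echo* | heterogen*~2thyroid |
      heterogen*~1texture | inflamed*

  - name: Goitre
    query: >-
      goit?r? | mng | multi?nodul* thyroid | enlarged~2thyroid |
      (enlarged~2gland & ¬enlarged~2parathy*) | enlarged~2lobe | hyperplasia

  # Previous surgery is also searched in the clinical history section.
  - name: Previous thyroid surgery
    sections: [clinical history, body, findings]
    query: >-
      thyroidectomy | lobectomy | isthmusectomy | (surgery & ¬refer*~2surgery)
      | resect* | incomplete~2thyroid | post?op | bed | hemiagenesis

  - name: BTA U1
    query: 'u1'
  - name: BTA U2
    query: 'u2 & ¬(u2?u3 | u2~1?3)'
  - name: BTA U3
    query: 'u3 & ¬(u3?u4 | u3~1?4 | u2?u3 | u2~1?3)'
  - name: BTA U4
    query: 'u4 & ¬(u4?u5 | u4~1?5 | u3?u4 | u3~1?4)'
  - name: BTA U5
    query: 'u5 & ¬(u4?u5 | u4~1?5)'

  # Derived classes: boolean logic over earlier labels, same query grammar.
  - name: Solitary thyroid nodule
    derived: true
    query: '"Thyroid nodule(s)" & ¬"Multiple thyroid nodules"'

  - name: Normal thyroid
    derived: true
    query: >-
      "Thyroid examination" & ¬("Thyroid nodule(s)" |
      "Altered thyroid echotexture" | "Goitre" | "Previous thyroid surgery")

# Consistency rules applied after classification: a U2-U5 grading implies a
# nodule was found, and multiple nodules (including MNG, which the
# nodule(s) query itself does not mention) imply the presence of nodules.
# Derived classes are re-evaluated after these fire.
post_processing:
  - {if: Multiple thyroid nodules, then: Thyroid nodule(s), set_to: true}
  - {if: BTA U2, then: Thyroid nodule(s), set_to: true}
  - {if: BTA U3, then: Thyroid nodule(s), set_to: true}
  - {if: BTA U4, then: Thyroid nodule(s), set_to: true}
  - {if: BTA U5, then: Thyroid nodule(s), set_to: true}

# Class groups for reporting: the nine main classes are aggregated
# separately from the five BTA gradings.
groups:
  main:
    - Thyroid examination
    - Lymph node examination
    - Thyroid nodule(s)
    - Multiple thyroid nodules
    - Solitary thyroid nodule
    - Altered thyroid echotexture
    - Goitre
    - Previous thyroid surgery
    - Normal thyroid
  bta:
    - BTA U1
    - BTA U2
    - BTA U3
    - BTA U4
    - BTA U5
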