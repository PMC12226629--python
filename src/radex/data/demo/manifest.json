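{
  "name": "thyroid_us_demo",
  "description": "Eight hand-written synthetic thyroid/neck ultrasound reports illustrating the packaged search strategy: normal examination, solitary graded nodule, multinodular goitre, thyroiditis, previous surgery, a parotid-cyst distractor, an ambiguous u2/u3 grading, and diffuse disease. All reports are synthetic; no patient data.",
  "files": {
    "corpus.csv": "reports: id, text, exam_date, age, exam_code",
    "reference_labels.csv": "reference-standard labels: id plus one boolean column per class"
  },
  "n_reports": 8,
  "strategy": "thyroid_us.yaml",
  "classes": 14
}
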