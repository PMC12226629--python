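"""Seeded template-grammar generator of labelled synthetic ultrasound reports.

Builds neck/thyroid ultrasound reports from section skeletons and phrase
banks, emitting for every report a complete ground-truth vector over the
14 classes of the packaged strategy, consistent by construction with the
derived-class logic (solitary = nodule and not multiple; normal = examined
and no abnormality) and the grading post-rules (a U2-U5 grading implies a
nodule).

Phrase banks cover positive findings, negated findings, hypothetical
phrasings, and distractors (parotid/salivary/thyroglossal cysts, cervical
lymph nodes) that exercise the strategy's exclusion windows. Noise comes
from phrase-variant sampling, pluralisation and British-spelling variants,
the MNG abbreviation, BTA grading tokens ('u1'..'u5', the ambiguous
'u2/u3'), and harmless typos in filler sentences. Templates whose correct
label is genuinely debatable (the known failure modes: hedged goitre
wording, hypothetical findings) are tagged ``ambiguous`` and carry the
reference reader's label rather than the literal one, so they surface as
realistic false positives; the deterministic agreement subset excludes
them.

Everything is a pure function of the seed: the same seed yields a
byte-identical corpus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .preprocess import Report

__all__ = ["CLASSES", "SynthConfig", "generate_corpus", "labels_frame"]

CLASSES = (
    "Thyroid examination",
    "Lymph node examination",
    "Thyroid nodule(s)",
    "Multiple thyroid nodules",
    "Altered thyroid echotexture",
    "Goitre",
    "Previous thyroid surgery",
    "BTA U1",
    "BTA U2",
    "BTA U3",
    "BTA U4",
    "BTA U5",
    "Solitary thyroid nodule",
    "Normal thyroid",
)


@dataclass
class SynthConfig:
    """Generation rates and sizes.

    Defaults emulate the study conditions of a mixed thyroid/neck referral
    stream: mean report length ~93 words, frequent negated findings,
    occasional distractor-only neck examinations, and a small fraction of
    deliberately ambiguous phrasings.
    """

    mean_words: int = 93
    sd_words: int = 18
    negation_rate: float = 0.30      # chance a nodule mention is negated
    distractor_rate: float = 0.15    # chance of a distractor-only report
    ambiguous_rate: float = 0.05     # chance of an ambiguous template
    lymph_rate: float = 0.55         # chance lymph nodes are commented on
    grade_rate: float = 0.7          # chance a nodule gets a BTA grading
    surgery_rate: float = 0.12
    force_solitary: bool = False
    force_multiple: bool = False

    def validate(self) -> None:
        if self.force_solitary and self.force_multiple:
            raise ValueError("cannot force both a solitary and multiple nodules")
        for name in ("negation_rate", "distractor_rate", "ambiguous_rate",
                     "lymph_rate", "grade_rate", "surgery_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_words < 20:
            raise ValueError("mean_words must be >= 20")


@dataclass
class _Block:
    """A template fragment: sentences per section plus label implications."""

    history: tuple[str, ...] = ()
    findings: tuple[str, ...] = ()
    labels: dict = field(default_factory=dict)  # class -> True
    ambiguous: bool = False


# --------------------------------------------------------------------------- #
# Phrase banks. Every phrase is crafted to fall clearly inside or outside
# the packaged strategy's term and proximity windows, so the implied labels
# are deterministic — except blocks tagged ambiguous.
# --------------------------------------------------------------------------- #

_EXAM_BASE = (
    "The thyroid gland is normal in size.",
    "The thyroid has been examined with a high frequency linear probe.",
    "Ultrasound assessment of the thyroid was performed.",
    "The thyroid appears normal in size and echotexture.",
)

_SOLITARY = (
    "There is a solitary nodule in the {side} lobe measuring {size} mm.",
    "A single well defined nodule is demonstrated in the {side} lobe.",
    "One {size} mm colloid nodule is present within the {side} lobe.",
)

_MULTIPLE = (
    "Multiple nodules are demonstrated throughout the gland.",
    "Several discrete nodules are present in each lobe.",
    "The gland contains multiple small colloid nodules.",
    "Appearances are those of a multinodular goitre.",   # also goitre (MNG)
    "Appearances are in keeping with mng.",              # also goitre (MNG)
)
# phrases 0-2 imply multiple nodules only; 3-4 additionally imply goitre
_MULTIPLE_GOITRE_FROM = 3

_NEGATED_NODULE = (
    "There are no thyroid nodules.",
    "No focal nodule is seen within the gland.",
    "No discrete nodules are identified.",
    "No cysts or nodules are demonstrated.",
)

_GOITRE = (
    "There is a diffuse goitre.",
    "Appearances are consistent with a simple goitre.",
    "The thyroid is enlarged.",
    "The gland is diffusely enlarged.",
)

_ECHOTEXTURE = (
    "Appearances are in keeping with thyroiditis.",
    "The gland is diffusely heterogeneous in echotexture.",
    "Heterogeneous thyroid parenchyma consistent with autoimmune disease.",
    "The parenchyma shows a heterogeneous texture.",
)

_SURGERY_HISTORY = (
    "Previous total thyroidectomy.",
    "Prior {side} lobectomy, surveillance scan.",
    "Previous thyroid surgery for benign disease.",
    "Previous {side} lobectomy.",
)

_LYMPH_NORMAL = (
    "No abnormal cervical lymph nodes.",
    "Cervical lymph nodes are of normal morphology.",
    "No cervical lymphadenopathy.",
    "Normal appearance of the cervical lymph node chains.",
)

_GRADE = "The nodule is graded {grade} by BTA criteria."
_GRADE_U1 = "The gland is graded u1 by BTA criteria."
_GRADE_AMBIG = "Graded u2/u3 by BTA criteria."

_DISTRACTOR_FINDINGS = (
    "A small {side} parotid cyst is noted.",
    "There is a simple {side} parotid cyst.",
    "A benign appearing salivary cyst is seen in the submandibular region.",
    "Appearances are consistent with a thyroglossal cyst.",
)

_DISTRACTOR_HISTORY = (
    "Lump in the {side} side of the neck.",
    "Palpable neck swelling.",
    "Neck discomfort, query cause.",
)

_HISTORY_GENERIC = (
    "Palpable neck lump.",
    "Swelling in the anterior neck.",
    "Routine surveillance.",
    "Hoarse voice, referred by GP.",
    "Difficulty swallowing.",
)

# Ambiguous templates: the known false-positive modes — hedged enlargement
# wording (a literal 'gland ... enlarged' proximity hit that reference
# readers call normal) and hypothetical phrasing (uncertainty is flagged
# but not suppressed). Their ground truth records the REFERENCE reading
# (finding not asserted), so the tool's literal match disagrees by design;
# they are excluded from the deterministic agreement subset and surface as
# false positives in evaluation and discrepancy review.
_AMBIGUOUS = (
    _Block(findings=("The thyroid gland appears slightly enlarged.",),
           ambiguous=True),
    _Block(findings=("Appearances may represent early thyroiditis.",),
           ambiguous=True),
    _Block(findings=("Possible tiny nodule in the isthmus, of doubtful significance.",),
           ambiguous=True),
)

# Filler sentences: free of every strategy keyword; typo noise is confined
# to these so it can never flip a label.
_FILLER = (
    "The {side} lobe measures {d1} x {d2} x {d3} cm.",
    "The isthmus is unremarkable.",
    "Normal vascularity on colour doppler.",
    "The trachea is central.",
    "The carotid arteries and jugular veins appear patent.",
    "The submandibular and parotid salivary tissue is unremarkable elsewhere.",
    "Comparison was made with the previous examination.",
    "The appearances are stable in the interval.",
    "The parathyroid regions are unremarkable.",
    "No retrosternal extension.",
    "The overlying soft tissues are within normal limits.",
    "The patient tolerated the examination well.",
)
# fillers safe to corrupt with a typo (no keyword fragments at all)
_TYPO_SAFE = (1, 3, 6, 7, 11)

_SIDES = ("left", "right")


def _fill(rng: random.Random, template: str) -> str:
    return template.format(
        side=rng.choice(_SIDES),
        size=rng.randint(4, 35),
        grade="",  # overwritten where used
        d1=f"{rng.uniform(2.5, 6.0):.1f}",
        d2=f"{rng.uniform(1.0, 3.0):.1f}",
        d3=f"{rng.uniform(1.0, 3.0):.1f}",
    )


def _typo(rng: random.Random, sentence: str) -> str:
    words = sentence.split()
    idx = [i for i, w in enumerate(words) if len(w) > 6 and w.isalpha()]
    if not idx:
        return sentence
    i = rng.choice(idx)
    w = words[i]
    j = rng.randrange(1, len(w) - 2)
    words[i] = w[:j] + w[j + 1] + w[j] + w[j + 2:]  # swap two inner letters
    return " ".join(words)


def _build_blocks(rng: random.Random, cfg: SynthConfig) -> list[_Block]:
    if rng.random() < cfg.distractor_rate and not (cfg.force_solitary or
                                                   cfg.force_multiple):
        blocks = [_Block(history=(rng.choice(_DISTRACTOR_HISTORY),),
                         findings=(rng.choice(_DISTRACTOR_FINDINGS),))]
        if rng.random() < cfg.lymph_rate:
            blocks.append(_Block(findings=(rng.choice(_LYMPH_NORMAL),),
                                 labels={"Lymph node examination": True}))
        return blocks

    blocks = [_Block(history=(rng.choice(_HISTORY_GENERIC),),
                     findings=(rng.choice(_EXAM_BASE),),
                     labels={"Thyroid examination": True})]

    if rng.random() < cfg.ambiguous_rate:
        blocks.append(rng.choice(_AMBIGUOUS))
        return blocks

    if cfg.force_solitary:
        scenario = "solitary"
    elif cfg.force_multiple:
        scenario = "multiple"
    else:
        scenario = rng.choices(
            ("normal", "solitary", "multiple", "goitre", "echotexture"),
            weights=(0.34, 0.22, 0.22, 0.11, 0.11))[0]

    if scenario == "solitary":
        blocks.append(_Block(findings=(rng.choice(_SOLITARY),),
                             labels={"Thyroid nodule(s)": True}))
        if rng.random() < cfg.grade_rate:
            if rng.random() < 0.15:
                # ambiguous-grading token: excluded from every single grade
                blocks.append(_Block(findings=(_GRADE_AMBIG,)))
            else:
                grade = rng.choice(("u2", "u3", "u4", "u5"))
                blocks.append(_Block(
                    findings=(_GRADE.format(grade=grade),),
                    labels={f"BTA {grade.upper()}": True}))
    elif scenario == "multiple":
        k = rng.randrange(len(_MULTIPLE))
        labels = {"Thyroid nodule(s)": True, "Multiple thyroid nodules": True}
        if k >= _MULTIPLE_GOITRE_FROM:
            labels["Goitre"] = True
        blocks.append(_Block(findings=(_MULTIPLE[k],), labels=labels))
    elif scenario == "goitre":
        blocks.append(_Block(findings=(rng.choice(_GOITRE),),
                             labels={"Goitre": True}))
    elif scenario == "echotexture":
        blocks.append(_Block(findings=(rng.choice(_ECHOTEXTURE),),
                             labels={"Altered thyroid echotexture": True}))
    else:  # normal: often an explicitly negated finding, sometimes a U1 grade
        if rng.random() < cfg.negation_rate:
            blocks.append(_Block(findings=(rng.choice(_NEGATED_NODULE),)))
        if rng.random() < 0.3:
            blocks.append(_Block(findings=(_GRADE_U1,),
                                 labels={"BTA U1": True}))

    if rng.random() < cfg.surgery_rate:
        blocks.append(_Block(history=(rng.choice(_SURGERY_HISTORY),),
                             labels={"Previous thyroid surgery": True}))
    if rng.random() < cfg.lymph_rate:
        blocks.append(_Block(findings=(rng.choice(_LYMPH_NORMAL),),
                             labels={"Lymph node examination": True}))
    return blocks


def _derive(labels: dict[str, bool]) -> dict[str, bool]:
    """Close a primary label set under the derived-class and post-rule logic."""
    out = {c: bool(labels.get(c, False)) for c in CLASSES}
    if any(out[f"BTA U{g}"] for g in (2, 3, 4, 5)):
        out["Thyroid nodule(s)"] = True
    if out["Multiple thyroid nodules"]:
        out["Thyroid nodule(s)"] = True
    out["Solitary thyroid nodule"] = (out["Thyroid nodule(s)"]
                                      and not out["Multiple thyroid nodules"])
    out["Normal thyroid"] = (out["Thyroid examination"]
                             and not (out["Thyroid nodule(s)"]
                                      or out["Altered thyroid echotexture"]
                                      or out["Goitre"]
                                      or out["Previous thyroid surgery"]))
    return out


def generate_corpus(n: int, seed: int,
                    config: Optional[SynthConfig] = None
                    ) -> tuple[list[Report], pd.DataFrame]:
    """Generate ``n`` labelled synthetic reports.

    Returns the reports and a ground-truth table with one boolean column
    per class plus an ``ambiguous`` flag marking templates excluded from
    the deterministic agreement subset. Deterministic for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    cfg = config or SynthConfig()
    cfg.validate()
    rng = random.Random(seed)

    reports: list[Report] = []
    rows: list[dict] = []
    for k in range(n):
        blocks = _build_blocks(rng, cfg)
        history = [_fill(rng, s) for b in blocks for s in b.history]
        findings = [_fill(rng, s) for b in blocks for s in b.findings]
        labels: dict[str, bool] = {}
        ambiguous = False
        for b in blocks:
            ambiguous |= b.ambiguous
            for cls, v in b.labels.items():
                labels[cls] = labels.get(cls, False) or v
        labels = _derive(labels)

        target = max(30, int(rng.gauss(cfg.mean_words, cfg.sd_words)))
        n_words = sum(len(s.split()) for s in history + findings)
        fillers = list(_FILLER)
        order = rng.sample(range(len(fillers)), len(fillers))
        for i in order:
            if n_words >= target:
                break
            sentence = _fill(rng, fillers[i])
            if i in _TYPO_SAFE and rng.random() < 0.1:
                sentence = _typo(rng, sentence)
            findings.append(sentence)
            n_words += len(sentence.split())

        text = ("Clinical history: " + " ".join(history) + "\n\n"
                "Findings: " + " ".join(findings))
        rid = f"SYN{seed:04d}-{k:05d}"
        meta = {
            "exam_date": f"{rng.randint(2015, 2019)}-{rng.randint(1, 12):02d}-"
                         f"{rng.randint(1, 28):02d}",
            "age": rng.randint(18, 90),
            "exam_code": rng.choice(("UNECK", "UTHYD", "UTHPY")),
        }
        reports.append(Report(id=rid, text=text, metadata=meta))
        rows.append({"id": rid, **labels, "ambiguous": ambiguous})

    columns = ["id", *CLASSES, "ambiguous"]
    truth = pd.DataFrame(rows, columns=columns) if rows else \
        pd.DataFrame(columns=columns)
    return reports, truth


def labels_frame(truth: pd.DataFrame) -> pd.DataFrame:
    """The ground-truth table without the ``ambiguous`` bookkeeping column."""
    return truth[["id", *CLASSES]].copy()
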