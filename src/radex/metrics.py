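"""Multi-label evaluation metrics.

Label-based metrics (precision, sensitivity/recall, specificity, F1,
accuracy) are computed per class from 2x2 confusion counts, then averaged
two ways: micro (pool the counts across classes first) and macro
(unweighted mean of per-class values). Example-based metrics summarise
whole-report correctness: Hamming loss is the fraction of all
(report, class) labels predicted wrongly, and the exact match ratio is the
fraction of reports with every label correct. Dataset statistics follow the
usual multi-label definitions: cardinality is the mean number of positive
labels per report, label density is cardinality divided by the number of
classes. Cohen's kappa measures inter-annotator agreement corrected for
chance.

Ratios with a zero denominator are undefined: they are reported as NaN with
a warning, never silently coerced to 0 or 1, because coercion biases
macro-averages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "label_metrics",
    "multilabel_metrics",
    "cohens_kappa",
]

LabelFrame = Union[pd.DataFrame, Mapping[str, Mapping[str, bool]]]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class 2x2 counts; TP+FP+FN+TN equals the number of reports."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class MetricsReport:
    """All label-based and example-based multi-label metrics."""

    per_class: pd.DataFrame          # rows: classes; cols: counts + metrics
    micro: dict[str, float]          # metrics from pooled counts
    macro: dict[str, float]          # unweighted means of per-class metrics
    hamming_loss: float
    exact_match_ratio: float
    cardinality: float               # mean positive labels/report (reference)
    label_density: float             # cardinality / n_classes
    n_reports: int
    classes: list[str]
    kappa: Optional[dict[str, float]] = None


def _as_frame(labels: LabelFrame) -> pd.DataFrame:
    if isinstance(labels, pd.DataFrame):
        df = labels.copy()
        if "id" in df.columns:
            df = df.set_index("id")
        return df.astype(bool)
    return pd.DataFrame.from_dict(labels, orient="index").astype(bool)


def _align(predictions: LabelFrame, reference: LabelFrame,
           classes: Optional[Sequence[str]] = None
           ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    pred = _as_frame(predictions)
    ref = _as_frame(reference)
    missing = sorted(set(ref.index).symmetric_difference(pred.index))
    if missing:
        raise ValueError(f"report ids do not match; unpaired ids: {missing[:10]}")
    if classes is None:
        classes = [c for c in pred.columns if c in set(ref.columns)]
        if not classes:
            raise ValueError("prediction and reference share no classes")
    else:
        classes = list(classes)
        for c in classes:
            if c not in pred.columns or c not in ref.columns:
                raise ValueError(f"class {c!r} missing from predictions or reference")
    ref = ref.loc[pred.index]
    return pred[classes], ref[classes], classes


def confusion(predictions: LabelFrame, reference: LabelFrame,
              classes: Optional[Sequence[str]] = None) -> dict[str, ConfusionCounts]:
    """Per-class TP/FP/FN/TN counts over aligned label tables.

    Tables may be DataFrames (one boolean column per class, ids as index or
    an ``id`` column) or nested mappings ``id -> class -> bool``. An id
    present on only one side is an error.
    """
    pred, ref, classes = _align(predictions, reference, classes)
    out: dict[str, ConfusionCounts] = {}
    for c in classes:
        p = pred[c].to_numpy()
        r = ref[c].to_numpy()
        out[c] = ConfusionCounts(
            tp=int((p & r).sum()),
            fp=int((p & ~r).sum()),
            fn=int((~p & r).sum()),
            tn=int((~p & ~r).sum()),
        )
    return out


def _ratio(num: int, den: int, name: str, context: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined for {context} (0/0); reported as NaN",
                      stacklevel=3)
        return math.nan
    return num / den


def label_metrics(counts: ConfusionCounts, *, context: str = "class") -> dict[str, float]:
    """Precision, sensitivity, specificity, F1 and accuracy from 2x2 counts.

    F1 is the harmonic mean of precision and sensitivity, computed directly
    as 2TP / (2TP + FP + FN) so it stays defined whenever any of TP, FP, FN
    is non-zero.
    """
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision", context)
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity", context)
    specificity = _ratio(counts.tn, counts.tn + counts.fp, "specificity", context)
    f1 = _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, "F1", context)
    accuracy = _ratio(counts.tp + counts.tn, counts.total, "accuracy", context)
    return {"precision": precision, "sensitivity": sensitivity,
            "specificity": specificity, "f1": f1, "accuracy": accuracy}


def multilabel_metrics(predictions: LabelFrame, reference: LabelFrame,
                       classes: Optional[Sequence[str]] = None) -> MetricsReport:
    """Full multi-label evaluation of predictions against a reference.

    ``classes`` restricts the evaluation to a class group (e.g. the nine
    main findings without the BTA gradings). Macro averages skip undefined
    (NaN) per-class values with a warning; micro averages are
    :func:`label_metrics` applied to the summed counts.
    """
    pred, ref, classes = _align(predictions, reference, classes)
    if len(pred) == 0:
        raise ValueError("empty corpus: no reports to evaluate")
    counts = confusion(pred, ref, classes)

    rows = {}
    for c in classes:
        cc = counts[c]
        rows[c] = {"tp": cc.tp, "fp": cc.fp, "fn": cc.fn, "tn": cc.tn,
                   **label_metrics(cc, context=f"class {c!r}")}
    per_class = pd.DataFrame.from_dict(rows, orient="index")

    pooled = ConfusionCounts(0, 0, 0, 0)
    for cc in counts.values():
        pooled = pooled + cc
    micro = label_metrics(pooled, context="micro average")

    macro: dict[str, float] = {}
    for m in ("precision", "sensitivity", "specificity", "f1", "accuracy"):
        vals = per_class[m].dropna()
        if len(vals) < len(classes):
            warnings.warn(f"macro {m}: {len(classes) - len(vals)} class(es) "
                          "undefined and excluded from the average", stacklevel=2)
        macro[m] = float(vals.mean()) if len(vals) else math.nan

    p = pred.to_numpy()
    r = ref.to_numpy()
    wrong = (p != r)
    hamming = float(wrong.sum()) / (len(pred) * len(classes))
    emr = float((~wrong).all(axis=1).mean())
    cardinality = float(r.sum(axis=1).mean())
    density = cardinality / len(classes)

    return MetricsReport(
        per_class=per_class, micro=micro, macro=macro,
        hamming_loss=hamming, exact_match_ratio=emr,
        cardinality=cardinality, label_density=density,
        n_reports=len(pred), classes=classes,
    )


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa between two aligned binary label vectors.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement and
    p_e the chance agreement from the raters' marginals. When p_e = 1 (both
    raters constant) kappa is undefined and reported as NaN with a warning.
    """
    a = [bool(x) for x in labels_a]
    b = [bool(x) for x in labels_b]
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty label vectors")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    pa = sum(a) / n
    pb = sum(b) / n
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        warnings.warn("Cohen's kappa undefined: chance agreement is 1 "
                      "(both raters constant); reported as NaN", stacklevel=2)
        return math.nan
    return (p_o - p_e) / (1 - p_e)


def kappa_per_class(labels_a: LabelFrame, labels_b: LabelFrame,
                    classes: Optional[Sequence[str]] = None) -> dict[str, float]:
    """Cohen's kappa per class plus ``pooled`` over the flattened matrices."""
    a, b, classes = _align(labels_a, labels_b, classes)
    out = {c: cohens_kappa(a[c], b[c]) for c in classes}
    out["pooled"] = cohens_kappa(a.to_numpy().ravel(), b.to_numpy().ravel())
    return out
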