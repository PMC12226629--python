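"""Multi-label metrics against hand computations and scikit-learn."""

import math
import random
import warnings

import numpy as np
import pandas as pd
import pytest

from radex.metrics import (ConfusionCounts, cohens_kappa, confusion,
                           kappa_per_class, label_metrics, multilabel_metrics)


def frame(matrix, classes, ids=None):
    ids = ids or [f"r{i}" for i in range(len(matrix))]
    return pd.DataFrame(matrix, columns=classes, index=ids).astype(bool)


class TestConfusion:
    def test_perfect_agreement(self):
        m = frame([[1, 0, 1]] * 10, list("abc"))
        counts = confusion(m, m)
        for c in "abc":
            assert counts[c].fp == counts[c].fn == 0
            assert counts[c].total == 10

    def test_hand_enumerated_fixture(self):
        pred = frame([[1, 1], [1, 0], [0, 1], [0, 0],
                      [1, 1], [0, 0], [1, 0], [0, 1]], ["x", "y"])
        ref = frame([[1, 0], [1, 1], [0, 1], [0, 0],
                     [0, 1], [1, 0], [1, 0], [0, 0]], ["x", "y"])
        counts = confusion(pred, ref)
        # enumerated by hand over the 8 rows
        assert counts["x"] == ConfusionCounts(tp=3, fp=1, fn=1, tn=3)
        assert counts["y"] == ConfusionCounts(tp=2, fp=2, fn=1, tn=3)

    def test_single_report_false_positive(self):
        counts = confusion(frame([[1]], ["c"]), frame([[0]], ["c"]))
        assert counts["c"] == ConfusionCounts(tp=0, fp=1, fn=0, tn=0)

    def test_id_mismatch_is_error(self):
        pred = frame([[1]], ["c"], ids=["a"])
        ref = frame([[1]], ["c"], ids=["b"])
        with pytest.raises(ValueError, match="unpaired"):
            confusion(pred, ref)


class TestLabelMetrics:
    def test_worked_example(self):
        m = label_metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
        assert m["precision"] == pytest.approx(0.75)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["f1"] == pytest.approx(0.75)

    def test_perfect_counts(self):
        m = label_metrics(ConfusionCounts(tp=4, fp=0, fn=0, tn=6))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_reported_as_nan_with_warning(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            m = label_metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=5))
        assert math.isnan(m["precision"])
        assert m["sensitivity"] == 0.0


class TestMultilabelMetrics:
    def test_identical_matrices(self):
        m = frame([[1, 0], [0, 1], [1, 1]], ["a", "b"])
        report = multilabel_metrics(m, m)
        assert report.hamming_loss == 0.0
        assert report.exact_match_ratio == 1.0

    def test_one_wrong_label_in_four(self):
        pred = frame([[1, 1], [1, 0]], ["a", "b"])
        ref = frame([[1, 0], [1, 0]], ["a", "b"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = multilabel_metrics(pred, ref)
        assert report.hamming_loss == pytest.approx(0.25)
        assert report.exact_match_ratio == pytest.approx(0.5)

    def test_cardinality_and_density(self):
        ref = frame([[1, 1, 0], [1, 0, 0]], ["a", "b", "c"])
        report = multilabel_metrics(ref, ref)
        assert report.cardinality == pytest.approx(1.5)
        assert report.label_density == pytest.approx(0.5)

    def test_micro_equals_metrics_of_summed_counts(self, rng):
        for _ in range(50):
            n, k = rng.randint(2, 12), rng.randint(1, 5)
            pred = frame([[rng.random() < 0.5 for _ in range(k)]
                          for _ in range(n)], [f"c{j}" for j in range(k)])
            ref = frame([[rng.random() < 0.5 for _ in range(k)]
                         for _ in range(n)], [f"c{j}" for j in range(k)])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = multilabel_metrics(pred, ref)
                counts = confusion(pred, ref)
                pooled = ConfusionCounts(0, 0, 0, 0)
                for cc in counts.values():
                    pooled = pooled + cc
                expected = label_metrics(pooled)
            for key, value in report.micro.items():
                same = (math.isnan(value) and math.isnan(expected[key])) or \
                    value == expected[key]
                assert same, key

    def test_hamming_zero_iff_exact_match_one(self, rng):
        for _ in range(100):
            n, k = rng.randint(1, 8), rng.randint(1, 4)
            pred = frame([[rng.random() < 0.5 for _ in range(k)]
                          for _ in range(n)], [f"c{j}" for j in range(k)])
            ref = frame([[rng.random() < 0.5 for _ in range(k)]
                         for _ in range(n)], [f"c{j}" for j in range(k)])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = multilabel_metrics(pred, ref)
            assert (report.hamming_loss == 0) == (report.exact_match_ratio == 1)

    def test_empty_corpus_is_error(self):
        empty = frame([], ["a"])
        with pytest.raises(ValueError, match="empty"):
            multilabel_metrics(empty, empty)

    def test_class_group_restriction(self):
        pred = frame([[1, 1, 0]], ["a", "b", "c"])
        ref = frame([[1, 0, 0]], ["a", "b", "c"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = multilabel_metrics(pred, ref, classes=["a", "c"])
        assert report.classes == ["a", "c"]
        assert report.hamming_loss == 0.0


class TestCohensKappa:
    def test_identical_vectors_with_both_labels(self):
        assert cohens_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_hand_computed_zero(self):
        # p_o = 0.5, marginals 0.5/0.5 -> p_e = 0.5 -> kappa = 0
        assert cohens_kappa([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)

    def test_constant_raters_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(cohens_kappa([1, 1, 1], [1, 1, 1]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            cohens_kappa([1], [1, 0])


class TestSklearnCrossCheck:
    def test_all_metrics_match_reference_implementation(self, rng):
        """Every metric agrees with scikit-learn to 1e-12 on 100 random
        label matrices."""
        from sklearn.metrics import (accuracy_score, cohen_kappa_score,
                                     f1_score, hamming_loss, precision_score,
                                     recall_score)
        for trial in range(100):
            n = rng.randint(2, 15)
            k = rng.randint(2, 6)  # k=1 would make sklearn treat y as binary
            p_true = rng.uniform(0.1, 0.9)
            pred_m = [[rng.random() < p_true for _ in range(k)] for _ in range(n)]
            ref_m = [[rng.random() < p_true for _ in range(k)] for _ in range(n)]
            classes = [f"c{j}" for j in range(k)]
            pred, ref = frame(pred_m, classes), frame(ref_m, classes)
            y_pred, y_true = np.array(pred_m), np.array(ref_m)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = multilabel_metrics(pred, ref)

                assert report.hamming_loss == \
                    pytest.approx(hamming_loss(y_true, y_pred), abs=1e-12)
                assert report.exact_match_ratio == \
                    pytest.approx(accuracy_score(y_true, y_pred), abs=1e-12)
                for j, c in enumerate(classes):
                    row = report.per_class.loc[c]
                    for ours, sk in (
                            ("precision", precision_score),
                            ("sensitivity", recall_score),
                            ("f1", f1_score)):
                        want = sk(y_true[:, j], y_pred[:, j],
                                  zero_division=np.nan)
                        if math.isnan(want):
                            assert math.isnan(row[ours]), (trial, c, ours)
                        else:
                            assert row[ours] == pytest.approx(want, abs=1e-12)
                    kap = cohen_kappa_score(y_true[:, j], y_pred[:, j])
                    ours_kap = cohens_kappa(pred[c], ref[c])
                    if math.isnan(kap) or math.isnan(ours_kap):
                        assert math.isnan(kap) == math.isnan(ours_kap)
                    else:
                        assert ours_kap == pytest.approx(kap, abs=1e-12)
                micro_f1 = f1_score(y_true, y_pred, average="micro",
                                    zero_division=np.nan)
                if not math.isnan(micro_f1) and not math.isnan(report.micro["f1"]):
                    assert report.micro["f1"] == pytest.approx(micro_f1, abs=1e-12)


def test_kappa_per_class_includes_pooled():
    a = frame([[1, 0], [0, 1], [1, 1]], ["x", "y"])
    b = frame([[1, 0], [0, 0], [1, 1]], ["x", "y"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = kappa_per_class(a, b)
    assert set(out) == {"x", "y", "pooled"}
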