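"""Strategy application: classification, post-rules, highlighting, review."""

import pytest

from radex.engine import (ClassificationResult, Evidence, PostRule,
                          SearchStrategy, StrategyClass, classify_corpus,
                          classify_report, flag_discrepancies, highlight,
                          strip_highlight)
from radex.preprocess import Report, preprocess_report
from radex.synth import CLASSES, generate_corpus


def classify_text(strategy, text, lexicon, rid="t1"):
    processed = preprocess_report(Report(id=rid, text=text))
    return classify_report(strategy, processed, lexicon)


NODULE = "Thyroid nodule(s)"
MULTI = "Multiple thyroid nodules"
SOLITARY = "Solitary thyroid nodule"
NORMAL = "Normal thyroid"


class TestClassifyReport:
    def test_grading_post_rule_forces_nodule(self, strategy, lexicon):
        result = classify_text(strategy,
                               "Findings: Thyroid seen. Graded u3 by BTA.",
                               lexicon)
        assert result.labels["BTA U3"]
        assert result.labels[NODULE]
        assert NODULE in result.rule_fired
        # derived classes re-evaluated after the rule fired
        assert result.labels[SOLITARY]
        assert not result.labels[NORMAL]

    def test_nodule_without_multiple_is_solitary(self, strategy, lexicon):
        result = classify_text(
            strategy, "Findings: thyroid with a single nodule.", lexicon)
        assert result.labels[NODULE] and not result.labels[MULTI]
        assert result.labels[SOLITARY]

    def test_empty_report_all_negative(self, strategy, lexicon):
        result = classify_text(strategy, "", lexicon)
        assert not any(result.labels.values())

    def test_negated_finding_not_positive(self, strategy, lexicon):
        result = classify_text(
            strategy, "Findings: thyroid normal. There are no thyroid nodules.",
            lexicon)
        assert not result.labels[NODULE]
        assert result.labels["Thyroid examination"]
        assert result.labels[NORMAL]
        # the negated match is still recorded as (flagged) evidence
        negated = [e for e in result.evidence[NODULE] if e.negated]
        assert negated and negated[0].trigger == "no"

    def test_exclusion_window(self, strategy, lexicon):
        result = classify_text(
            strategy, "Findings: a left parotid cyst is seen.", lexicon)
        assert not result.labels[NODULE]
        result2 = classify_text(
            strategy, "Findings: thyroid contains a colloid cyst.", lexicon)
        assert result2.labels[NODULE]

    def test_idempotent(self, strategy, lexicon):
        text = ("Clinical history: prior lobectomy. "
                "Findings: multinodular goitre, no abnormal nodes.")
        processed = preprocess_report(Report(id="x", text=text))
        r1 = classify_report(strategy, processed, lexicon)
        r2 = classify_report(strategy, processed, lexicon)
        assert r1.labels == r2.labels
        assert r1.evidence == r2.evidence

    def test_clinical_history_searched_for_surgery_only(self, strategy, lexicon):
        result = classify_text(
            strategy,
            "Clinical history: previous thyroidectomy. Findings: unremarkable.",
            lexicon)
        assert result.labels["Previous thyroid surgery"]
        # 'thyroidectomy' in the history must not count as an examination
        assert not result.labels["Thyroid examination"]


class TestClassifyCorpus:
    def test_empty_corpus(self, strategy):
        assert classify_corpus(strategy, []) == []

    def test_duplicate_ids_rejected_before_processing(self, strategy):
        reports = [Report("a", "x"), Report("a", "y")]
        with pytest.raises(ValueError, match="duplicate"):
            classify_corpus(strategy, reports)

    def test_recovers_generator_ground_truth(self, strategy):
        reports, truth = generate_corpus(120, seed=3)
        results = classify_corpus(strategy, reports)
        assert [r.report_id for r in results] == [r.id for r in reports]
        truth = truth.set_index("id")
        for result in results:
            row = truth.loc[result.report_id]
            if row["ambiguous"]:
                continue
            for cls in CLASSES:
                assert result.labels[cls] == bool(row[cls]), \
                    (result.report_id, cls)

    def test_post_rule_soundness_identities(self, strategy):
        reports, _ = generate_corpus(150, seed=8)
        for r in classify_corpus(strategy, reports):
            grade = any(r.labels[f"BTA U{g}"] for g in (2, 3, 4, 5))
            assert not (grade and not r.labels[NODULE])
            assert not (r.labels[SOLITARY] and r.labels[MULTI])
            if r.labels[NORMAL]:
                assert not any(r.labels[c] for c in
                               (NODULE, "Altered thyroid echotexture",
                                "Goitre", "Previous thyroid surgery"))

    def test_positive_primary_labels_have_evidence(self, strategy):
        # negated spans never justify a positive label for negation-enabled
        # classes; examination-performed classes accept negated mentions and
        # rule-forced labels carry their rule instead of a span
        reports, _ = generate_corpus(100, seed=5)
        negation_on = {c.name for c in strategy.classes
                       if not c.derived and c.negation}
        for r in classify_corpus(strategy, reports):
            for cls, value in r.labels.items():
                if value and cls in negation_on and cls not in r.rule_fired:
                    assert any(not e.negated for e in r.evidence[cls]), \
                        (r.report_id, cls)


class TestHighlight:
    def test_round_trip_strips_to_raw_text(self, strategy, lexicon):
        text = ("Clinical history: neck lump & <swelling>.\n\n"
                "Findings: multinodular goitre, heterogeneous echotexture, "
                "no abnormal lymph nodes.")
        report = Report(id="h1", text=text)
        result = classify_report(strategy, preprocess_report(report), lexicon)
        doc = highlight(report, result)
        assert strip_highlight(doc) == text

    def test_distinct_classes_marked(self, strategy, lexicon):
        text = ("Findings: multinodular goitre with heterogeneous echotexture. "
                "No abnormal lymph nodes.")
        report = Report(id="h2", text=text)
        result = classify_report(strategy, preprocess_report(report), lexicon)
        doc = highlight(report, result)
        for cls in ("Goitre", MULTI, "Altered thyroid echotexture",
                    "Lymph node examination"):
            assert result.labels[cls], cls
            assert f"title=\"{cls}" in doc or cls in doc
        assert "negation trigger" in doc  # 'no abnormal' marked distinctly

    def test_report_without_matches_unchanged(self, strategy, lexicon):
        text = "nothing of interest here"
        report = Report(id="h3", text=text)
        result = classify_report(strategy, preprocess_report(report), lexicon)
        doc = highlight(report, result)
        assert strip_highlight(doc) == text
        assert "<span" not in doc.split("<hr>")[1]

    def test_out_of_bounds_span_is_a_defect(self):
        report = Report(id="h4", text="short")
        result = ClassificationResult(
            report_id="h4", labels={"C": True},
            evidence={"C": [Evidence("body", 0, 99, "short")]})
        with pytest.raises(ValueError, match="outside"):
            highlight(report, result)


class TestFlagDiscrepancies:
    @staticmethod
    def _results_and_reference(strategy, n=40, seed=13):
        reports, truth = generate_corpus(n, seed=seed)
        results = classify_corpus(strategy, reports)
        truth = truth.set_index("id")
        reference = {rid: {c: bool(truth.loc[rid, c]) for c in CLASSES}
                     for rid in truth.index}
        return reports, results, reference, truth

    def test_agreement_yields_no_records(self, strategy):
        reports, results, reference, truth = \
            self._results_and_reference(strategy)
        results = [r for r in results
                   if not truth.loc[r.report_id, "ambiguous"]]
        assert flag_discrepancies(results, reference) == []

    def test_injected_errors_all_flagged(self, strategy):
        reports, results, reference, truth = \
            self._results_and_reference(strategy)
        results = [r for r in results
                   if not truth.loc[r.report_id, "ambiguous"]]
        flipped = [(results[i].report_id, cls)
                   for i, cls in [(0, NODULE), (3, "Goitre"), (7, "BTA U1")]]
        for rid, cls in flipped:
            reference[rid][cls] = not reference[rid][cls]
        records = flag_discrepancies(results, reference)
        assert len(records) == len(flipped)
        assert {(r.report_id, r.class_name) for r in records} == set(flipped)

    def test_fp_records_carry_spans(self, strategy, lexicon):
        report = Report(id="fp1", text="Findings: thyroid nodule seen.")
        result = classify_report(strategy, preprocess_report(report), lexicon)
        reference = {"fp1": {c: False for c in CLASSES}}
        records = flag_discrepancies([result], reference,
                                     reports={"fp1": report})
        fp = [r for r in records if r.class_name == NODULE]
        assert fp and fp[0].kind == "FP" and "nodule" in fp[0].evidence

    def test_missing_reference_skipped_and_logged(self, strategy, lexicon,
                                                  caplog):
        report = Report(id="m1", text="Findings: thyroid normal.")
        result = classify_report(strategy, preprocess_report(report), lexicon)
        with caplog.at_level("WARNING", logger="radex.engine"):
            records = flag_discrepancies([result], {})
        assert records == []
        assert "m1" in caplog.text
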