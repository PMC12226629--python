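"""Apply a search strategy to a corpus: classification, highlighting, review.

A :class:`SearchStrategy` is an ordered set of named classes, each defined
by a query over its target report sections, plus derived classes (boolean
logic over earlier labels) and post-processing implication rules (e.g. a
BTA U2-U5 nodule grading implies the presence of a thyroid nodule).

For each report, every non-derived class is evaluated over its configured
sections with negation detection applied to its matches; derived classes
are then computed from the labels; post-processing rules fire last and
derived classes are re-evaluated once more so the output is a fixpoint.
Each positive label carries its supporting evidence spans (raw-text
coordinates) for highlighting and for review of discrepancies against
reference-standard labels.
"""

from __future__ import annotations

import html as _html
import json
import logging
import re
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

from .negation import NegationLexicon, default_lexicon, detect_negation
from .preprocess import (ProcessedReport, Report, Sentence, StandardiseConfig,
                         DEFAULT_HEADERS, preprocess_report)
from .query_lang import (ParseError, QueryNode, parse_query, validate_strategy)
from .regex_compile import MatchSpan, evaluate, export_patterns, compile_leaf

logger = logging.getLogger("radex.engine")

__all__ = [
    "StrategyClass",
    "PostRule",
    "SearchStrategy",
    "Evidence",
    "ClassificationResult",
    "load_strategy",
    "packaged_strategy",
    "classify_report",
    "classify_corpus",
    "highlight",
    "strip_highlight",
    "flag_discrepancies",
    "results_to_frame",
]


@dataclass
class StrategyClass:
    """One named class: a query, its target sections, and flags."""

    name: str
    query: str
    sections: Optional[tuple[str, ...]] = None  # None -> strategy default
    derived: bool = False
    negation: bool = True  # apply negation detection to this class's matches
    node: Optional[QueryNode] = None  # parsed lazily

    def parsed(self) -> QueryNode:
        if self.node is None:
            self.node = parse_query(self.query)
        return self.node


@dataclass(frozen=True)
class PostRule:
    """Implication applied after classification: if `if_class` then set
    `then_class` to `set_to`."""

    if_class: str
    then_class: str
    set_to: bool = True


@dataclass
class SearchStrategy:
    """An ordered, validated set of classes plus post-processing rules."""

    classes: list[StrategyClass]
    post_rules: list[PostRule] = field(default_factory=list)
    name: str = "strategy"
    default_sections: tuple[str, ...] = ("body",)
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")

    @property
    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]

    def sections_of(self, cls: StrategyClass) -> tuple[str, ...]:
        return cls.sections if cls.sections is not None else self.default_sections

    def validate(self) -> list[ParseError]:
        return validate_strategy(self)

    def export_regexes(self) -> str:
        """All compiled leaf patterns, one block per class, for audit."""
        lines = []
        for cls in self.classes:
            lines.append(f"## class: {cls.name}")
            lines.append(f"## query: {cls.query.strip()}")
            for compiled, polarity in export_patterns(cls.parsed()):
                tag = "match" if polarity else "exclude"
                lines.append(f"# {tag}")
                lines.append(compiled.pattern)
            lines.append("")
        return "\n".join(lines)


def load_strategy(path: Union[str, Path]) -> SearchStrategy:
    """Load a strategy YAML file and validate it; raises the first
    :class:`ParseError` when invalid."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    classes = []
    for entry in doc.get("classes", []):
        classes.append(StrategyClass(
            name=str(entry["name"]),
            query=str(entry["query"]),
            sections=tuple(entry["sections"]) if "sections" in entry else None,
            derived=bool(entry.get("derived", False)),
            negation=bool(entry.get("negation", True)),
        ))
    rules = [PostRule(str(r["if"]), str(r["then"]), bool(r.get("set_to", True)))
             for r in doc.get("post_processing", [])]
    strategy = SearchStrategy(
        classes=classes,
        post_rules=rules,
        name=str(doc.get("name", Path(path).stem)),
        default_sections=tuple(doc.get("default_sections", ("body",))),
        groups={k: list(v) for k, v in (doc.get("groups") or {}).items()},
    )
    errors = strategy.validate()
    if errors:
        raise errors[0]
    return strategy


def packaged_strategy() -> SearchStrategy:
    """The shipped thyroid/neck ultrasound strategy (14 classes)."""
    ref = resources.files("radex").joinpath("data/thyroid_us.yaml")
    with resources.as_file(ref) as path:
        return load_strategy(path)


# --------------------------------------------------------------------------- #
# Classification
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class Evidence:
    """A match supporting (or, when negated, failing to support) a label.

    ``start``/``end`` are raw-text coordinates in the original report;
    ``trigger_span`` locates the negation cue in raw text when present.
    """

    section: str
    start: int
    end: int
    text: str
    negated: bool = False
    trigger: Optional[str] = None
    trigger_span: Optional[tuple[int, int]] = None


@dataclass
class ClassificationResult:
    report_id: str
    labels: dict[str, bool]
    evidence: dict[str, list[Evidence]]
    rule_fired: dict[str, str] = field(default_factory=dict)
    error: Optional[str] = None


def _named_sentences(processed: ProcessedReport,
                     names: Sequence[str]) -> list[tuple[str, Sentence]]:
    """Sentences of the named sections, tagged with their section; absent
    sections fall back (once) to 'body'."""
    out: list[tuple[str, Sentence]] = []
    fell_back = False
    for name in names:
        if name in processed.sentences:
            out.extend((name, s) for s in processed.sentences[name])
        elif not fell_back and "body" not in names:
            out.extend(("body", s) for s in processed.sentences.get("body", []))
            fell_back = True
    return out


def _classify_primary(cls: StrategyClass, strategy: SearchStrategy,
                      processed: ProcessedReport,
                      lexicon: NegationLexicon,
                      and_scope: str) -> tuple[bool, list[Evidence]]:
    named = _named_sentences(processed, strategy.sections_of(cls))
    texts = [s.text for _, s in named]
    node = cls.parsed()

    # collect every positive-polarity leaf match for evidence/negation
    pos_spans_by_sentence: dict[int, list[MatchSpan]] = {}
    for compiled, polarity in export_patterns(node):
        if not polarity:
            continue
        rx = compiled.regex
        for i, text in enumerate(texts):
            for m in rx.finditer(text):
                if m.start() == m.end():
                    continue
                pos_spans_by_sentence.setdefault(i, []).append(
                    MatchSpan(m.start(), m.end(), m.group(0), sentence=i))

    # verdicts are always computed so highlighting can mark negation cues;
    # they gate the label only for negation-enabled classes
    verdicts: dict[tuple[int, MatchSpan], object] = {}
    for i, spans in pos_spans_by_sentence.items():
        for ns in detect_negation(texts[i], spans, lexicon):
            verdicts[(i, ns.span)] = ns

    def span_filter(i: int, span: MatchSpan) -> bool:
        ns = verdicts.get((i, span))
        return ns is None or not ns.negated

    present, _ = evaluate(node, texts, and_scope=and_scope,
                          span_filter=span_filter if cls.negation else None)

    evidence: list[Evidence] = []
    seen: set[tuple[int, int, int]] = set()
    for i, spans in sorted(pos_spans_by_sentence.items()):
        section, sentence = named[i]
        for span in spans:
            key = (i, span.start, span.end)
            if key in seen:
                continue
            seen.add(key)
            raw_start, raw_end = sentence.raw_span(span.start, span.end)
            ns = verdicts.get((i, span))
            trig_span = None
            if ns is not None and ns.negated and ns.trigger_start is not None:
                trig_span = sentence.raw_span(ns.trigger_start, ns.trigger_end)
            evidence.append(Evidence(
                section=section,
                start=raw_start,
                end=raw_end,
                text=processed.report.text[raw_start:raw_end],
                negated=bool(ns is not None and ns.negated),
                trigger=ns.trigger if ns is not None else None,
                trigger_span=trig_span,
            ))
    evidence.sort(key=lambda e: (e.start, e.end))
    return present, evidence


def classify_report(strategy: SearchStrategy,
                    processed: ProcessedReport,
                    lexicon: Optional[NegationLexicon] = None,
                    *,
                    and_scope: str = "section") -> ClassificationResult:
    """Classify one preprocessed report for every class of the strategy.

    Deterministic: primaries are evaluated over their sections with
    negation applied, derived classes by boolean logic over earlier labels,
    post-processing rules last (with one derived re-evaluation pass so
    labels reach a fixpoint, asserted after two passes).
    """
    lexicon = lexicon or default_lexicon()
    labels: dict[str, bool] = {}
    evidence: dict[str, list[Evidence]] = {}
    rule_fired: dict[str, str] = {}

    def eval_derived(cls: StrategyClass) -> bool:
        present, _ = evaluate(cls.parsed(), [], resolver=lambda n: labels[n])
        return present

    for cls in strategy.classes:
        if cls.derived:
            labels[cls.name] = eval_derived(cls)
            evidence[cls.name] = []
        else:
            present, ev = _classify_primary(cls, strategy, processed, lexicon,
                                            and_scope)
            labels[cls.name] = present
            evidence[cls.name] = ev

    def apply_rules() -> None:
        for rule in strategy.post_rules:
            if labels.get(rule.if_class) and labels.get(rule.then_class) != rule.set_to:
                labels[rule.then_class] = rule.set_to
                rule_fired[rule.then_class] = (
                    f"{rule.if_class} => {rule.then_class}={rule.set_to}")

    apply_rules()
    # a fired rule may change inputs of derived classes: re-derive, re-apply
    for _ in range(2):
        before = dict(labels)
        for cls in strategy.classes:
            if cls.derived:
                labels[cls.name] = eval_derived(cls)
        apply_rules()
        if labels == before:
            break
    else:
        raise AssertionError("post-rule/derived labels did not reach a fixpoint")

    return ClassificationResult(
        report_id=processed.report.id,
        labels=labels,
        evidence=evidence,
        rule_fired=rule_fired,
    )


def classify_corpus(strategy: SearchStrategy,
                    reports: Sequence[Report],
                    lexicon: Optional[NegationLexicon] = None,
                    *,
                    headers: Sequence[str] = DEFAULT_HEADERS,
                    config: Optional[StandardiseConfig] = None,
                    and_scope: str = "section") -> list[ClassificationResult]:
    """Classify a corpus, one result per report, order preserved.

    Duplicate report ids are an error before any processing starts.
    Per-report failures are logged and recorded on the result, never
    aborting the batch.
    """
    ids = [r.id for r in reports]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate report ids: {dupes[:10]}")
    lexicon = lexicon or default_lexicon()
    t0 = time.perf_counter()
    results: list[ClassificationResult] = []
    for report in reports:
        try:
            processed = preprocess_report(report, headers, config)
            results.append(classify_report(strategy, processed, lexicon,
                                           and_scope=and_scope))
        except Exception as exc:  # noqa: BLE001 — batch must survive one bad report
            logger.exception("report %s failed", report.id)
            results.append(ClassificationResult(
                report_id=report.id,
                labels={c.name: False for c in strategy.classes},
                evidence={c.name: [] for c in strategy.classes},
                error=f"{type(exc).__name__}: {exc}",
            ))
    elapsed = time.perf_counter() - t0
    counts = {name: sum(r.labels.get(name, False) for r in results)
              for name in strategy.class_names}
    logger.info("classified %d reports in %.2fs (%.1f ms/report); positives: %s",
                len(results), elapsed,
                1000 * elapsed / max(len(results), 1), counts)
    return results


# --------------------------------------------------------------------------- #
# Highlighting
# --------------------------------------------------------------------------- #

_PALETTE = ["#9ecae1", "#a1d99b", "#bcbddc", "#fdae6b", "#fc9272", "#c7e9c0",
            "#fdd0a2", "#d9d9d9", "#dadaeb", "#c6dbef", "#e7ba52", "#ce6dbd",
            "#969696", "#9c9ede"]


def _merge_same_class(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in sorted(spans):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def highlight(report: Report, result: ClassificationResult) -> str:
    """Render a report as standalone HTML with one style per class over its
    evidence spans; negation triggers are marked distinctly. Stripping the
    markup (:func:`strip_highlight`) reproduces the raw text exactly."""
    text = report.text
    by_class: dict[str, list[tuple[int, int]]] = {}
    neg_spans: list[tuple[int, int]] = []
    for cls_name, evs in result.evidence.items():
        for ev in evs:
            if not (0 <= ev.start < ev.end <= len(text)):
                raise ValueError(
                    f"evidence span ({ev.start}, {ev.end}) outside report "
                    f"{report.id} text — offset defect")
            if ev.negated:
                if ev.trigger_span is not None:
                    neg_spans.append(ev.trigger_span)
            by_class.setdefault(cls_name, []).append((ev.start, ev.end))

    classes = [c for c in result.labels if by_class.get(c)]
    colour = {c: _PALETTE[i % len(_PALETTE)] for i, c in enumerate(result.labels)}

    # segment the text at every span boundary and tag each segment
    cuts = {0, len(text)}
    tagged: list[tuple[int, int, str, str]] = []  # start, end, kind, label
    for c in classes:
        for a, b in _merge_same_class(by_class[c]):
            cuts.update((a, b))
            tagged.append((a, b, "class", c))
    for a, b in _merge_same_class(neg_spans):
        cuts.update((a, b))
        tagged.append((a, b, "negation", "negation trigger"))
    bounds = sorted(cuts)

    body_parts: list[str] = []
    for a, b in zip(bounds, bounds[1:]):
        seg = _html.escape(text[a:b])
        covering = [(kind, label) for (s, e, kind, label) in tagged
                    if s <= a and b <= e]
        if covering:
            neg = any(k == "negation" for k, _ in covering)
            labels = [l for k, l in covering if k == "class"]
            style = ""
            if labels:
                style += f"background:{colour[labels[0]]};"
            if neg:
                style += "text-decoration:underline wavy;font-style:italic;"
            title = _html.escape("; ".join(labels + (["negation trigger"] if neg else [])))
            seg = f'<span style="{style}" title="{title}">{seg}</span>'
        body_parts.append(seg)

    legend = "".join(
        f'<span style="background:{colour[c]};margin-right:1em;">{_html.escape(c)}</span>'
        for c in classes)
    pos = ", ".join(_html.escape(c) for c, v in result.labels.items() if v) or "none"
    return (
        "<!DOCTYPE html><html><head><meta charset=\"utf-8\">"
        f"<title>{_html.escape(report.id)}</title></head><body>"
        f"<p><b>Report {_html.escape(report.id)}</b> — positive: {pos}</p>"
        f"<p>{legend}</p><hr>"
        f'<pre id="report-text" style="white-space:pre-wrap;">{"".join(body_parts)}</pre>'
        "</body></html>"
    )


_TAG_RX = re.compile(r"<[^>]*>")


def strip_highlight(html_doc: str) -> str:
    """Recover the raw report text from a highlight document."""
    m = re.search(r'<pre id="report-text"[^>]*>(.*)</pre>', html_doc, re.DOTALL)
    if m is None:
        raise ValueError("not a highlight document")
    return _html.unescape(_TAG_RX.sub("", m.group(1)))


# --------------------------------------------------------------------------- #
# Discrepancy review
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class Discrepancy:
    report_id: str
    class_name: str
    kind: str  # "FP" or "FN"
    evidence: str  # offending spans (FP) or section text for review (FN)


def flag_discrepancies(results: Sequence[ClassificationResult],
                       reference: dict[str, dict[str, bool]],
                       *,
                       reports: Optional[dict[str, Report]] = None) -> list[Discrepancy]:
    """Compare predictions with reference-standard labels.

    Returns one record per (report, class) disagreement: false positives
    carry the offending match spans, false negatives the report text for
    manual review. Pairs with no reference label are excluded and logged.
    """
    out: list[Discrepancy] = []
    for result in results:
        ref_labels = reference.get(result.report_id)
        if ref_labels is None:
            logger.warning("no reference labels for report %s — skipped",
                           result.report_id)
            continue
        for cls_name, pred in result.labels.items():
            if cls_name not in ref_labels:
                logger.warning("no reference label for (%s, %s) — skipped",
                               result.report_id, cls_name)
                continue
            ref = bool(ref_labels[cls_name])
            if pred == ref:
                continue
            if pred and not ref:
                spans = [f"[{e.start}:{e.end}] {e.text!r}"
                         for e in result.evidence.get(cls_name, [])
                         if not e.negated]
                out.append(Discrepancy(result.report_id, cls_name, "FP",
                                       "; ".join(spans)))
            else:
                text = ""
                if reports and result.report_id in reports:
                    text = reports[result.report_id].text
                out.append(Discrepancy(result.report_id, cls_name, "FN", text))
    return out


# --------------------------------------------------------------------------- #
# Tabular output
# --------------------------------------------------------------------------- #

def results_to_frame(results: Sequence[ClassificationResult],
                     *, with_evidence: bool = True):
    """Results as a DataFrame: one boolean column per class plus an
    evidence JSON column."""
    import pandas as pd

    rows = []
    for r in results:
        row: dict[str, object] = {"id": r.report_id, **{k: bool(v) for k, v in r.labels.items()}}
        if with_evidence:
            row["evidence"] = json.dumps({
                c: [{"section": e.section, "start": e.start, "end": e.end,
                     "text": e.text, "negated": e.negated,
                     **({"trigger": e.trigger} if e.trigger else {})}
                    for e in evs]
                for c, evs in r.evidence.items() if evs
            }, sort_keys=True)
        if r.error:
            row["error"] = r.error
        rows.append(row)
    return pd.DataFrame(rows)
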