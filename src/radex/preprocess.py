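"""Corpus filtering, header-based sectioning, and text standardisation.

Free-text clinical reports arrive as one blob per record with embedded
section headers ("Clinical history:", "Findings:"...). This module splits
each report at configured headers, lowercases and normalises punctuation,
and tokenises into sentences — keeping, for every standardised character,
its offset in the raw report text so downstream match spans can be
highlighted on the original document without drift.

All spans and offsets are 0-based, half-open, defined on the RAW text.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

logger = logging.getLogger("radex.preprocess")

__all__ = [
    "Report",
    "Sentence",
    "ProcessedReport",
    "FilterCriteria",
    "StandardiseConfig",
    "filter_corpus",
    "split_sections",
    "standardise",
    "preprocess_report",
    "read_corpus",
    "write_corpus",
]

DEFAULT_HEADERS = ("clinical history", "findings", "conclusion", "comment")

# Conservative stopword list; negation cues (no, not, without, never...) are
# deliberately NOT stopwords — removing them would break negation detection
# and silently change proximity-gap semantics.
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be been by for from has have in is it its of on or
    that the this to was were will with which""".split()
)

# Tokens after which a full stop is treated as an abbreviation dot rather
# than a sentence boundary (plus any single-letter token).
_ABBREVIATIONS = frozenset(
    {"cm", "mm", "ml", "cc", "kg", "dr", "mr", "mrs", "ms", "vs", "approx"}
)


@dataclass
class Report:
    """A raw free-text report with a pseudoidentifier and optional metadata."""

    id: str
    text: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("report id must be non-empty")


@dataclass(frozen=True)
class Sentence:
    """A standardised sentence plus the raw-text offset of every character."""

    text: str
    offsets: tuple[int, ...]  # offsets[i] = raw index of text[i]

    def raw_span(self, start: int, end: int) -> tuple[int, int]:
        """Map a half-open span in standardised coordinates to raw ones."""
        if not (0 <= start < end <= len(self.text)):
            raise ValueError(f"span ({start}, {end}) outside sentence")
        return self.offsets[start], self.offsets[end - 1] + 1


@dataclass
class ProcessedReport:
    """A report split into sections, each standardised and sentence-tokenised.

    ``sections`` maps section name to raw-text chunk spans (a duplicated
    header contributes several chunks); ``sentences`` maps section name to
    the standardised sentences of all its chunks in order. Unheaded leading
    text lives in section ``body``.
    """

    report: Report
    sections: dict[str, list[tuple[int, int]]]
    sentences: dict[str, list[Sentence]]

    def section_text(self, name: str) -> str:
        return "\n".join(self.report.text[a:b] for a, b in self.sections.get(name, []))

    def section_sentences(self, names: Sequence[str]) -> list[Sentence]:
        """Sentences of the named sections; absent sections fall back to
        ``body`` so unstructured reports still classify."""
        out: list[Sentence] = []
        seen_fallback = False
        for name in names:
            if name in self.sentences:
                out.extend(self.sentences[name])
            elif not seen_fallback:
                out.extend(self.sentences.get("body", []))
                seen_fallback = True
        return out


# --------------------------------------------------------------------------- #
# Corpus filtering
# --------------------------------------------------------------------------- #

@dataclass
class FilterCriteria:
    """Inclusion/exclusion criteria for a corpus.

    ``keep_most_recent`` keeps, for each pseudoidentifier, only the report
    with the latest ``exam_date`` (avoiding train/test leakage from repeat
    examinations of one patient).
    """

    date_from: Optional[_dt.date] = None
    date_to: Optional[_dt.date] = None
    min_age: Optional[float] = None
    max_age: Optional[float] = None
    exam_codes: Optional[frozenset[str]] = None
    keep_most_recent: bool = False


def _as_date(value) -> Optional[_dt.date]:
    if value is None or value == "":
        return None
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def filter_corpus(reports: Iterable[Report],
                  criteria: FilterCriteria) -> list[Report]:
    """Return the reports passing every active criterion.

    A report missing metadata required by an active criterion is excluded
    and logged rather than guessed at.
    """
    kept: list[Report] = []
    for rep in reports:
        meta = rep.metadata
        try:
            date = _as_date(meta.get("exam_date"))
        except ValueError:
            logger.warning("report %s: unparseable exam_date %r — excluded",
                           rep.id, meta.get("exam_date"))
            continue
        age = meta.get("age")
        age = None if age in (None, "") else float(age)
        code = meta.get("exam_code")
        if criteria.date_from is not None or criteria.date_to is not None:
            if date is None:
                logger.warning("report %s: no exam_date for date filter — excluded", rep.id)
                continue
            if criteria.date_from is not None and date < criteria.date_from:
                continue
            if criteria.date_to is not None and date > criteria.date_to:
                continue
        if criteria.min_age is not None or criteria.max_age is not None:
            if age is None:
                logger.warning("report %s: no age for age filter — excluded", rep.id)
                continue
            if criteria.min_age is not None and age < criteria.min_age:
                continue
            if criteria.max_age is not None and age > criteria.max_age:
                continue
        if criteria.exam_codes is not None:
            if code is None or code not in criteria.exam_codes:
                if code is None:
                    logger.warning("report %s: no exam_code for code filter — excluded", rep.id)
                continue
        kept.append(rep)

    if criteria.keep_most_recent:
        latest: dict[str, Report] = {}
        for rep in kept:
            date = _as_date(rep.metadata.get("exam_date")) or _dt.date.min
            prev = latest.get(rep.id)
            if prev is None or date >= (_as_date(prev.metadata.get("exam_date"))
                                        or _dt.date.min):
                latest[rep.id] = rep
        # preserve original order of the surviving reports
        surviving = set(map(id, latest.values()))
        kept = [r for r in kept if id(r) in surviving]
    return kept


# --------------------------------------------------------------------------- #
# Sectioning
# --------------------------------------------------------------------------- #

def split_sections(report: Report,
                   headers: Sequence[str] = DEFAULT_HEADERS) -> ProcessedReport:
    """Partition a report's text at literal header occurrences.

    Headers match case-insensitively with an optional trailing colon; the
    header text itself is excluded from section content. Text before the
    first header goes to ``body``; a headerless report is one single
    ``body`` section. A duplicated header appends to the same section.
    """
    text = report.text
    hits: list[tuple[int, int, str]] = []  # (start, end, canonical name)
    for header in headers:
        rx = re.compile(r"(?<!\w)" + re.escape(header) + r"\s*:?", re.IGNORECASE)
        for m in rx.finditer(text):
            hits.append((m.start(), m.end(), header.lower()))
    hits.sort()
    sections: dict[str, list[tuple[int, int]]] = {}
    if not hits:
        if text:
            sections["body"] = [(0, len(text))]
    else:
        first = hits[0][0]
        if text[:first].strip():
            sections["body"] = [(0, first)]
        for k, (start, end, name) in enumerate(hits):
            nxt = hits[k + 1][0] if k + 1 < len(hits) else len(text)
            sections.setdefault(name, []).append((end, nxt))
    return ProcessedReport(report=report, sections=sections, sentences={})


# --------------------------------------------------------------------------- #
# Standardisation & sentence tokenisation
# --------------------------------------------------------------------------- #

@dataclass
class StandardiseConfig:
    """Text standardisation options.

    Stopword removal defaults to OFF: proximity gaps count intervening
    words, so stripping stopwords changes NEAR/X semantics ("thyroid
    contains multiple nodules" is a NEAR/2 hit only because "contains"
    counts). It remains available behind this flag; when on, gap counting
    operates on the surviving tokens.
    """

    remove_stopwords: bool = False
    stopwords: frozenset[str] = DEFAULT_STOPWORDS


_TERMINATORS = frozenset(".!?")


def _is_boundary(text: str, i: int) -> bool:
    """Is the terminator at raw index ``i`` a sentence boundary?"""
    ch = text[i]
    nxt = text[i + 1] if i + 1 < len(text) else ""
    if nxt and not nxt.isspace():
        return False  # mid-token punctuation: decimals, '?cancer', 'u2.5'
    if ch == ".":
        # abbreviation guard: single-letter tokens and measurement units
        j = i - 1
        while j >= 0 and (text[j].isalnum()):
            j -= 1
        token = text[j + 1:i].lower()
        if len(token) == 1 and token.isalpha():
            return False
        if token in _ABBREVIATIONS:
            return False
    return True


def standardise(text: str,
                config: Optional[StandardiseConfig] = None,
                *,
                base_offset: int = 0) -> list[Sentence]:
    """Standardise section text and split it into sentences.

    Lowercases, maps punctuation (including ``/ - ( )``) to spaces, keeps
    decimal points inside numbers, collapses whitespace runs, and splits at
    sentence-final ``. ! ?`` (with an abbreviation guard) and blank lines.
    Every output character carries its raw-text offset (shifted by
    ``base_offset``), so match spans map back onto the original report.
    """
    config = config or StandardiseConfig()
    sentences: list[Sentence] = []
    chars: list[str] = []
    offs: list[int] = []
    pending_space: Optional[int] = None  # raw idx of first char of a ws run

    def flush() -> None:
        nonlocal chars, offs, pending_space
        if chars:
            sent = Sentence("".join(chars), tuple(offs))
            if config.remove_stopwords:
                sent = _remove_stopwords(sent, config.stopwords)
            if sent.text:
                sentences.append(sent)
        chars, offs = [], []
        pending_space = None

    def emit(ch: str, raw_idx: int) -> None:
        nonlocal pending_space
        if pending_space is not None and chars:
            chars.append(" ")
            offs.append(pending_space)
        pending_space = None
        chars.append(ch)
        offs.append(raw_idx)

    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        raw = base_offset + i
        if ch.isalnum():
            emit(ch.lower(), raw)
        elif ch in _TERMINATORS:
            prev = text[i - 1] if i > 0 else ""
            nxt = text[i + 1] if i + 1 < n else ""
            if ch == "." and prev.isdigit() and nxt.isdigit():
                emit(ch, raw)  # decimal point inside a number
            elif _is_boundary(text, i):
                flush()
            else:
                if pending_space is None:
                    pending_space = raw
        elif ch == "\n":
            # blank line ends a sentence even without terminal punctuation
            j = i + 1
            while j < n and text[j] in " \t\r":
                j += 1
            if j < n and text[j] == "\n":
                flush()
                i = j
            elif pending_space is None:
                pending_space = raw
        elif ch.isspace():
            if pending_space is None:
                pending_space = raw
        else:
            # all other punctuation/symbols become word separators
            if pending_space is None:
                pending_space = raw
        i += 1
    flush()
    return sentences


def _remove_stopwords(sentence: Sentence, stopwords: frozenset[str]) -> Sentence:
    chars: list[str] = []
    offs: list[int] = []
    for m in re.finditer(r"\S+", sentence.text):
        token = m.group(0)
        if token.lower() in stopwords:
            continue
        if chars:
            chars.append(" ")
            offs.append(sentence.offsets[m.start()] - 1 if m.start() > 0
                        else sentence.offsets[m.start()])
        chars.extend(token)
        offs.extend(sentence.offsets[m.start():m.end()])
    return Sentence("".join(chars), tuple(offs))


def preprocess_report(report: Report,
                      headers: Sequence[str] = DEFAULT_HEADERS,
                      config: Optional[StandardiseConfig] = None) -> ProcessedReport:
    """Full preprocessing: sectioning plus per-section standardisation."""
    processed = split_sections(report, headers)
    for name, chunks in processed.sections.items():
        sents: list[Sentence] = []
        for a, b in chunks:
            sents.extend(standardise(report.text[a:b], config, base_offset=a))
        processed.sentences[name] = sents
    return processed


# --------------------------------------------------------------------------- #
# Corpus I/O (CSV / JSONL, UTF-8)
# --------------------------------------------------------------------------- #

_META_KEYS = ("exam_date", "age", "exam_code")


def _record_to_report(rec: dict) -> Report:
    meta = {k: rec[k] for k in _META_KEYS if rec.get(k) not in (None, "")}
    return Report(id=str(rec["id"]), text=str(rec.get("text", "")), metadata=meta)


def read_corpus(path: Union[str, Path]) -> list[Report]:
    """Read reports from CSV or JSONL (by extension); keys/columns:
    ``id``, ``text``, optional ``exam_date``, ``age``, ``exam_code``."""
    path = Path(path)
    reports: list[Report] = []
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    reports.append(_record_to_report(json.loads(line)))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            for rec in csv.DictReader(fh):
                reports.append(_record_to_report(rec))
    return reports


def write_corpus(reports: Iterable[Report], path: Union[str, Path]) -> None:
    """Write reports to CSV or JSONL (by extension)."""
    path = Path(path)
    rows = [{"id": r.id, "text": r.text,
             **{k: r.metadata.get(k, "") for k in _META_KEYS}}
            for r in reports]
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, default=str) + "\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["id", "text", *_META_KEYS])
            writer.writeheader()
            writer.writerows([{k: ("" if v is None else v) for k, v in row.items()}
                              for row in rows])
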