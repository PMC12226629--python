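"""Compile query AST nodes to word-boundary regular expressions and evaluate.

Keyword terms compile to patterns wrapped in ``\\b`` word boundaries: ``*``
becomes ``\\w*`` (zero or more word characters) and ``?`` becomes ``\\w?``
(zero or one word character, so ``h?emoglobin`` matches both British and
American spellings). Proximity nodes compile to a lazy intervening-word
group: ``a THEN/X b`` allows 0..X whole words between the operands and
``NEAR/X`` is the alternation of both orders.

:func:`evaluate` recursively evaluates a full boolean query over
standardised sentences, returning presence plus all supporting match spans.
Proximity never crosses a sentence boundary; AND combines evidence at
section scope by default (its operands may hit different sentences) or at
sentence scope when configured.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

from .query_lang import And, ClassRef, Near, Not, Or, QueryNode, Term, Then, to_string

__all__ = [
    "CompiledPattern",
    "MatchSpan",
    "compile_term",
    "compile_proximity",
    "compile_leaf",
    "export_patterns",
    "evaluate",
]


@dataclass(frozen=True)
class CompiledPattern:
    """A leaf pattern compiled to regular-expression text, with provenance."""

    pattern: str
    source_node: QueryNode

    @property
    def regex(self) -> re.Pattern:
        return _compiled(self.pattern)


@dataclass(frozen=True)
class MatchSpan:
    """A character-span hit, 0-based half-open, within one sentence."""

    start: int
    end: int
    text: str
    sentence: int = 0


_REGEX_CACHE: dict[str, re.Pattern] = {}


def _compiled(pattern: str) -> re.Pattern:
    rx = _REGEX_CACHE.get(pattern)
    if rx is None:
        rx = _REGEX_CACHE[pattern] = re.compile(pattern, re.IGNORECASE)
    return rx


def _atom_to_regex(atom: str) -> str:
    parts = []
    for ch in atom:
        if ch == "*":
            parts.append(r"\w*")
        elif ch == "?":
            parts.append(r"\w?")
        else:
            parts.append(re.escape(ch))
    return r"\b" + "".join(parts) + r"\b"


def compile_term(term: Term) -> CompiledPattern:
    """Compile a keyword term; multi-atom phrases join atoms with exactly
    one non-word-character run (``thyroglossal cyst`` ->
    ``\\bthyroglossal\\b\\W+\\bcyst\\b``)."""
    pattern = r"\W+".join(_atom_to_regex(a) for a in term.atoms)
    return CompiledPattern(pattern, term)


def _gap_group(gap: int) -> str:
    # lazy quantifier keeps highlighted spans minimal
    return r"(?:\W+\w+){0,%d}?\W+" % gap


def compile_proximity(node: Union[Near, Then]) -> CompiledPattern:
    """Compile a proximity node; NEAR/X matches both operand orders."""
    left = compile_term(node.left).pattern
    right = compile_term(node.right).pattern
    gap = _gap_group(node.gap)
    forward = f"{left}{gap}{right}"
    if isinstance(node, Then):
        return CompiledPattern(forward, node)
    backward = f"{right}{gap}{left}"
    return CompiledPattern(f"(?:{forward}|{backward})", node)


def compile_leaf(node: Union[Term, Near, Then]) -> CompiledPattern:
    if isinstance(node, Term):
        return compile_term(node)
    return compile_proximity(node)


def export_patterns(node: QueryNode, *, _polarity: bool = True) -> list[tuple[CompiledPattern, bool]]:
    """Flatten a query into its compiled leaf patterns for audit.

    Returns ``(compiled, polarity)`` pairs, ``polarity=False`` for leaves
    under an odd number of NOTs (exclusion patterns). Boolean structure is
    recorded in each pattern's ``source_node`` provenance.
    """
    if isinstance(node, (Term, Near, Then)):
        return [(compile_leaf(node), _polarity)]
    if isinstance(node, Not):
        return export_patterns(node.child, _polarity=not _polarity)
    if isinstance(node, (And, Or)):
        out: list[tuple[CompiledPattern, bool]] = []
        for child in node.children:
            out.extend(export_patterns(child, _polarity=_polarity))
        return out
    return []  # ClassRef has no pattern of its own


# --------------------------------------------------------------------------- #
# Recursive evaluation
# --------------------------------------------------------------------------- #

SpanFilter = Callable[[int, MatchSpan], bool]
Resolver = Callable[[str], bool]


def _leaf_spans(node: Union[Term, Near, Then], sentences: Sequence[str],
                idxs: Sequence[int],
                span_filter: Optional[SpanFilter]) -> list[MatchSpan]:
    rx = compile_leaf(node).regex
    spans: list[MatchSpan] = []
    for i in idxs:
        for m in rx.finditer(sentences[i]):
            if m.start() == m.end():
                continue
            span = MatchSpan(m.start(), m.end(), m.group(0), sentence=i)
            if span_filter is None or span_filter(i, span):
                spans.append(span)
    return spans


def _eval(node: QueryNode, sentences: Sequence[str], idxs: Sequence[int],
          resolver: Optional[Resolver], and_scope: str,
          span_filter: Optional[SpanFilter]) -> tuple[bool, list[MatchSpan]]:
    if isinstance(node, (Term, Near, Then)):
        spans = _leaf_spans(node, sentences, idxs, span_filter)
        return bool(spans), spans
    if isinstance(node, ClassRef):
        if resolver is None:
            raise LookupError(
                f'class reference "{node.name}" used without a resolver '
                "(strategy-ordering defect)")
        return bool(resolver(node.name)), []
    if isinstance(node, Not):
        present, _ = _eval(node.child, sentences, idxs, resolver, and_scope,
                           span_filter)
        return (not present), []
    if isinstance(node, Or):
        results = [_eval(c, sentences, idxs, resolver, and_scope, span_filter)
                   for c in node.children]
        present = any(p for p, _ in results)
        spans = [s for _, ss in results for s in ss]
        return present, _sorted(spans)
    if isinstance(node, And):
        if and_scope == "sentence" and len(idxs) > 1:
            present = False
            spans: list[MatchSpan] = []
            for i in idxs:
                results = [_eval(c, sentences, [i], resolver, and_scope,
                                 span_filter) for c in node.children]
                if all(p for p, _ in results):
                    present = True
                    spans.extend(s for _, ss in results for s in ss)
            return present, _sorted(spans) if present else []
        results = [_eval(c, sentences, idxs, resolver, and_scope, span_filter)
                   for c in node.children]
        present = all(p for p, _ in results)
        if not present:
            return False, []
        return True, _sorted([s for _, ss in results for s in ss])
    raise TypeError(f"not a query node: {node!r}")


def _sorted(spans: list[MatchSpan]) -> list[MatchSpan]:
    return sorted(set(spans), key=lambda s: (s.sentence, s.start, s.end))


def evaluate(node: QueryNode,
             text: Union[str, Sequence[str]],
             resolver: Optional[Resolver] = None,
             *,
             and_scope: str = "section",
             span_filter: Optional[SpanFilter] = None) -> tuple[bool, list[MatchSpan]]:
    """Recursively evaluate a query over standardised text.

    Parameters
    ----------
    node : QueryNode
        Parsed query.
    text : str or sequence of str
        One standardised sentence, or the ordered sentences of a section.
        Term and proximity patterns are matched within single sentences.
    resolver : callable, optional
        Maps a quoted class-reference name to its (report-level) boolean
        label; required when the query contains class references.
    and_scope : ``"section"`` or ``"sentence"``
        With ``"section"`` (default) the operands of AND may match in
        different sentences; with ``"sentence"`` they must co-occur in one.
    span_filter : callable, optional
        ``f(sentence_index, span) -> bool``; spans rejected by the filter
        (e.g. negated matches) do not count as evidence and do not make a
        leaf present.

    Returns
    -------
    (present, spans)
        ``spans`` are the non-overlapping leftmost matches supporting a
        positive result; NOT contributes no spans.
    """
    if and_scope not in ("section", "sentence"):
        raise ValueError("and_scope must be 'section' or 'sentence'")
    sentences = [text] if isinstance(text, str) else list(text)
    return _eval(node, sentences, range(len(sentences)), resolver, and_scope,
                 span_filter)


def query_regex(expression_or_node: Union[str, QueryNode]) -> str:
    """Audit helper: render every leaf pattern of a query as regex text."""
    from .query_lang import parse_query

    node = (parse_query(expression_or_node)
            if isinstance(expression_or_node, str) else expression_or_node)
    lines = []
    for compiled, polarity in export_patterns(node):
        tag = "match" if polarity else "exclude"
        lines.append(f"# {tag}: {to_string(compiled.source_node)}")
        lines.append(compiled.pattern)
    return "\n".join(lines)
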