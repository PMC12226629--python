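"""Search-expression language: tokenizer, parser, and strategy validation.

A search strategy is written in a high-level query syntax of keywords,
wildcard modifiers and logical connectors, in the style of bibliographic
search builders (PubMed/Ovid):

* ``thyr*``            — ``*`` matches zero or more word characters
* ``wom?n``            — ``?`` matches zero or one word character
* ``a NEAR/2 b``       — order-independent proximity, at most 2 words between
* ``a THEN/2 b``       — order-dependent proximity
* ``AND`` / ``OR`` / ``NOT`` / ``EXCEPT`` — boolean connectors, with
  precedence NOT > AND > OR; ``EXCEPT`` is sugar for ``AND NOT``
* ``"Class name"``     — reference to an earlier class label (derived classes)

Shorthand spellings ``&``, ``|``, ``¬`` and ``~X`` (also the typographic
tilde ``∼``) map to AND, OR, NOT and NEAR/X respectively. Operators are
case-insensitive. Adjacent bare words form an exact-adjacency phrase.

The parser produces a small immutable AST (:class:`Term`, :class:`Near`,
:class:`Then`, :class:`And`, :class:`Or`, :class:`Not`, :class:`ClassRef`)
that the compiler in :mod:`radex.regex_compile` turns into word-boundary
aware regular expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

__all__ = [
    "Term",
    "ClassRef",
    "Near",
    "Then",
    "And",
    "Or",
    "Not",
    "QueryNode",
    "Token",
    "ParseError",
    "tokenize",
    "parse",
    "parse_query",
    "to_string",
    "validate_strategy",
]


# --------------------------------------------------------------------------- #
# AST node types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class Term:
    """A keyword pattern: one or more atoms (words) matched in exact adjacency.

    Each atom is a string of literal characters interleaved with the
    modifiers ``*`` (zero or more word characters) and ``?`` (zero or one
    word character). Multi-atom terms denote an exact phrase such as
    ``thyroglossal cyst``.
    """

    atoms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.atoms or any(not a for a in self.atoms):
            raise ValueError("Term requires at least one non-empty atom")


@dataclass(frozen=True)
class ClassRef:
    """A quoted reference to a previously defined class label."""

    name: str


@dataclass(frozen=True)
class Near:
    """Order-independent proximity: operands within ``gap`` intervening words."""

    left: Term
    right: Term
    gap: int


@dataclass(frozen=True)
class Then:
    """Order-dependent proximity: ``left`` before ``right``, ``gap`` words apart."""

    left: Term
    right: Term
    gap: int


@dataclass(frozen=True)
class And:
    children: tuple["QueryNode", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("And requires >= 2 children")


@dataclass(frozen=True)
class Or:
    children: tuple["QueryNode", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("Or requires >= 2 children")


@dataclass(frozen=True)
class Not:
    child: "QueryNode"


QueryNode = Union[Term, ClassRef, Near, Then, And, Or, Not]


# --------------------------------------------------------------------------- #
# Errors and tokens
# --------------------------------------------------------------------------- #

ERROR_KINDS = frozenset(
    {
        "unmatched_parenthesis",
        "unexpected_symbol",
        "dangling_operator",
        "unknown_class_reference",
        "bad_gap",
    }
)


class ParseError(Exception):
    """A syntax or reference error in a search expression.

    Attributes
    ----------
    position : int
        Character index into the original expression.
    kind : str
        One of ``unmatched_parenthesis``, ``unexpected_symbol``,
        ``dangling_operator``, ``unknown_class_reference``, ``bad_gap``.
    class_name : str or None
        Set by :func:`validate_strategy` to the offending class.
    """

    def __init__(self, position: int, kind: str, message: str,
                 class_name: Optional[str] = None) -> None:
        assert kind in ERROR_KINDS, kind
        self.position = position
        self.kind = kind
        self.message = message
        self.class_name = class_name
        super().__init__(message)

    def __str__(self) -> str:
        prefix = f"[{self.class_name}] " if self.class_name else ""
        return f"{prefix}{self.kind} at position {self.position}: {self.message}"


@dataclass(frozen=True)
class Token:
    kind: str          # TERM, CLASSREF, LPAREN, RPAREN, AND, OR, NOT, EXCEPT, NEAR, THEN
    value: object      # term text / class name / gap int / None
    pos: int           # character offset in the source expression


# Typographic variants normalised before scanning (Unicode minus the ASCII
# forms shows up in copy-pasted strategies).
_QUOTE_CHARS = "“”„″˝"   # curly/double-prime quotes
_TILDE_CHARS = "∼˜～"               # ∼ ˜ ～
_NOT_CHARS = "¬"                             # ¬

_VERBOSE_OPS = {"AND": "AND", "OR": "OR", "NOT": "NOT", "EXCEPT": "EXCEPT"}


def _is_term_char(ch: str) -> bool:
    return ch.isalnum() or ch in "*?"


def tokenize(expression: str) -> list[Token]:
    """Scan a search expression into a token stream.

    Both verbose (``AND``, ``NEAR/2``) and shorthand (``&``, ``~2``)
    spellings produce identical tokens. Raises :class:`ParseError` with kind
    ``unexpected_symbol`` for characters outside the grammar and ``bad_gap``
    for a proximity operator without a valid non-negative integer gap.
    """
    tokens: list[Token] = []
    i, n = 0, len(expression)
    while i < n:
        ch = expression[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "(":
            tokens.append(Token("LPAREN", None, i))
            i += 1
        elif ch == ")":
            tokens.append(Token("RPAREN", None, i))
            i += 1
        elif ch == "&":
            tokens.append(Token("AND", None, i))
            i += 1
        elif ch == "|":
            tokens.append(Token("OR", None, i))
            i += 1
        elif ch in _NOT_CHARS:
            tokens.append(Token("NOT", None, i))
            i += 1
        elif ch == "~" or ch in _TILDE_CHARS:
            start = i
            i += 1
            while i < n and expression[i].isspace():
                i += 1
            j = i
            while j < n and expression[j].isdigit():
                j += 1
            if j == i:
                raise ParseError(start, "bad_gap",
                                 "proximity '~' must be followed by an integer gap")
            tokens.append(Token("NEAR", int(expression[i:j]), start))
            i = j
        elif ch == '"' or ch in _QUOTE_CHARS:
            start = i
            i += 1
            j = i
            while j < n and expression[j] != '"' and expression[j] not in _QUOTE_CHARS:
                j += 1
            if j >= n:
                raise ParseError(start, "unexpected_symbol",
                                 "unterminated class-reference quote")
            name = expression[i:j].strip()
            if not name:
                raise ParseError(start, "unexpected_symbol",
                                 "empty class reference")
            tokens.append(Token("CLASSREF", name, start))
            i = j + 1
        elif _is_term_char(ch):
            start = i
            j = i
            while j < n and _is_term_char(expression[j]):
                j += 1
            word = expression[start:j]
            upper = word.upper()
            if upper in _VERBOSE_OPS:
                tokens.append(Token(_VERBOSE_OPS[upper], None, start))
                i = j
            elif upper in ("NEAR", "THEN") and j < n and expression[j] == "/":
                k = j + 1
                m = k
                while m < n and expression[m].isdigit():
                    m += 1
                if m == k:
                    raise ParseError(start, "bad_gap",
                                     f"{upper}/ requires an integer gap")
                tokens.append(Token(upper, int(expression[k:m]), start))
                i = m
            elif upper in ("NEAR", "THEN"):
                raise ParseError(start, "bad_gap",
                                 f"{upper} requires a '/X' gap, e.g. {upper}/2")
            else:
                tokens.append(Token("TERM", word, start))
                i = j
        else:
            raise ParseError(i, "unexpected_symbol",
                             f"unexpected symbol {ch!r}")
    if not tokens:
        raise ParseError(0, "dangling_operator", "empty expression")
    return tokens


# --------------------------------------------------------------------------- #
# Recursive-descent parser (precedence: NOT > AND > OR; proximity is part of
# a term-level pattern and binds tighter than NOT)
# --------------------------------------------------------------------------- #

class _Parser:
    def __init__(self, tokens: list[Token], source_len: int) -> None:
        self.tokens = tokens
        self.i = 0
        self.end = source_len

    def peek(self) -> Optional[Token]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> Optional[Token]:
        tok = self.peek()
        if tok is not None:
            self.i += 1
        return tok

    def parse(self) -> QueryNode:
        node = self.or_expr()
        tok = self.peek()
        if tok is not None:
            if tok.kind in ("RPAREN", "LPAREN"):
                raise ParseError(tok.pos, "unmatched_parenthesis",
                                 f"unmatched {'closing' if tok.kind == 'RPAREN' else 'opening'} parenthesis")
            raise ParseError(tok.pos, "dangling_operator",
                             f"unexpected trailing {tok.kind}")
        return node

    def or_expr(self) -> QueryNode:
        children = [self.and_expr()]
        while (tok := self.peek()) is not None and tok.kind == "OR":
            self.next()
            children.append(self.and_expr())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def and_expr(self) -> QueryNode:
        children = [self.unary()]
        while (tok := self.peek()) is not None and tok.kind in ("AND", "EXCEPT"):
            self.next()
            operand = self.unary()
            # EXCEPT desugars at parse time; evaluation never sees it.
            children.append(Not(operand) if tok.kind == "EXCEPT" else operand)
        return children[0] if len(children) == 1 else And(tuple(children))

    def unary(self) -> QueryNode:
        tok = self.peek()
        if tok is not None and tok.kind == "NOT":
            self.next()
            return Not(self.unary())
        return self.proximity()

    def proximity(self) -> QueryNode:
        left = self.primary()
        tok = self.peek()
        if tok is not None and tok.kind in ("NEAR", "THEN"):
            op = self.next()
            assert op is not None
            gap = op.value
            if not isinstance(gap, int) or gap < 0:
                raise ParseError(op.pos, "bad_gap", f"invalid gap {gap!r}")
            if not isinstance(left, Term):
                raise ParseError(op.pos, "dangling_operator",
                                 f"{op.kind}/{gap} requires keyword-term operands")
            right = self.primary()
            if not isinstance(right, Term):
                raise ParseError(op.pos, "dangling_operator",
                                 f"{op.kind}/{gap} requires keyword-term operands")
            node = Near(left, right, gap) if op.kind == "NEAR" else Then(left, right, gap)
            nxt = self.peek()
            if nxt is not None and nxt.kind in ("NEAR", "THEN"):
                raise ParseError(nxt.pos, "dangling_operator",
                                 "proximity operators cannot be chained; parenthesise")
            return node
        return left

    def primary(self) -> QueryNode:
        tok = self.peek()
        if tok is None:
            raise ParseError(self.end, "dangling_operator",
                             "operator with a missing operand")
        if tok.kind == "TERM":
            atoms = []
            while (t := self.peek()) is not None and t.kind == "TERM":
                self.next()
                atoms.append(t.value)
            return Term(tuple(atoms))  # adjacent words form an exact phrase
        if tok.kind == "CLASSREF":
            self.next()
            return ClassRef(tok.value)
        if tok.kind == "LPAREN":
            self.next()
            inner = self.or_expr()
            nxt = self.peek()
            if nxt is None:
                raise ParseError(tok.pos, "unmatched_parenthesis",
                                 "unmatched opening parenthesis")
            if nxt.kind != "RPAREN":
                raise ParseError(nxt.pos, "unmatched_parenthesis",
                                 "expected closing parenthesis")
            self.next()
            return inner
        if tok.kind == "RPAREN":
            raise ParseError(tok.pos, "unmatched_parenthesis",
                             "unmatched closing parenthesis")
        raise ParseError(tok.pos, "dangling_operator",
                         f"operator {tok.kind} with a missing operand")


def parse(tokens: list[Token], source_len: Optional[int] = None) -> QueryNode:
    """Parse a token stream into a query AST.

    Precedence is NOT > AND > OR, proximity binds tighter than NOT,
    parentheses override, and EXCEPT desugars to ``AND NOT``.
    """
    if source_len is None:
        source_len = max((t.pos for t in tokens), default=0) + 1
    return _Parser(tokens, source_len).parse()


def parse_query(expression: str) -> QueryNode:
    """Tokenize and parse an expression in one step."""
    return parse(tokenize(expression), source_len=len(expression))


# --------------------------------------------------------------------------- #
# Pretty printer
# --------------------------------------------------------------------------- #

def _fmt(node: QueryNode) -> str:
    if isinstance(node, Term):
        return " ".join(node.atoms)
    if isinstance(node, ClassRef):
        return f'"{node.name}"'
    if isinstance(node, Near):
        return f"({_fmt(node.left)} NEAR/{node.gap} {_fmt(node.right)})"
    if isinstance(node, Then):
        return f"({_fmt(node.left)} THEN/{node.gap} {_fmt(node.right)})"
    if isinstance(node, Not):
        return f"NOT ({_fmt(node.child)})"
    op = " AND " if isinstance(node, And) else " OR "
    return "(" + op.join(_fmt(c) for c in node.children) + ")"


def to_string(node: QueryNode) -> str:
    """Render an AST back to query syntax; ``parse_query(to_string(n))`` is
    structurally identical to ``n``."""
    return _fmt(node)


# --------------------------------------------------------------------------- #
# Strategy validation
# --------------------------------------------------------------------------- #

def iter_class_refs(node: QueryNode) -> Iterable[str]:
    """Yield every class-reference name in the tree."""
    if isinstance(node, ClassRef):
        yield node.name
    elif isinstance(node, (And, Or)):
        for c in node.children:
            yield from iter_class_refs(c)
    elif isinstance(node, Not):
        yield from iter_class_refs(node.child)


def validate_strategy(strategy) -> list[ParseError]:
    """Validate every class of a strategy; returns accumulated errors.

    A strategy is valid iff every class query parses, every quoted class
    reference resolves to a class defined *earlier* in the strategy (which
    also rules out cyclic derived-class definitions), and post-processing
    rules reference defined classes. Errors are returned, not raised, each
    carrying the offending class name.
    """
    errors: list[ParseError] = []
    defined: list[str] = []
    for cls in strategy.classes:
        query = getattr(cls, "query", None)
        node = None
        if isinstance(query, str):
            try:
                node = parse_query(query)
            except ParseError as exc:
                exc.class_name = cls.name
                errors.append(exc)
        else:
            node = query
        if node is not None:
            for ref in iter_class_refs(node):
                if ref not in defined:
                    hint = ("cyclic or forward" if ref == cls.name
                            else "unknown or later-defined")
                    errors.append(
                        ParseError(0, "unknown_class_reference",
                                   f'{hint} class reference "{ref}"',
                                   class_name=cls.name))
        defined.append(cls.name)
    for rule in getattr(strategy, "post_rules", []) or []:
        for name in (rule.if_class, rule.then_class):
            if name not in defined:
                errors.append(
                    ParseError(0, "unknown_class_reference",
                               f'post-processing rule references undefined class "{name}"',
                               class_name=name))
    return errors
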