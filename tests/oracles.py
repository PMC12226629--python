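"""Independent oracles for property tests.

These deliberately avoid the package's compilation path: term matching is a
hand-rolled character-level matcher, proximity is token-window enumeration,
and boolean connectives are plain set semantics over token streams. They
exist so the recursive regex evaluator can be checked against a second,
structurally different implementation.
"""

from __future__ import annotations

import random
from functools import lru_cache

from radex.query_lang import And, Near, Not, Or, Term, Then, QueryNode


def tokenize_text(text: str) -> list[str]:
    """Split standardised text into word tokens (alphanumeric runs)."""
    tokens: list[str] = []
    current: list[str] = []
    for ch in text:
        if ch.isalnum() or ch == "_":
            current.append(ch.lower())
        elif current:
            tokens.append("".join(current))
            current = []
    if current:
        tokens.append("".join(current))
    return tokens


@lru_cache(maxsize=None)
def atom_matches(atom: str, token: str) -> bool:
    """Does a wildcard atom consume the whole token? '*' = 0+ word chars,
    '?' = 0..1 word chars, otherwise literal (case-insensitive)."""
    atom = atom.lower()
    token = token.lower()

    def rec(pi: int, ti: int) -> bool:
        if pi == len(atom):
            return ti == len(token)
        ch = atom[pi]
        if ch == "*":
            return any(rec(pi + 1, k) for k in range(ti, len(token) + 1))
        if ch == "?":
            return rec(pi + 1, ti) or (ti < len(token) and rec(pi + 1, ti + 1))
        return ti < len(token) and token[ti] == ch and rec(pi + 1, ti + 1)

    return rec(0, 0)


def term_occurrences(term: Term, tokens: list[str]) -> list[tuple[int, int]]:
    """Token ranges [i, j] (inclusive) where the phrase occurs."""
    k = len(term.atoms)
    out = []
    for i in range(len(tokens) - k + 1):
        if all(atom_matches(a, tokens[i + d]) for d, a in enumerate(term.atoms)):
            out.append((i, i + k - 1))
    return out


def brute_force_present(node: QueryNode, tokens: list[str]) -> bool:
    """Set-semantics presence of a query over one token stream."""
    if isinstance(node, Term):
        return bool(term_occurrences(node, tokens))
    if isinstance(node, (Near, Then)):
        left = term_occurrences(node.left, tokens)
        right = term_occurrences(node.right, tokens)
        for i1, j1 in left:
            for i2, j2 in right:
                if i2 > j1 and i2 - j1 - 1 <= node.gap:
                    return True
                if isinstance(node, Near) and i1 > j2 and i1 - j2 - 1 <= node.gap:
                    return True
        return False
    if isinstance(node, And):
        return all(brute_force_present(c, tokens) for c in node.children)
    if isinstance(node, Or):
        return any(brute_force_present(c, tokens) for c in node.children)
    if isinstance(node, Not):
        return not brute_force_present(node.child, tokens)
    raise TypeError(node)


# --------------------------------------------------------------------------- #
# Random generators
# --------------------------------------------------------------------------- #

DEFAULT_VOCAB = ("nodule", "nodules", "thyroid", "cyst", "gland",
                 "lymph", "node", "left")


def random_term(rng: random.Random, vocab=DEFAULT_VOCAB) -> Term:
    n_atoms = 1 if rng.random() < 0.8 else 2
    atoms = []
    for _ in range(n_atoms):
        word = rng.choice(vocab)
        style = rng.randrange(5)
        if style == 1 and len(word) > 3:
            word = word[: rng.randint(3, len(word) - 1)] + "*"
        elif style == 2 and len(word) > 3:
            word = word[:-1] + "?"
        elif style == 3:
            word = "*" + word[rng.randint(1, len(word) - 1):]
        atoms.append(word)
    return Term(tuple(atoms))


def random_query(rng: random.Random, max_ops: int = 5,
                 vocab=DEFAULT_VOCAB) -> QueryNode:
    """A random query with at most ``max_ops`` operators."""
    if max_ops <= 0:
        return random_term(rng, vocab)
    choice = rng.randrange(6)
    if choice == 0:
        return random_term(rng, vocab)
    if choice == 1:
        left = random_term(rng, vocab)
        right = random_term(rng, vocab)
        gap = rng.randint(0, 3)
        return (Near if rng.random() < 0.5 else Then)(left, right, gap)
    if choice == 2:
        return Not(random_query(rng, max_ops - 1, vocab))
    n = rng.randint(2, 3)
    budget = max_ops - 1
    children = []
    for _ in range(n):
        take = rng.randint(0, budget)
        children.append(random_query(rng, take, vocab))
        budget -= take
    return (And if choice in (3, 4) else Or)(tuple(children))


def random_sentence(rng: random.Random, vocab=DEFAULT_VOCAB,
                    max_len: int = 10) -> str:
    return " ".join(rng.choice(vocab) for _ in range(rng.randint(0, max_len)))


# --------------------------------------------------------------------------- #
# Boolean precedence oracle: translate a flat expression to Python, whose
# not/and/or precedence (not > and > or) matches the query grammar.
# --------------------------------------------------------------------------- #

def random_bool_expression(rng: random.Random, n_atoms: int) -> list[str]:
    """A random flat word list over atoms a..f, AND/OR/NOT and parentheses,
    always syntactically valid."""
    atoms = "abcdef"[:n_atoms]
    out: list[str] = []

    def operand(depth: int) -> None:
        while rng.random() < 0.3:
            out.append("NOT")
        if depth < 2 and rng.random() < 0.25:
            out.append("(")
            expression(depth + 1)
            out.append(")")
        else:
            out.append(rng.choice(atoms))

    def expression(depth: int) -> None:
        operand(depth)
        for _ in range(rng.randint(0, 2)):
            out.append(rng.choice(("AND", "OR")))
            operand(depth)

    expression(0)
    return out


def python_truth(words: list[str], assignment: dict[str, bool]) -> bool:
    """Evaluate the flat expression with Python's boolean operators."""
    py = " ".join(
        {"AND": "and", "OR": "or", "NOT": "not"}.get(w, w) for w in words)
    return bool(eval(py, {"__builtins__": {}}, dict(assignment)))  # noqa: S307


def ast_truth(node: QueryNode, assignment: dict[str, bool]) -> bool:
    """Evaluate a parsed boolean query under an atom assignment."""
    if isinstance(node, Term):
        return assignment["".join(node.atoms)]
    if isinstance(node, And):
        return all(ast_truth(c, assignment) for c in node.children)
    if isinstance(node, Or):
        return any(ast_truth(c, assignment) for c in node.children)
    if isinstance(node, Not):
        return not ast_truth(node.child, assignment)
    raise TypeError(node)


# --------------------------------------------------------------------------- #
# Random AST generator for round-trip tests (words avoid operator spellings)
# --------------------------------------------------------------------------- #

_RT_WORDS = ("alpha", "beta", "gamma", "delta", "nod*", "cys?t", "*oma", "u2")


def random_ast(rng: random.Random, depth: int = 3) -> QueryNode:
    choice = rng.randrange(6) if depth > 0 else 0
    if choice <= 1:
        n_atoms = rng.randint(1, 2)
        return Term(tuple(rng.choice(_RT_WORDS) for _ in range(n_atoms)))
    if choice == 2:
        return Near(random_ast(rng, 0), random_ast(rng, 0), rng.randint(0, 9))
    if choice == 3:
        return Then(random_ast(rng, 0), random_ast(rng, 0), rng.randint(0, 9))
    if choice == 4:
        return Not(random_ast(rng, depth - 1))
    cls = And if rng.random() < 0.5 else Or
    return cls(tuple(random_ast(rng, depth - 1)
                     for _ in range(rng.randint(2, 3))))
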