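"""NegEx-style negation detection for match spans.

A finding mention is negated when a pre-negation trigger ("no", "without",
"no evidence of"...) occurs within a bounded number of tokens before it, or
a post-negation trigger ("not seen", "ruled out"...) within the bound after
it, with no scope terminator ("but", "however"...) in between. Pseudo
triggers ("not only", "no change") look like triggers but never negate.
Negation never crosses a sentence boundary; detection runs on one
standardised sentence at a time.

Hypothetical/uncertainty phrasings ("possible", "query", "?cancer") are
deliberately NOT negation: an optional uncertainty lexicon can flag such
matches for review without suppressing them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .regex_compile import MatchSpan

__all__ = [
    "NegationLexicon",
    "NegatedSpan",
    "detect_negation",
    "load_lexicon",
    "default_lexicon",
]

DEFAULT_SCOPE = 5  # classic NegEx window, in tokens


@dataclass
class NegationLexicon:
    """Trigger phrases and scope for rule-based negation detection."""

    pre_triggers: tuple[str, ...]
    post_triggers: tuple[str, ...]
    pseudo_triggers: tuple[str, ...] = ()
    terminators: tuple[str, ...] = ()
    uncertainty_triggers: tuple[str, ...] = ()
    scope: int = DEFAULT_SCOPE

    def __post_init__(self) -> None:
        if self.scope < 1:
            raise ValueError("negation scope must be >= 1 token")
        for name in ("pre_triggers", "post_triggers", "pseudo_triggers",
                     "terminators", "uncertainty_triggers"):
            setattr(self, name, tuple(t.lower() for t in getattr(self, name)))


@dataclass(frozen=True)
class NegatedSpan:
    """A match span with its negation verdict and the trigger responsible.

    ``trigger_start``/``trigger_end`` give the trigger phrase's character
    span in the same (standardised-sentence) coordinates as the match span,
    so highlighting can mark the negation cue distinctly.
    """

    span: MatchSpan
    negated: bool
    trigger: Optional[str] = None
    trigger_start: Optional[int] = None
    trigger_end: Optional[int] = None
    uncertain: bool = False


_TOKEN_RX = re.compile(r"\w+")


def _phrase_occurrences(tokens: list[str], phrase: str) -> list[tuple[int, int]]:
    """Token-index half-open ranges where a (possibly multi-word) phrase
    occurs."""
    words = phrase.split()
    k = len(words)
    return [(i, i + k) for i in range(len(tokens) - k + 1)
            if tokens[i:i + k] == words]


def detect_negation(sentence: str,
                    spans: Sequence[MatchSpan],
                    lexicon: NegationLexicon) -> list[NegatedSpan]:
    """Classify each match span of one standardised sentence as negated or not.

    A span is negated iff a pre-trigger ends within ``lexicon.scope`` tokens
    before its first token, or a post-trigger starts within scope after its
    last token, with no terminator token between trigger and span. Where
    several triggers apply, the longest (most tokens, then most characters)
    wins. Trigger occurrences that are part of a pseudo-trigger phrase are
    ignored.
    """
    token_matches = list(_TOKEN_RX.finditer(sentence))
    tokens = [m.group(0) for m in token_matches]

    pseudo_cover: set[int] = set()
    for phrase in lexicon.pseudo_triggers:
        for a, b in _phrase_occurrences(tokens, phrase):
            pseudo_cover.update(range(a, b))

    def trigger_sites(phrases: Iterable[str],
                      pseudo_guard: bool = True) -> list[tuple[int, int, str]]:
        sites = []
        for phrase in phrases:
            for a, b in _phrase_occurrences(tokens, phrase):
                if pseudo_guard and any(t in pseudo_cover for t in range(a, b)):
                    continue
                sites.append((a, b, phrase))
        return sites

    pre_sites = trigger_sites(lexicon.pre_triggers)
    post_sites = trigger_sites(lexicon.post_triggers)
    # pseudo-triggers guard negation only; an uncertainty cue may share them
    unc_sites = trigger_sites(lexicon.uncertainty_triggers, pseudo_guard=False)
    term_idx = {a for t in lexicon.terminators
                for a, b in _phrase_occurrences(tokens, t)}

    def token_range(span: MatchSpan) -> tuple[int, int]:
        first = last = None
        for i, m in enumerate(token_matches):
            if m.end() > span.start and m.start() < span.end:
                if first is None:
                    first = i
                last = i
        if first is None:  # span covers no token (should not happen)
            return (0, -1)
        return first, last

    out: list[NegatedSpan] = []
    for span in spans:
        first, last = token_range(span)
        # (n_words, n_chars, phrase, a, b) — longest trigger wins
        candidates: list[tuple[int, int, str, int, int]] = []
        uncertain = False
        if last >= first:
            for a, b, phrase in pre_sites:
                if b <= first and first - b <= lexicon.scope:
                    if not any(b <= t < first for t in term_idx):
                        candidates.append((b - a, len(phrase), phrase, a, b))
            for a, b, phrase in post_sites:
                if a > last and a - last - 1 <= lexicon.scope:
                    if not any(last < t < a for t in term_idx):
                        candidates.append((b - a, len(phrase), phrase, a, b))
            # uncertainty cues flag a span for review but never suppress it
            for a, b, phrase in unc_sites:
                if (b <= first and first - b <= lexicon.scope) or \
                        (a > last and a - last - 1 <= lexicon.scope):
                    uncertain = True
        if candidates:
            _, _, best, a, b = max(candidates)
            t_start = token_matches[a].start()
            t_end = token_matches[b - 1].end()
            out.append(NegatedSpan(span, True, best, t_start, t_end,
                                   uncertain=uncertain))
        else:
            out.append(NegatedSpan(span, False, None, uncertain=uncertain))
    return out


# --------------------------------------------------------------------------- #
# Lexicon file format: one trigger per line, "<TAG>\t<phrase>",
# TAG in {PRE, POST, PSEUDO, TERM}; '#' comments; optional "SCOPE\t<int>".
# --------------------------------------------------------------------------- #

def load_lexicon(path: Union[str, Path]) -> NegationLexicon:
    """Load a negation lexicon from a plain-text trigger file."""
    groups: dict[str, list[str]] = {"PRE": [], "POST": [], "PSEUDO": [],
                                    "TERM": [], "UNC": []}
    scope = DEFAULT_SCOPE
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            tag, phrase = line.split(None, 1)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: expected '<TAG> <phrase>'") from exc
        tag = tag.upper()
        if tag == "SCOPE":
            scope = int(phrase)
        elif tag in groups:
            groups[tag].append(phrase.strip().lower())
        else:
            raise ValueError(f"{path}:{lineno}: unknown tag {tag!r}")
    return NegationLexicon(
        pre_triggers=tuple(groups["PRE"]),
        post_triggers=tuple(groups["POST"]),
        pseudo_triggers=tuple(groups["PSEUDO"]),
        terminators=tuple(groups["TERM"]),
        uncertainty_triggers=tuple(groups["UNC"]),
        scope=scope,
    )


def default_lexicon() -> NegationLexicon:
    """The packaged lexicon, seeded with the standard NegEx trigger set."""
    ref = resources.files("radex").joinpath("data/negex_triggers.txt")
    with resources.as_file(ref) as path:
        return load_lexicon(path)
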