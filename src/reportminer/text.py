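"""Tokenization, stemming and negation tagging of report text.

The pipeline converts one report into the *set* of distinct terms it
mentions: lowercase alphabetic tokens are stemmed, and a token falling
inside the scope of a negation cue ("no", "without", ...) becomes a
separate negated term rendered as ``[no] <surface>``. Presence, not
multiplicity, is what matters downstream (document-frequency counting), so
``process_report`` returns a set. A term and its negated twin are distinct
and may co-occur in one report ("no discrete mass but discrete
calcification").

Negation scope is a simple proximity window: a cue negates the following
``scope_window`` tokens, cut short by sentence punctuation, an adversative
conjunction, or the next cue — a minimal NegEx-style realization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .stemming import stem

__all__ = ["Term", "NegationConfig", "tokenize", "stem", "tag_negation", "process_report"]

#: sentinel emitted for scope-terminating punctuation
TERMINATOR = "<TERM>"

_TOKEN_RE = re.compile(r"[a-z]+|[.;:]")


@dataclass(frozen=True)
class Term:
    """A stemmed, negation-flagged vocabulary item.

    Identity (equality/hashing) is the ``(stem, negated)`` pair; ``surface``
    records the raw token that produced the term and is used only to pick a
    human-readable display form.
    """

    stem: str
    negated: bool
    surface: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.stem or self.stem != self.stem.lower() or " " in self.stem:
            raise ValueError(f"invalid stem {self.stem!r}")

    @property
    def display(self) -> str:
        surface = self.surface or self.stem
        return f"[no] {surface}" if self.negated else surface

    @staticmethod
    def render(surface: str, negated: bool) -> str:
        return f"[no] {surface}" if negated else surface


@dataclass(frozen=True)
class NegationConfig:
    """Cue lexicon and proximity window for negation tagging.

    ``cues`` are single-token cue words; ``scope_window`` is how many tokens
    after a cue are negated; ``terminators`` are tokens that end a scope
    early (punctuation sentinels are always terminators).
    """

    cues: tuple[str, ...] = ("no", "not", "without", "absent", "free of", "negative for")
    scope_window: int = 3
    terminators: tuple[str, ...] = ("but", "however")

    def __post_init__(self) -> None:
        if self.scope_window < 1:
            raise ValueError("scope_window must be >= 1")
        if any(not c.strip() for c in self.cues):
            raise ValueError("cues must be non-empty phrases")

    @property
    def cue_phrases(self) -> tuple[tuple[str, ...], ...]:
        """Cues as token tuples, longest first (greedy phrase matching)."""
        phrases = [tuple(c.lower().split()) for c in self.cues]
        return tuple(sorted(phrases, key=len, reverse=True))


def tokenize(text: str) -> list[str]:
    """Lowercase alphabetic tokens in document order, with punctuation kept
    as ``<TERM>`` sentinels (needed to bound negation scopes).

    Tokens containing digits are dropped entirely (measurements, series
    numbers, dates), as are single-character tokens.
    """
    out: list[str] = []
    # split on whitespace first so "t2" is seen as one digit-bearing word
    for raw in text.lower().split():
        if any(ch.isdigit() for ch in re.sub(r"[^a-z0-9]", "", raw)):
            # still emit any trailing sentence punctuation
            if raw and raw[-1] in ".;:":
                out.append(TERMINATOR)
            continue
        for piece in _TOKEN_RE.findall(raw):
            if piece in ".;:":
                out.append(TERMINATOR)
            elif len(piece) >= 2:
                out.append(piece)
    return out


def tag_negation(tokens: list[str], config: NegationConfig | None = None) -> list[Term]:
    """Turn a token stream into an ordered list of terms with negation flags.

    A token is negated iff it lies within ``scope_window`` tokens after a
    cue; any terminator or a new cue resets the scope. Cues and terminators
    themselves emit no term.
    """
    if config is None:
        config = NegationConfig()
    phrases = config.cue_phrases
    terminators = set(config.terminators) | {TERMINATOR}
    remaining = 0  # tokens left in the current negation scope
    terms: list[Term] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok in terminators:
            remaining = 0
            i += 1
            continue
        matched = next(
            (p for p in phrases if tuple(tokens[i : i + len(p)]) == p), None
        )
        if matched is not None:
            remaining = config.scope_window
            i += len(matched)
            continue
        negated = remaining > 0
        if remaining:
            remaining -= 1
        terms.append(Term(stem=stem(tok), negated=negated, surface=tok))
        i += 1
    return terms


def process_report(text: str, config: NegationConfig | None = None) -> set[Term]:
    """The distinct term set of one report (document-frequency semantics)."""
    return set(tag_negation(tokenize(text), config))
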