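"""Shared low-level text machinery: tokenization, sentence splitting,
cleaning, stopwords, and a dependency-free fallback lemmatizer.

Keyword matching everywhere in the package operates on the token
sequences produced by :func:`tokenize`, so a hyphenated keyword such as
``e-juice`` is the token sequence ``("e", "juice")`` and is distinct
from the single token ``ejuice``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

__all__ = [
    "Token",
    "tokenize",
    "split_sentences",
    "clean_text",
    "keyword_tokens",
    "is_probably_english",
    "STOPWORDS",
    "simple_lemmatize",
]

_TOKEN_RE = re.compile(r"[A-Za-z0-9']+")
_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_EMAIL_RE = re.compile(r"\b[\w.+-]+@[\w-]+\.[\w.-]+\b")
_SENT_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)|\n+")


@dataclass(frozen=True)
class Token:
    """A lowercased word token with its character span in the source text."""

    text: str
    start: int
    end: int


def tokenize(text: str) -> list[Token]:
    """Unicode word tokens (letters, digits, apostrophes), lowercased,
    with character offsets into the original string."""
    return [
        Token(m.group(0).lower(), m.start(), m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences.

    Boundaries are runs of ``. ! ?`` followed by whitespace or end of
    text; a newline is always a boundary. Empty spans are dropped.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY_RE.finditer(text):
        end = m.end()
        if text[start:end].strip():
            spans.append((start, end))
        start = end
    if text[start:].strip():
        spans.append((start, len(text)))
    return spans


def sentence_index_of(position: int, spans: Sequence[tuple[int, int]]) -> int:
    """Index of the sentence span containing character ``position``."""
    for i, (s, e) in enumerate(spans):
        if s <= position < e:
            return i
    return max(len(spans) - 1, 0)


def clean_text(text: str) -> str:
    """Strip URLs and email addresses; collapse the leftover whitespace."""
    text = _URL_RE.sub(" ", text)
    text = _EMAIL_RE.sub(" ", text)
    return re.sub(r"[ \t]{2,}", " ", text).strip()


def keyword_tokens(keyword: str) -> tuple[str, ...]:
    """Normalize a keyword to the token tuple it must match contiguously."""
    return tuple(t.text for t in tokenize(keyword))


_UNICODE_WORD_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def is_probably_english(text: str, min_ascii_fraction: float = 0.5) -> bool:
    """Cheap language heuristic: at least ``min_ascii_fraction`` of
    alphabetic word tokens (counted over the full Unicode range, so
    non-Latin script is visible to the denominator) must be pure ASCII.
    A pluggable detector can replace this anywhere it is used."""
    tokens = _UNICODE_WORD_RE.findall(text)
    if not tokens:
        return False
    n_ascii = sum(1 for t in tokens if t.isascii())
    return n_ascii / len(tokens) >= min_ascii_fraction


LanguageFilter = Callable[[str], bool]

# Compact English stopword list (articles, pronouns, auxiliaries,
# prepositions, conjunctions, common adverbs) used by the FIM and topic
# stages. Deliberately small; callers may pass their own set.
STOPWORDS: frozenset[str] = frozenset(
    """
    a about above after again against all am an and any are aren't as at be
    because been before being below between both but by can can't cannot
    could couldn't did didn't do does doesn't doing don't down during each
    few for from further had hadn't has hasn't have haven't having he he'd
    he'll he's her here here's hers herself him himself his how how's i i'd
    i'll i'm i've if in into is isn't it it's its itself let's me more most
    mustn't my myself no nor not of off on once only or other ought our ours
    ourselves out over own same shan't she she'd she'll she's should
    shouldn't so some such than that that's the their theirs them themselves
    then there there's these they they'd they'll they're they've this those
    through to too under until up very was wasn't we we'd we'll we're we've
    were weren't what what's when when's where where's which while who who's
    whom why why's with won't would wouldn't you you'd you'll you're you've
    your yours yourself yourselves
    """.split()
)


def simple_lemmatize(token: str) -> str:
    """Rule-based suffix stripper used when no external lemmatizer is
    plugged in.

    Handles regular plurals and -ing/-ed verb forms; leaves short tokens
    and -ly adverbs alone. This is a deliberately conservative stand-in
    for a real lemmatizer, sufficient for the token-level tests here.
    """
    if len(token) <= 3 or not token.isalpha():
        return token
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("sses"):
        return token[:-2]
    if token.endswith("s") and not token.endswith(("ss", "us", "is")):
        token = token[:-1]
    if token.endswith("ing") and len(token) > 5:
        stem = token[:-3]
        if len(stem) >= 3 and stem[-1] == stem[-2]:  # coughing->cough, running->run
            stem = stem if stem[-2:] in ("ll", "ss") else stem[:-1] + stem[-1]
        if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in "aeiouls":
            stem = stem[:-1]
        return stem
    if token.endswith("ed") and len(token) > 4:
        stem = token[:-2]
        if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in "aeiouls":
            stem = stem[:-1]
        return stem
    return token


def lemmatize_all(tokens: Iterable[str],
                  lemmatizer: Callable[[str], str] | None = None) -> list[str]:
    f = lemmatizer or simple_lemmatize
    return [f(t) for t in tokens]
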