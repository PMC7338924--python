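"""Keyword taxonomies and corpus construction.

A corpus of social-media posts is reduced to topic subsets by matching
curated keyword lists: an e-cigarette list defines the working corpus,
a health list (nine symptom categories) and a flavor list (seven e-liquid
flavor categories) define subsets of it. Matching is case-insensitive on
token boundaries, multi-word keywords match as contiguous token sequences
and win over their subwords, and semantically ambiguous keywords (the
canonical example is "tobacco", which usually refers to combustible
products) survive only when a sentence-level context rule fires.
"""

from __future__ import annotations

import random
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

from ._text import (
    LanguageFilter,
    clean_text,
    is_probably_english,
    keyword_tokens,
    sentence_index_of,
    split_sentences,
    tokenize,
)

HEALTH_CATEGORIES = (
    "Respiratory", "Cardiovascular", "Neurological", "Psychological",
    "Digestive", "Mouth", "Throat", "Cancer", "Other",
)
FLAVOR_CATEGORIES = (
    "Fruit", "Menthol or Mint", "Tobacco", "Sweet", "Beverage", "Mixed", "Other",
)

_CANONICAL_CATEGORIES = {"health": HEALTH_CATEGORIES, "flavor": FLAVOR_CATEGORIES}


class TaxonomyError(ValueError):
    """Raised when a taxonomy fails validation or is used unvalidated."""


@dataclass(frozen=True)
class Post:
    """One social-media message (title and body concatenated)."""

    post_id: str
    user_id: str
    created_utc: int
    text: str


@dataclass(frozen=True)
class DisambiguationRule:
    """Sentence-level context rule for an ambiguous keyword.

    A match of ``ambiguous_keyword`` survives only if the sentence that
    contains it also contains at least one of ``context_keywords``.
    """

    ambiguous_keyword: str
    context_keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.context_keywords:
            raise TaxonomyError(
                f"disambiguation rule for {self.ambiguous_keyword!r} "
                "has no context keywords"
            )


@dataclass(frozen=True)
class MatchRecord:
    """A single keyword hit inside a post."""

    post_id: str
    taxonomy: str
    category: str
    keyword: str
    sentence_index: int


@dataclass
class KeywordTaxonomy:
    """A named keyword taxonomy: category -> keyword list, plus rules."""

    name: str
    categories: dict[str, list[str]]
    disambiguation_rules: list[DisambiguationRule] = field(default_factory=list)
    _validated: bool = field(default=False, repr=False)
    _index: dict | None = field(default=None, repr=False)

    def validate(self, strict: bool = True) -> "KeywordTaxonomy":
        """Check invariants; returns self so calls can be chained.

        With ``strict`` the health/flavor taxonomies must carry exactly
        their canonical category labels.
        """
        seen: dict[str, str] = {}
        for cat, keywords in self.categories.items():
            for kw in keywords:
                if kw != kw.lower():
                    raise TaxonomyError(f"keyword {kw!r} is not lowercase")
                if kw in seen and seen[kw] != cat:
                    raise TaxonomyError(
                        f"keyword {kw!r} appears in categories "
                        f"{seen[kw]!r} and {cat!r}"
                    )
                seen[kw] = cat
        if strict and self.name in _CANONICAL_CATEGORIES:
            expected = set(_CANONICAL_CATEGORIES[self.name])
            got = set(self.categories)
            if got != expected:
                raise TaxonomyError(
                    f"{self.name} taxonomy must have categories {sorted(expected)}, "
                    f"got {sorted(got)}"
                )
        rule_keywords = [r.ambiguous_keyword for r in self.disambiguation_rules]
        if len(rule_keywords) != len(set(rule_keywords)):
            raise TaxonomyError("duplicate disambiguation rules")
        self._validated = True
        self._index = None
        return self

    @property
    def validated(self) -> bool:
        return self._validated

    def all_keywords(self) -> list[str]:
        return [kw for kws in self.categories.values() for kw in kws]

    def category_of(self, keyword: str) -> str:
        for cat, kws in self.categories.items():
            if keyword in kws:
                return cat
        raise KeyError(keyword)

    # --- compiled matching index ------------------------------------
    def _compiled(self) -> dict:
        if self._index is None:
            by_first: dict[str, list[tuple[tuple[str, ...], str, str]]] = {}
            for cat, kws in self.categories.items():
                for kw in kws:
                    toks = keyword_tokens(kw)
                    if not toks:
                        continue
                    by_first.setdefault(toks[0], []).append((toks, kw, cat))
            for lst in by_first.values():
                lst.sort(key=lambda item: -len(item[0]))  # longest match first
            rules = {
                r.ambiguous_keyword: tuple(
                    keyword_tokens(c) for c in r.context_keywords
                )
                for r in self.disambiguation_rules
            }
            self._index = {"by_first": by_first, "rules": rules}
        return self._index


def _contains_sequence(tokens: Sequence[str], seq: tuple[str, ...]) -> bool:
    n = len(seq)
    if n == 0:
        return False
    return any(tuple(tokens[i : i + n]) == seq for i in range(len(tokens) - n + 1))


def match_keywords(post: Post, taxonomy: KeywordTaxonomy) -> list[MatchRecord]:
    """All surviving keyword hits of ``taxonomy`` in ``post``.

    One record per (keyword, occurrence); at any token position the
    longest matching keyword wins and shorter keywords starting inside
    it are suppressed. Records for an ambiguous keyword are emitted only
    when its sentence also contains a context keyword.
    """
    if not taxonomy.validated:
        raise TaxonomyError(
            f"taxonomy {taxonomy.name!r} must be validated before matching"
        )
    if not post.text:
        return []
    index = taxonomy._compiled()
    by_first = index["by_first"]
    rules: Mapping[str, tuple[tuple[str, ...], ...]] = index["rules"]

    spans = split_sentences(post.text)
    tokens = tokenize(post.text)
    words = [t.text for t in tokens]
    sent_of_token = [sentence_index_of(t.start, spans) for t in tokens]
    # token word lists per sentence, for rule checks
    sent_words: dict[int, list[str]] = {}
    for w, s in zip(words, sent_of_token):
        sent_words.setdefault(s, []).append(w)

    records: list[MatchRecord] = []
    i = 0
    while i < len(words):
        candidates = by_first.get(words[i], ())
        matched_len = 0
        for toks, kw, cat in candidates:
            if tuple(words[i : i + len(toks)]) == toks:
                sidx = sent_of_token[i]
                ctx = rules.get(kw)
                if ctx is not None:
                    swords = sent_words.get(sidx, [])
                    if not any(_contains_sequence(swords, c) for c in ctx):
                        continue  # rule failed; try shorter candidates
                records.append(
                    MatchRecord(post.post_id, taxonomy.name, cat, kw, sidx)
                )
                matched_len = len(toks)
                break
        i += matched_len if matched_len else 1
    return records


def filter_corpus(
    posts: Iterable[Post],
    taxonomy: KeywordTaxonomy,
    language_filter: LanguageFilter | None = is_probably_english,
    counters: dict[str, int] | None = None,
) -> Iterator[Post]:
    """Stream exactly the posts with at least one surviving keyword hit.

    Each emitted post carries its cleaned text (URLs and email addresses
    stripped); posts that are empty after cleaning or fail the pluggable
    language filter are dropped. Input order is preserved.
    """
    c = counters if counters is not None else {}
    c.setdefault("read", 0)
    c.setdefault("dropped_empty", 0)
    c.setdefault("dropped_language", 0)
    c.setdefault("dropped_no_match", 0)
    c.setdefault("kept", 0)
    for post in posts:
        c["read"] += 1
        text = clean_text(post.text or "")
        if not text:
            c["dropped_empty"] += 1
            continue
        if language_filter is not None and not language_filter(text):
            c["dropped_language"] += 1
            continue
        cleaned = Post(post.post_id, post.user_id, post.created_utc, text)
        if not match_keywords(cleaned, taxonomy):
            c["dropped_no_match"] += 1
            continue
        c["kept"] += 1
        yield cleaned


@dataclass(frozen=True)
class ClassifiedPost:
    """Category assignment of a post under the health and flavor taxonomies."""

    post_id: str
    health_categories: frozenset[str]
    flavor_categories: frozenset[str]
    health_keywords: Mapping[str, int]  # keyword -> occurrence count
    flavor_keywords: Mapping[str, int]


def classify_post(
    post: Post, health: KeywordTaxonomy, flavor: KeywordTaxonomy
) -> ClassifiedPost:
    """Union of surviving category hits plus keyword-level counts.

    Keyword counts are retained because downstream entry extraction
    keeps only posts with exactly one distinct flavor keyword.
    """
    h_recs = match_keywords(post, health)
    f_recs = match_keywords(post, flavor)
    return ClassifiedPost(
        post_id=post.post_id,
        health_categories=frozenset(r.category for r in h_recs),
        flavor_categories=frozenset(r.category for r in f_recs),
        health_keywords=dict(Counter(r.keyword for r in h_recs)),
        flavor_keywords=dict(Counter(r.keyword for r in f_recs)),
    )


@dataclass
class AuditSample:
    """A seeded sample of keyword-matching posts for manual precision audit."""

    keyword: str
    post_ids: list[str]
    highlights: list[str]  # the sentence containing the hit, per sampled post
    precision: float | None = None


def audit_filter_precision(
    posts: Sequence[Post],
    taxonomy: KeywordTaxonomy,
    keyword: str,
    n_sample: int = 100,
    seed: int = 0,
    labels: Sequence[bool] | None = None,
) -> AuditSample:
    """Draw matching posts for manual relevance labeling.

    Returns the sampled post ids with the sentence containing the first
    hit highlighted; when ``labels`` (one per sampled post) are supplied,
    precision = relevant / sample size is filled in.
    """
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")
    matching: list[tuple[Post, MatchRecord]] = []
    for post in posts:
        for rec in match_keywords(post, taxonomy):
            if rec.keyword == keyword:
                matching.append((post, rec))
                break
    if not matching:
        warnings.warn(f"keyword {keyword!r} matches no post; empty audit")
        return AuditSample(keyword, [], [])
    rng = random.Random(seed)
    k = min(n_sample, len(matching))
    sample = rng.sample(matching, k)
    ids, highlights = [], []
    for post, rec in sample:
        spans = split_sentences(post.text)
        s, e = spans[rec.sentence_index] if spans else (0, len(post.text))
        ids.append(post.post_id)
        highlights.append(post.text[s:e].strip())
    audit = AuditSample(keyword, ids, highlights)
    if labels is not None:
        if len(labels) != k:
            raise ValueError(f"expected {k} labels, got {len(labels)}")
        audit.precision = sum(map(bool, labels)) / k
    return audit
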