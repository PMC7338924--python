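"""Lexicon sentiment scoring with health-keyword neutralization.

Symptom words carry intrinsic negative valence ("headache", "cough"),
which would contaminate any measurement of how users *feel* about the
product they are discussing. Health keywords are therefore replaced by
a neutral placeholder before scoring; the remaining text is scored with
a VADER-style valence lexicon: raw valences are summed (negation flips
within a three-token window, exclamation/ALL-CAPS boosters optional)
and the sum ``s`` is squashed to [-1, 1] as ``s / sqrt(s^2 + 15)``.
Scores are discretized into positive / neutral / negative propensities
at the +-0.05 thresholds, and per-category positive-vs-negative
proportions are compared with pooled two-proportion z-tests under
Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._text import keyword_tokens, tokenize
from .taxonomy import Post

__all__ = [
    "load_lexicon",
    "bundled_lexicon",
    "LexiconScorer",
    "VaderBackend",
    "neutralize_keywords",
    "classify_propensity",
    "two_proportion_z_test",
    "bonferroni_adjust",
    "summarize_category",
    "sentiment_table",
    "CategorySentimentSummary",
]

NORMALIZATION_CONSTANT = 15.0
NEGATION_WINDOW = 3
NEGATION_FACTOR = -0.74
EXCLAMATION_BOOST = 0.292
MAX_EXCLAMATIONS = 4
CAPS_BOOST = 0.733

NEGATIONS = frozenset(
    "not no never neither nor cannot can't don't won't wont isn't doesn't "
    "didn't wasn't weren't ain't without hardly barely".split()
)


def load_lexicon(path) -> dict[str, float]:
    """Read a whitespace-separated token/valence lexicon (the reference
    VADER file format works: extra columns are ignored)."""
    lex: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                lex[parts[0].lower()] = float(parts[1])
            except (IndexError, ValueError):
                continue
    return lex


def bundled_lexicon() -> dict[str, float]:
    """The small synthetic lexicon shipped with the package."""
    ref = resources.files("vapelens") / "data" / "mini_lexicon.txt"
    with resources.as_file(ref) as path:
        return load_lexicon(path)


class LexiconScorer:
    """Hermetic lexicon scorer following the published compound-score
    design: valence sum with negation flip and optional boosters,
    squashed by ``s / sqrt(s^2 + C)`` with C = 15."""

    def __init__(
        self,
        lexicon: Mapping[str, float] | None = None,
        negation: bool = True,
        boosters: bool = True,
    ) -> None:
        self.lexicon = dict(lexicon) if lexicon is not None else bundled_lexicon()
        self.negation = negation
        self.boosters = boosters

    def score(self, text: str) -> float:
        if not text:
            return 0.0
        tokens = tokenize(text)
        words = [t.text for t in tokens]
        raw = [text[t.start : t.end] for t in tokens]
        all_caps_text = all(w.isupper() for w in raw if w.isalpha()) if raw else False
        s = 0.0
        for i, w in enumerate(words):
            v = self.lexicon.get(w)
            if v is None or v == 0.0:
                continue
            if (
                self.boosters
                and raw[i].isupper()
                and len(raw[i]) > 1
                and raw[i].isalpha()
                and not all_caps_text
            ):
                v += math.copysign(CAPS_BOOST, v)
            if self.negation and any(
                words[j] in NEGATIONS
                for j in range(max(0, i - NEGATION_WINDOW), i)
            ):
                v *= NEGATION_FACTOR
            s += v
        if self.boosters and s != 0.0:
            n_excl = min(text.count("!"), MAX_EXCLAMATIONS)
            s += math.copysign(n_excl * EXCLAMATION_BOOST, s)
        return s / math.sqrt(s * s + NORMALIZATION_CONSTANT)


class VaderBackend:
    """Adapter exposing the reference VADER implementation through the
    same ``score(text)`` interface. Requires the ``vaderSentiment``
    package, which is not bundled."""

    def __init__(self) -> None:
        try:
            from vaderSentiment.vaderSentiment import SentimentIntensityAnalyzer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the vaderSentiment package is required for VaderBackend"
            ) from exc
        self._analyzer = SentimentIntensityAnalyzer()

    def score(self, text: str) -> float:  # pragma: no cover - optional
        return self._analyzer.polarity_scores(text)["compound"]


def neutralize_keywords(
    text: str, keywords: Iterable[str], placeholder: str = "X"
) -> str:
    """Replace every token-boundary occurrence of a keyword with the
    placeholder. Multi-word keywords are replaced as single units;
    matching is case-insensitive; all other characters are untouched.
    Idempotent as long as the placeholder is not itself a keyword."""
    kw_tuples = sorted(
        {keyword_tokens(k) for k in keywords if k.strip()},
        key=len,
        reverse=True,
    )
    if not kw_tuples:
        return text
    tokens = tokenize(text)
    words = [t.text for t in tokens]
    replacements: list[tuple[int, int]] = []  # char spans
    i = 0
    while i < len(words):
        matched = 0
        for kt in kw_tuples:
            if tuple(words[i : i + len(kt)]) == kt:
                replacements.append((tokens[i].start, tokens[i + len(kt) - 1].end))
                matched = len(kt)
                break
        i += matched if matched else 1
    out = text
    for start, end in reversed(replacements):
        out = out[:start] + placeholder + out[end:]
    return out


def neutralizable_keywords(
    health_keywords: Iterable[str],
    lexicon: Mapping[str, float],
    widen_to_all: bool = False,
) -> list[str]:
    """Health keywords to neutralize: by default exactly those carrying
    nonzero valence in the scoring lexicon; optionally all of them."""
    kws = list(health_keywords)
    if widen_to_all:
        return kws
    return [
        k
        for k in kws
        if any(lexicon.get(tok, 0.0) != 0.0 for tok in keyword_tokens(k))
    ]


def classify_propensity(score: float) -> str:
    """positive if score >= +0.05, negative if score <= -0.05, else
    neutral (open interval)."""
    if not -1.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [-1, 1]")
    if score >= 0.05:
        return "positive"
    if score <= -0.05:
        return "negative"
    return "neutral"


class ZTestResult(NamedTuple):
    z: float
    p_value: float
    degenerate: bool = False


def two_proportion_z_test(x1: int, n1: int, x2: int, n2: int) -> ZTestResult:
    """Pooled two-proportion z-test, two-sided normal p-value."""
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ZTestResult(float("nan"), 1.0, degenerate=True)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return ZTestResult(z, 2 * stats.norm.sf(abs(z)), degenerate=False)


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """p_adj = min(1, m * p); ``m`` defaults to the number of tests."""
    if any(not 0 <= p <= 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    m = m if m is not None else len(p_values)
    return [min(1.0, m * p) for p in p_values]


@dataclass
class CategorySentimentSummary:
    category: str
    n_posts: int
    mean_score: float
    p_pos: float
    p_neu: float
    p_neg: float
    z: float
    p_raw: float
    p_adj: float | None = None
    degenerate: bool = False
    empty: bool = False


def summarize_category(
    posts: Sequence[Post],
    category: str,
    neutralize: Sequence[str],
    scorer: LexiconScorer,
    placeholder: str = "X",
) -> CategorySentimentSummary:
    """Neutralize, score and classify each post of one health category;
    compare the positive vs negative proportions with the pooled z-test.
    The multiplicity adjustment across categories is applied by
    :func:`sentiment_table`."""
    if not posts:
        return CategorySentimentSummary(
            category, 0, float("nan"), float("nan"), float("nan"),
            float("nan"), float("nan"), float("nan"), empty=True,
        )
    scores = [
        scorer.score(neutralize_keywords(p.text, neutralize, placeholder))
        for p in posts
    ]
    labels = [classify_propensity(s) for s in scores]
    n = len(posts)
    n_pos = labels.count("positive")
    n_neg = labels.count("negative")
    zres = two_proportion_z_test(n_pos, n, n_neg, n)
    return CategorySentimentSummary(
        category=category,
        n_posts=n,
        mean_score=float(np.mean(scores)),
        p_pos=n_pos / n,
        p_neu=labels.count("neutral") / n,
        p_neg=n_neg / n,
        z=zres.z,
        p_raw=zres.p_value,
        degenerate=zres.degenerate,
    )


def sentiment_table(
    posts_by_category: Mapping[str, Sequence[Post]],
    health_keywords: Iterable[str],
    scorer: LexiconScorer | None = None,
    widen_neutralization: bool = False,
    m: int | None = None,
    placeholder: str = "X",
) -> pd.DataFrame:
    """Per-category sentiment summary table with Bonferroni-adjusted
    p-values (``m`` defaults to the number of categories tested)."""
    scorer = scorer or LexiconScorer()
    neutral = neutralizable_keywords(
        health_keywords, scorer.lexicon, widen_to_all=widen_neutralization
    )
    summaries = [
        summarize_category(list(posts), cat, neutral, scorer, placeholder)
        for cat, posts in posts_by_category.items()
    ]
    tested = [s for s in summaries if not s.empty]
    adjusted = bonferroni_adjust([s.p_raw for s in tested], m=m or len(tested))
    for s, p_adj in zip(tested, adjusted):
        s.p_adj = p_adj
    return pd.DataFrame(
        [
            {
                "category": s.category,
                "n": s.n_posts,
                "mean_score": s.mean_score,
                "p_pos": s.p_pos,
                "p_neu": s.p_neu,
                "p_neg": s.p_neg,
                "z": s.z,
                "p_raw": s.p_raw,
                "p_adj": s.p_adj,
            }
            for s in summaries
        ]
    )
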