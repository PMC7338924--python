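"""Frequent itemset mining over post token sets.

Keyword lists are enriched by mining combinations of co-occurring tokens
from the seed-filtered corpus: tokens that frequently co-occur with a
seed keyword are surfaced as candidate list entries for human review.
The miner is classic Apriori — level-wise candidate generation with
downward-closure pruning — which is ample at desk-scale corpus sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from ._text import STOPWORDS, clean_text, tokenize
from .taxonomy import Post

__all__ = [
    "Transaction",
    "FrequentItemset",
    "posts_to_transactions",
    "mine_frequent_itemsets",
    "enrichment_candidates",
]


@dataclass(frozen=True)
class Transaction:
    post_id: str
    items: frozenset[str]


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[str]
    support: int
    support_fraction: float


def posts_to_transactions(
    posts: Iterable[Post], stopwords: frozenset[str] | set[str] = STOPWORDS
) -> list[Transaction]:
    """One transaction per post: deduplicated lowercase tokens minus
    stopwords. Posts whose item set comes out empty are dropped."""
    out = []
    for post in posts:
        items = frozenset(
            t.text for t in tokenize(clean_text(post.text))
        ) - frozenset(stopwords)
        if items:
            out.append(Transaction(post.post_id, items))
    return out


def _support_count(
    candidate: frozenset[str], transactions: Sequence[frozenset[str]]
) -> int:
    return sum(1 for t in transactions if candidate <= t)


def mine_frequent_itemsets(
    transactions: Sequence[Transaction],
    min_support: int = 2,
    max_size: int = 3,
) -> list[FrequentItemset]:
    """Apriori. Exactly the itemsets of size <= ``max_size`` with support
    >= ``min_support`` (absolute count), sorted by
    (size, -support, lexicographic). Downward closure holds by
    construction: every subset of a returned itemset is also returned.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if not transactions:
        return []
    sets = [t.items for t in transactions]
    n = len(sets)

    # L1
    counts: dict[str, int] = {}
    for s in sets:
        for item in s:
            counts[item] = counts.get(item, 0) + 1
    level = {
        frozenset([item]): c for item, c in counts.items() if c >= min_support
    }
    results: dict[frozenset[str], int] = dict(level)

    size = 1
    while level and size < max_size:
        # Candidate generation: join frequent k-sets sharing a (k-1)-prefix,
        # then prune candidates with an infrequent subset.
        frequent = sorted(level, key=lambda s: tuple(sorted(s)))
        keys = [tuple(sorted(s)) for s in frequent]
        candidates: set[frozenset[str]] = set()
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                if keys[i][:-1] != keys[j][:-1]:
                    break  # sorted order: no further joins for i
                cand = frozenset(keys[i]) | frozenset(keys[j])
                if all(
                    frozenset(sub) in level
                    for sub in combinations(sorted(cand), size)
                ):
                    candidates.add(cand)
        level = {}
        for cand in candidates:
            c = _support_count(cand, sets)
            if c >= min_support:
                level[cand] = c
        results.update(level)
        size += 1

    out = [
        FrequentItemset(items, sup, sup / n) for items, sup in results.items()
    ]
    out.sort(key=lambda f: (len(f.items), -f.support, tuple(sorted(f.items))))
    return out


def enrichment_candidates(
    itemsets: Sequence[FrequentItemset],
    seed_keywords: Iterable[str],
    top_k: int = 20,
) -> list[tuple[str, int, str]]:
    """Ranked non-seed tokens co-occurring with a seed in a frequent
    itemset: ``(token, best_support, co_seed)`` triples, ranked by the
    support of the token's best co-itemset. Intended for manual review;
    never auto-appended to a taxonomy.
    """
    seeds = set(seed_keywords)
    best: dict[str, tuple[int, str]] = {}
    for fs in itemsets:
        hit_seeds = fs.items & seeds
        if not hit_seeds:
            continue
        co_seed = min(hit_seeds)
        for token in fs.items - seeds:
            cur = best.get(token)
            if cur is None or fs.support > cur[0]:
                best[token] = (fs.support, co_seed)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return [(tok, sup, seed) for tok, (sup, seed) in ranked[:top_k]]
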