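"""Topic modeling of the health-related corpus.

Pipeline: lowercase/lemmatize/stopword-strip, merge frequent bigrams and
trigrams into single underscore-joined terms (so "throat hit" enters the
model as one element), fit latent Dirichlet allocation by collapsed
Gibbs sampling, and label topics whose top terms are dominated by flavor
or health keywords.

The Gibbs sampler is implemented here rather than delegated so that runs
are hermetic and bit-reproducible from a seed: each token's topic is
resampled from

    p(z = k | rest)  ∝  (n_dk + α) (n_kw + β) / (n_k + V β)

with all counts excluding the token being resampled. A numba-compiled
kernel is used when available; a pure-Python kernel produces identical
output (both consume the same pre-drawn uniform variates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from ._text import STOPWORDS, lemmatize_all, tokenize

try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "TokenizedDoc",
    "TopicModelState",
    "preprocess",
    "detect_collocations",
    "fit_lda",
    "top_terms",
    "label_topics",
]


@dataclass
class TokenizedDoc:
    doc_id: str
    tokens: list[str]


def preprocess(
    texts: Iterable[tuple[str, str]],
    stopwords: frozenset[str] | set[str] = STOPWORDS,
    lemmatizer: Callable[[str], str] | None = None,
) -> tuple[list[TokenizedDoc], int]:
    """(doc_id, text) pairs -> tokenized docs.

    lowercase -> tokenize -> lemmatize -> drop stopwords; documents that
    come out empty are dropped. Returns (docs, n_dropped).
    """
    docs: list[TokenizedDoc] = []
    dropped = 0
    sw = frozenset(stopwords)
    for doc_id, text in texts:
        toks = lemmatize_all((t.text for t in tokenize(text)), lemmatizer)
        toks = [t for t in toks if t and t not in sw]
        if toks:
            docs.append(TokenizedDoc(doc_id, toks))
        else:
            dropped += 1
    return docs, dropped


def _collocation_pass(
    docs: Sequence[TokenizedDoc], min_count: int, threshold: float
) -> list[TokenizedDoc]:
    unigram: dict[str, int] = {}
    bigram: dict[tuple[str, str], int] = {}
    for d in docs:
        for t in d.tokens:
            unigram[t] = unigram.get(t, 0) + 1
        for a, b in zip(d.tokens, d.tokens[1:]):
            bigram[(a, b)] = bigram.get((a, b), 0) + 1
    vocab_size = len(unigram)

    def score(a: str, b: str) -> float:
        cab = bigram.get((a, b), 0)
        if cab < min_count:
            return 0.0
        return (cab - min_count) * vocab_size / (unigram[a] * unigram[b])

    merged_docs = []
    for d in docs:
        out: list[str] = []
        i = 0
        toks = d.tokens
        while i < len(toks):
            if i + 1 < len(toks) and score(toks[i], toks[i + 1]) > threshold:
                out.append(toks[i] + "_" + toks[i + 1])
                i += 2  # greedy left-to-right, non-overlapping
            else:
                out.append(toks[i])
                i += 1
        merged_docs.append(TokenizedDoc(d.doc_id, out))
    return merged_docs


def detect_collocations(
    docs: Sequence[TokenizedDoc],
    min_count: int = 20,
    threshold: float = 10.0,
    passes: int = 2,
) -> list[TokenizedDoc]:
    """Merge frequent adjacent pairs into single terms using the
    count-based phrase score

        score(a, b) = (count(a,b) - min_count) * V / (count(a) * count(b))

    with V the vocabulary size; pairs scoring above ``threshold`` are
    joined left-to-right without overlap. A second pass over the merged
    corpus builds trigrams out of bigrams.
    """
    if passes not in (1, 2):
        raise ValueError("passes must be 1 or 2")
    out = list(docs)
    for _ in range(passes):
        out = _collocation_pass(out, min_count, threshold)
    return out


@dataclass
class TopicModelState:
    """Final state of a collapsed Gibbs run."""

    n_topics: int
    alpha: float
    beta: float
    vocabulary: list[str]
    doc_ids: list[str]
    assignments: np.ndarray  # topic per token position (flat)
    doc_of_token: np.ndarray
    word_of_token: np.ndarray
    doc_topic: np.ndarray  # (D, K) counts
    topic_word: np.ndarray  # (K, V) counts
    topic_totals: np.ndarray  # (K,) counts
    n_iters: int = 0
    seed: int | None = None

    def theta(self) -> np.ndarray:
        """Document-topic distributions, rows summing to 1."""
        num = self.doc_topic + self.alpha
        return num / num.sum(axis=1, keepdims=True)

    def phi(self) -> np.ndarray:
        """Topic-word distributions, rows summing to 1."""
        num = self.topic_word + self.beta
        return num / num.sum(axis=1, keepdims=True)


def _gibbs_sweep_py(z, docs_idx, words_idx, ndk, nkw, nk, alpha, beta, u):
    K = ndk.shape[1]
    V = nkw.shape[1]
    vb = V * beta
    for t in range(z.shape[0]):
        d = docs_idx[t]
        w = words_idx[t]
        k = z[t]
        ndk[d, k] -= 1
        nkw[k, w] -= 1
        nk[k] -= 1
        p = (ndk[d] + alpha) * (nkw[:, w] + beta) / (nk + vb)
        cdf = np.cumsum(p)
        k_new = int(np.searchsorted(cdf, u[t] * cdf[-1], side="right"))
        if k_new >= K:
            k_new = K - 1
        z[t] = k_new
        ndk[d, k_new] += 1
        nkw[k_new, w] += 1
        nk[k_new] += 1


if _HAVE_NUMBA:

    @njit(cache=True)
    def _gibbs_sweep_nb(z, docs_idx, words_idx, ndk, nkw, nk, alpha, beta, u):
        K = ndk.shape[1]
        V = nkw.shape[1]
        vb = V * beta
        for t in range(z.shape[0]):
            d = docs_idx[t]
            w = words_idx[t]
            k = z[t]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            total = 0.0
            for kk in range(K):
                total += (ndk[d, kk] + alpha) * (nkw[kk, w] + beta) / (nk[kk] + vb)
            target = u[t] * total
            acc = 0.0
            k_new = K - 1
            for kk in range(K):
                acc += (ndk[d, kk] + alpha) * (nkw[kk, w] + beta) / (nk[kk] + vb)
                if acc >= target:
                    k_new = kk
                    break
            z[t] = k_new
            ndk[d, k_new] += 1
            nkw[k_new, w] += 1
            nk[k_new] += 1


def fit_lda(
    docs: Sequence[TokenizedDoc],
    n_topics: int,
    alpha: float | None = None,
    beta: float = 0.01,
    n_iters: int = 1000,
    seed: int = 0,
) -> TopicModelState:
    """Collapsed Gibbs sampling for LDA; seeded runs are reproducible.

    ``alpha`` defaults to 50 / K. The sampler draws one uniform variate
    per token per sweep from a seeded generator, so the numba and
    pure-Python kernels produce identical assignments.
    """
    if n_topics < 2:
        raise ValueError("n_topics must be >= 2")
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    vocab = sorted({t for d in docs for t in d.tokens})
    if not vocab:
        raise ValueError("empty vocabulary")
    word_id = {w: i for i, w in enumerate(vocab)}
    doc_of, word_of = [], []
    for di, d in enumerate(docs):
        for t in d.tokens:
            doc_of.append(di)
            word_of.append(word_id[t])
    n_tokens = len(word_of)
    if n_topics > n_tokens:
        raise ValueError(f"K={n_topics} exceeds total token count {n_tokens}")
    alpha = 50.0 / n_topics if alpha is None else alpha

    doc_of_a = np.asarray(doc_of, dtype=np.int64)
    word_of_a = np.asarray(word_of, dtype=np.int64)
    rng = np.random.default_rng(seed)
    z = rng.integers(0, n_topics, size=n_tokens).astype(np.int64)

    D, K, V = len(docs), n_topics, len(vocab)
    ndk = np.zeros((D, K), dtype=np.int64)
    nkw = np.zeros((K, V), dtype=np.int64)
    nk = np.zeros(K, dtype=np.int64)
    np.add.at(ndk, (doc_of_a, z), 1)
    np.add.at(nkw, (z, word_of_a), 1)
    np.add.at(nk, z, 1)

    sweep = _gibbs_sweep_nb if _HAVE_NUMBA else _gibbs_sweep_py
    for _ in range(n_iters):
        u = rng.random(n_tokens)
        sweep(z, doc_of_a, word_of_a, ndk, nkw, nk, float(alpha), float(beta), u)

    return TopicModelState(
        n_topics=K,
        alpha=float(alpha),
        beta=float(beta),
        vocabulary=vocab,
        doc_ids=[d.doc_id for d in docs],
        assignments=z,
        doc_of_token=doc_of_a,
        word_of_token=word_of_a,
        doc_topic=ndk,
        topic_word=nkw,
        topic_totals=nk,
        n_iters=n_iters,
        seed=seed,
    )


def top_terms(state: TopicModelState, n: int = 10) -> list[list[str]]:
    """The n highest-probability terms per topic; ties break
    lexicographically; n is truncated at the vocabulary size."""
    phi = state.phi()
    n = min(n, len(state.vocabulary))
    out = []
    for k in range(state.n_topics):
        order = sorted(
            range(len(state.vocabulary)),
            key=lambda w: (-phi[k, w], state.vocabulary[w]),
        )
        out.append([state.vocabulary[w] for w in order[:n]])
    return out


def _normalize_term(keyword: str) -> str:
    return "_".join(keyword.lower().split())


def label_topics(
    state: TopicModelState,
    flavor_keywords: Iterable[str],
    health_keywords: Iterable[str],
    top_n: int = 10,
    min_hits: int = 2,
) -> list[str]:
    """Label each topic flavor / health / other by counting taxonomy
    keywords among its ``top_n`` terms; flavor wins ties. Multi-word
    keywords are matched against their underscore-merged form. This is
    a reproducible proxy for what was originally a manual judgement.
    """
    if not top_n >= min_hits >= 1:
        raise ValueError("need top_n >= min_hits >= 1")
    fset = {_normalize_term(k) for k in flavor_keywords}
    hset = {_normalize_term(k) for k in health_keywords}
    labels = []
    for terms in top_terms(state, top_n):
        f_hits = sum(1 for t in terms if t in fset)
        h_hits = sum(1 for t in terms if t in hset)
        if f_hits >= min_hits and f_hits >= h_hits:
            labels.append("flavor")
        elif h_hits >= min_hits:
            labels.append("health")
        else:
            labels.append("other")
    return labels
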