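"""End-to-end orchestration: filter -> temporal -> sentiment -> topics
-> entries -> GEE -> contrasts, with a provenance manifest.

All randomness derives from a single root seed, fanned out per stage, so
reruns with the same configuration produce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, association, sentiment, temporal, topics
from .io import Manifest, read_posts, read_taxonomy
from .taxonomy import Post, classify_post, filter_corpus

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one run."""

    posts_path: str
    ecig_taxonomy: str
    health_taxonomy: str
    flavor_taxonomy: str
    lexicon_path: str | None = None  # None -> bundled lexicon
    out_dir: str = "results"
    seed: int = 0
    window: tuple[str, str] | None = None
    # FIM
    fim_min_support: int = 10
    fim_max_size: int = 3
    # topics
    n_topics: int = 20
    lda_iters: int = 200
    colloc_min_count: int = 20
    colloc_threshold: float = 10.0
    # association
    min_entries: int = 10
    corstr: str = "exchangeable"
    # display
    rounding_mode: str = "round"
    counting_mode: str = "posts"
    health_categories: Sequence[str] | None = None  # None -> all with entries

    def stage_seed(self, stage: str) -> int:
        # deterministic per-stage fan-out, kept below 2**31
        tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:2], "big")
        return int(
            np.random.SeedSequence([self.seed, tag]).generate_state(1)[0] % (2**31)
        )

    def validate(self) -> "PipelineConfig":
        for p in (self.posts_path, self.ecig_taxonomy, self.health_taxonomy,
                  self.flavor_taxonomy):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.lexicon_path is not None and not Path(self.lexicon_path).exists():
            raise FileNotFoundError(self.lexicon_path)
        return self


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; artifacts land in ``out_dir``.

    Returns a bundle with the in-memory results (trends, sentiment
    table, topics, probabilities, contrasts, heatmap, manifest). A stage
    failure raises :class:`PipelineError` after writing a partial
    manifest naming the completed stages.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(
        parameters={
            k: v for k, v in vars(config).items() if isinstance(v, (int, float, str))
        },
        seeds={"root": config.seed},
        versions={"vapelens": __version__, "python": sys.version.split()[0]},
    )
    for p in (config.posts_path, config.ecig_taxonomy, config.health_taxonomy,
              config.flavor_taxonomy):
        manifest.add_input(p)
    if config.lexicon_path:
        manifest.add_input(config.lexicon_path)

    bundle: dict = {"manifest": manifest}
    stage = "filter"
    try:
        ecig = read_taxonomy(config.ecig_taxonomy)
        health = read_taxonomy(config.health_taxonomy)
        flavor = read_taxonomy(config.flavor_taxonomy)
        counters: dict[str, int] = {}
        corpus: list[Post] = list(
            filter_corpus(read_posts(config.posts_path), ecig, counters=counters)
        )
        manifest.counters["filter"] = counters
        classified = {
            p.post_id: classify_post(p, health, flavor) for p in corpus
        }
        health_posts = [
            p for p in corpus if classified[p.post_id].health_categories
        ]
        manifest.stages_completed.append(stage)

        stage = "temporal"
        assignment = {
            pid: sorted(c.health_categories) for pid, c in classified.items()
        }
        counts = temporal.monthly_counts(
            corpus, assignment, window=config.window,
            counting_mode=config.counting_mode,
        )
        totals = temporal.monthly_totals(corpus, window=config.window)
        props = temporal.normalize_series(counts, totals)
        trends = counts.stack().rename("count").reset_index()
        trends.columns = ["month", "category", "count"]
        trends["proportion"] = props.stack().to_numpy()
        trends["month"] = trends["month"].astype(str)
        trends.to_csv(out / "trends.csv", index=False)
        bundle["trends"] = trends
        manifest.stages_completed.append(stage)

        stage = "sentiment"
        scorer = (
            sentiment.LexiconScorer(sentiment.load_lexicon(config.lexicon_path))
            if config.lexicon_path
            else sentiment.LexiconScorer()
        )
        by_cat: dict[str, list[Post]] = {}
        for p in health_posts:
            for cat in classified[p.post_id].health_categories:
                by_cat.setdefault(cat, []).append(p)
        sent_table = sentiment.sentiment_table(
            dict(sorted(by_cat.items())), health.all_keywords(), scorer
        )
        sent_table.to_csv(out / "sentiment.csv", index=False)
        bundle["sentiment"] = sent_table
        manifest.stages_completed.append(stage)

        stage = "topics"
        docs, _ = topics.preprocess((p.post_id, p.text) for p in health_posts)
        docs = topics.detect_collocations(
            docs, config.colloc_min_count, config.colloc_threshold
        )
        state = topics.fit_lda(
            docs,
            n_topics=config.n_topics,
            n_iters=config.lda_iters,
            seed=config.stage_seed("topics"),
        )
        terms = topics.top_terms(state, 10)
        labels = topics.label_topics(
            state, flavor.all_keywords(), health.all_keywords()
        )
        phi = state.phi()
        topic_json = [
            {
                "topic": k,
                "label": labels[k],
                "top_terms": [
                    {
                        "term": t,
                        "weight": float(phi[k, state.vocabulary.index(t)]),
                    }
                    for t in terms[k]
                ],
            }
            for k in range(state.n_topics)
        ]
        (out / "topics.json").write_text(json.dumps(topic_json, indent=2))
        bundle["topics"] = topic_json
        manifest.stages_completed.append(stage)

        stage = "entries"
        entries = association.extract_entries(
            corpus, health, flavor, classified=classified
        )
        pd.DataFrame(
            [vars(e) for e in entries]
        ).to_csv(out / "entries.csv", index=False)
        bundle["entries"] = entries
        manifest.stages_completed.append(stage)

        stage = "gee"
        present = sorted({e.health_category for e in entries})
        cats = list(config.health_categories) if config.health_categories else present
        fits = [
            association.fit_gee(
                entries, cat, corstr=config.corstr,
                min_entries=config.min_entries,
            )
            for cat in cats
        ]
        prob_rows = []
        for fit in fits:
            for level, est in association.estimate_probabilities(fit).items():
                prob_rows.append(
                    {
                        "flavor": level,
                        "health": fit.health_category,
                        "prob": est.probability,
                        "se": est.se,
                        "n": fit.n_entries,
                        "alpha_hat": fit.alpha_hat,
                        "converged": fit.converged,
                    }
                )
        probs = pd.DataFrame(prob_rows)
        probs.to_csv(out / "probabilities.csv", index=False)
        heatmap = association.heatmap_table(fits)
        heatmap.to_csv(out / "heatmap.csv")
        bundle["fits"] = fits
        bundle["probabilities"] = probs
        bundle["heatmap"] = heatmap
        manifest.stages_completed.append(stage)

        stage = "contrasts"
        contrast_rows = [
            vars(c) for fit in fits for c in association.pairwise_tukey(fit)
        ]
        contrasts = pd.DataFrame(contrast_rows)
        contrasts.to_csv(out / "contrasts.csv", index=False)
        bundle["contrasts"] = contrasts
        manifest.stages_completed.append(stage)
    except Exception as exc:
        manifest.write(out / "manifest.json")
        raise PipelineError(stage, exc) from exc

    for name in ("trends.csv", "sentiment.csv", "topics.json", "entries.csv",
                 "probabilities.csv", "heatmap.csv", "contrasts.csv"):
        manifest.add_output(out / name)
    manifest.write(out / "manifest.json")
    return bundle
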