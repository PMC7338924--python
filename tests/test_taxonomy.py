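"""Keyword matching, disambiguation, corpus filtering and classification."""

import random

import pytest

from vapelens.taxonomy import (
    DisambiguationRule,
    KeywordTaxonomy,
    TaxonomyError,
    audit_filter_precision,
    classify_post,
    filter_corpus,
    match_keywords,
)

from conftest import make_post


@pytest.fixture(scope="module")
def mini_flavor():
    """Flavor-like taxonomy with a tobacco context rule."""
    return KeywordTaxonomy(
        "mini",
        {"Tobacco": ["tobacco"], "Fruit": ["strawberry"]},
        [DisambiguationRule("tobacco", ("flavor", "e-liquid"))],
    ).validate()


class TestMatchKeywords:
    def test_direct_containment(self, ecig_tax):
        recs = match_keywords(make_post("I love my vape."), ecig_tax)
        assert len(recs) == 1
        assert (recs[0].category, recs[0].keyword, recs[0].sentence_index) == (
            "ecig", "vape", 0,
        )

    def test_ambiguous_keyword_without_context_is_suppressed(self, mini_flavor):
        assert match_keywords(make_post("Tobacco kills."), mini_flavor) == []

    def test_ambiguous_keyword_with_context_survives(self, mini_flavor):
        recs = match_keywords(
            make_post("This tobacco flavor e-liquid is smooth."), mini_flavor
        )
        assert [r.keyword for r in recs] == ["tobacco"]

    def test_context_must_be_in_same_sentence(self, mini_flavor):
        text = "Tobacco is gross. I do like the flavor of mango."
        assert match_keywords(make_post(text), mini_flavor) == []

    def test_multiword_keyword_wins_over_subword(self):
        tax = KeywordTaxonomy(
            "t", {"Throat": ["sore throat", "throat"]}
        ).validate()
        recs = match_keywords(make_post("My sore throat is back."), tax)
        assert [r.keyword for r in recs] == ["sore throat"]

    def test_hyphenated_and_fused_variants_are_distinct(self, ecig_tax):
        recs = match_keywords(make_post("e-juice or ejuice?"), ecig_tax)
        assert sorted(r.keyword for r in recs) == ["e-juice", "ejuice"]

    def test_case_insensitive_token_boundary(self, ecig_tax):
        assert match_keywords(make_post("VAPE!"), ecig_tax)
        # substring inside a longer token is not a hit
        assert match_keywords(make_post("vapex"), ecig_tax) == []

    def test_unvalidated_taxonomy_raises(self):
        tax = KeywordTaxonomy("t", {"A": ["vape"]})
        with pytest.raises(TaxonomyError):
            match_keywords(make_post("vape"), tax)

    def test_empty_text_gives_empty_list(self, ecig_tax):
        assert match_keywords(make_post(""), ecig_tax) == []

    def test_determinism_under_stream_order(self, ecig_tax, health_tax):
        posts = [
            make_post(f"My vape gave me a cough number {i}.", post_id=f"p{i}")
            for i in range(20)
        ]
        ref = {p.post_id: match_keywords(p, health_tax) for p in posts}
        shuffled = posts[:]
        random.Random(0).shuffle(shuffled)
        assert {p.post_id: match_keywords(p, health_tax) for p in shuffled} == ref

    def test_disambiguation_soundness_by_rescan(self, flavor_tax):
        from vapelens._text import keyword_tokens, split_sentences, tokenize

        texts = [
            "Love this tobacco flavor e-liquid. Smoking tobacco is bad.",
            "tobacco juice all day",
            "Plain tobacco cigarettes.",
            "The tobacco vape and the menthol one.",
        ]
        rule = flavor_tax.disambiguation_rules[0]
        for text in texts:
            post = make_post(text)
            for rec in match_keywords(post, flavor_tax):
                if rec.keyword != rule.ambiguous_keyword:
                    continue
                spans = split_sentences(post.text)
                s, e = spans[rec.sentence_index]
                sent_tokens = [t.text for t in tokenize(post.text[s:e])]
                assert any(
                    all(w in sent_tokens for w in keyword_tokens(ctx))
                    for ctx in rule.context_keywords
                )


class TestValidation:
    def test_rejects_uppercase_keyword(self):
        with pytest.raises(TaxonomyError):
            KeywordTaxonomy("t", {"A": ["Vape"]}).validate()

    def test_rejects_keyword_in_two_categories(self):
        with pytest.raises(TaxonomyError):
            KeywordTaxonomy("t", {"A": ["vape"], "B": ["vape"]}).validate()

    def test_health_taxonomy_requires_canonical_categories(self):
        with pytest.raises(TaxonomyError):
            KeywordTaxonomy("health", {"Respiratory": ["cough"]}).validate()

    def test_rule_requires_context(self):
        with pytest.raises(TaxonomyError):
            DisambiguationRule("tobacco", ())


class TestFilterCorpus:
    def test_keeps_only_matching_posts(self, ecig_tax):
        posts = [
            make_post("nothing relevant here", post_id="a"),
            make_post("my new e-juice arrived", post_id="b"),
            make_post("also irrelevant", post_id="c"),
        ]
        kept = list(filter_corpus(posts, ecig_tax))
        assert [p.post_id for p in kept] == ["b"]

    def test_url_only_post_dropped(self, ecig_tax):
        posts = [make_post("https://example.com/vape-deals")]
        counters = {}
        assert list(filter_corpus(posts, ecig_tax, counters=counters)) == []
        assert counters["dropped_empty"] == 1

    def test_urls_and_emails_stripped_from_kept_text(self, ecig_tax):
        posts = [make_post("buy vape at https://shop.example or a@b.com now")]
        (kept,) = filter_corpus(posts, ecig_tax)
        assert "http" not in kept.text and "@" not in kept.text
        assert "vape" in kept.text

    def test_non_english_dropped(self, ecig_tax):
        posts = [make_post("вейп вейп вейп вейп vape")]
        counters = {}
        assert list(filter_corpus(posts, ecig_tax, counters=counters)) == []
        assert counters["dropped_language"] == 1

    def test_empty_stream(self, ecig_tax):
        assert list(filter_corpus([], ecig_tax)) == []

    def test_subset_nesting(self, ecig_tax, health_tax, flavor_tax):
        posts = [
            make_post("vape with a cough", post_id="a"),
            make_post("strawberry cough no device word", post_id="b"),
            make_post("juul is fine", post_id="c"),
        ]
        corpus = list(filter_corpus(posts, ecig_tax))
        health_subset = [p for p in corpus if match_keywords(p, health_tax)]
        flavor_subset = [p for p in corpus if match_keywords(p, flavor_tax)]
        corpus_ids = {p.post_id for p in corpus}
        assert {p.post_id for p in health_subset} <= corpus_ids
        assert {p.post_id for p in flavor_subset} <= corpus_ids

    def test_adding_keyword_is_monotone(self):
        posts = [
            make_post("I use a mod daily", post_id="a"),
            make_post("my vape broke", post_id="b"),
        ]
        small = KeywordTaxonomy("t", {"ecig": ["vape"]}).validate()
        bigger = KeywordTaxonomy("t", {"ecig": ["vape", "mod"]}).validate()
        n_small = len(list(filter_corpus(posts, small)))
        n_big = len(list(filter_corpus(posts, bigger)))
        assert n_big >= n_small


class TestClassifyPost:
    def test_two_keywords_one_category(self, health_tax, flavor_tax):
        cls = classify_post(
            make_post("a cough and wheezing all night"), health_tax, flavor_tax
        )
        assert cls.health_categories == {"Respiratory"}
        assert cls.flavor_categories == frozenset()

    def test_cross_taxonomy_assignment(self, health_tax, flavor_tax):
        cls = classify_post(
            make_post("strawberry juice gave me a headache"),
            health_tax,
            flavor_tax,
        )
        assert cls.health_categories == {"Neurological"}
        assert cls.flavor_categories == {"Fruit"}

    def test_keyword_counts_retained(self, health_tax, flavor_tax):
        cls = classify_post(
            make_post("menthol and mint with a sore throat"),
            health_tax,
            flavor_tax,
        )
        assert cls.health_categories == {"Throat"}
        assert cls.flavor_categories == {"Menthol or Mint"}
        assert sum(cls.flavor_keywords.values()) == 2
        assert set(cls.flavor_keywords) == {"menthol", "mint"}


class TestAuditPrecision:
    def _posts(self, n, keyword="vape"):
        return [
            make_post(f"I use my {keyword} a lot. Post {i}.", post_id=f"p{i}")
            for i in range(n)
        ]

    def test_all_relevant(self, ecig_tax):
        posts = self._posts(200)
        audit = audit_filter_precision(
            posts, ecig_tax, "vape", n_sample=100, seed=1, labels=[True] * 100
        )
        assert audit.precision == 1.0
        assert len(audit.post_ids) == 100

    def test_partial_precision(self, ecig_tax):
        posts = self._posts(100)
        labels = [True] * 85 + [False] * 15
        audit = audit_filter_precision(
            posts, ecig_tax, "vape", n_sample=100, seed=1, labels=labels
        )
        assert audit.precision == pytest.approx(0.85)

    def test_sample_capped_at_available(self, ecig_tax):
        posts = self._posts(3)
        audit = audit_filter_precision(posts, ecig_tax, "vape", n_sample=100, seed=0)
        assert len(audit.post_ids) == 3

    def test_absent_keyword_warns_and_is_empty(self, ecig_tax):
        with pytest.warns(UserWarning):
            audit = audit_filter_precision(
                self._posts(5), ecig_tax, "juul", n_sample=10, seed=0
            )
        assert audit.post_ids == []

    def test_highlight_is_containing_sentence(self, ecig_tax):
        posts = [make_post("First line. My vape is here. Last.")]
        audit = audit_filter_precision(posts, ecig_tax, "vape", n_sample=1, seed=0)
        assert audit.highlights == ["My vape is here."]

    def test_seeded_sampling_is_reproducible(self, ecig_tax):
        posts = self._posts(50)
        a = audit_filter_precision(posts, ecig_tax, "vape", n_sample=10, seed=7)
        b = audit_filter_precision(posts, ecig_tax, "vape", n_sample=10, seed=7)
        assert a.post_ids == b.post_ids
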