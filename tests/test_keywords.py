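import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import worksent as ws
from worksent.keywords import KeywordFitness, SeedKeyword

from conftest import tweet


class TestCombineCategories:
    def test_two_by_two_seed_list(self):
        ks = ws.combine_categories(["workplace", "corporate"], ["stress", "good"])
        assert {str(k) for k in ks} == {
            "workplace stress",
            "workplace good",
            "corporate stress",
            "corporate good",
        }

    def test_singleton(self):
        ks = ws.combine_categories(["office"], ["good"])
        assert {str(k) for k in ks} == {"office good"}

    def test_cross_product_size(self):
        prefixes, postfixes = ["a", "b", "c"], ["w", "x", "y", "z"]
        ks = ws.combine_categories(prefixes, postfixes)
        expected = {f"{p} {q}" for p in prefixes for q in postfixes}
        assert {str(k) for k in ks} == expected and len(ks) == 12

    def test_empty_input_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            ks = ws.combine_categories([], ["x"])
        assert len(ks) == 0 and "empty" in caplog.text

    @given(
        prefixes=st.lists(st.sampled_from("abcde"), min_size=1, max_size=5),
        postfixes=st.lists(st.sampled_from("vwxyz"), min_size=1, max_size=5),
    )
    def test_size_never_exceeds_product(self, prefixes, postfixes):
        ks = ws.combine_categories(prefixes, postfixes)
        assert len(ks) <= len(prefixes) * len(postfixes)


class TestExpandSynonyms:
    def test_known_geometry_k2(self, toy_vectors):
        out = ws.expand_synonyms(["work"], toy_vectors, k=2)
        # oracle: exhaustive pairwise cosine against "work"
        sims = {
            w: float(
                toy_vectors[w] @ toy_vectors["work"]
                / (np.linalg.norm(toy_vectors[w]) * np.linalg.norm(toy_vectors["work"]))
            )
            for w in toy_vectors
            if w != "work"
        }
        expected = sorted(sims, key=lambda w: (-sims[w], w))[:2]
        assert out == ["work"] + expected

    def test_k_zero_identity(self, toy_vectors):
        assert ws.expand_synonyms(["work", "work", "cat"], toy_vectors, k=0) == ["work", "cat"]

    def test_out_of_vocabulary_passes_through(self, toy_vectors):
        out = ws.expand_synonyms(["zebra"], toy_vectors, k=3)
        assert out == ["zebra"]


class TestMatchTweet:
    @pytest.mark.parametrize(
        "keyword,text,expected",
        [
            ("workplace stress", "Stress at my workplace is unreal", True),
            ("workplace stress", "my workplace is great", False),
            ("work", "#work is fine", True),
            ("workplace stress", "WORKPLACE ... STRESS!!!", True),
            ("work", "working hard", False),  # whole-word only
        ],
    )
    def test_examples(self, keyword, text, expected):
        assert ws.match_tweet(SeedKeyword.from_phrase(keyword), tweet(text)) is expected

    @given(perm=st.permutations(["alpha", "beta", "gamma"]))
    def test_order_insensitive(self, perm):
        kw = SeedKeyword(tuple(perm))
        assert ws.match_tweet(kw, tweet("Gamma then BETA then alpha"))

    def test_hashtag_token_is_stripped_for_matching(self):
        kw = SeedKeyword.from_phrase("overworked tired")
        assert ws.match_tweet(kw, tweet("so tired #overworked"))


def _planted_pool(seed=7):
    """5 relevant + 5 irrelevant candidates over a two-cluster embedding space;
    irrelevant keywords retrieve only off-topic tweets."""
    rng = np.random.default_rng(seed)
    d = 6
    rel = [f"rel{i}" for i in range(5)]
    irr = [f"irr{i}" for i in range(5)]
    filler = [f"fill{i}" for i in range(10)]

    def vec(axis):
        v = np.zeros(d)
        v[axis] = 1.0
        return v + 0.05 * rng.normal(size=d)

    vectors = {t: vec(0) for t in rel + filler[:5]}
    vectors.update({t: vec(1) for t in irr + filler[5:]})
    table = ws.WordVectorTable(vectors)

    tweets, n = [], 0
    for t in rel:
        for j in range(8):
            tweets.append(tweet(f"{t} {filler[j % 5]} chatter", tweet_id=f"s{n}"))
            n += 1
    for t in irr:
        for j in range(2):
            tweets.append(tweet(f"{t} {filler[5 + j % 5]} chatter", tweet_id=f"s{n}"))
            n += 1
    pool = ws.KeywordSet()
    for t in rel + irr:
        pool.add(t, "seed")
    return pool, tweets, table


class TestOptimizeKeywords:
    def test_single_candidate_degenerate(self, toy_vectors):
        pool = ws.KeywordSet()
        pool.add("work", "seed")
        out = ws.optimize_keywords(pool, [tweet("work is work")], toy_vectors, seed=3)
        assert {str(k) for k in out} == {"work"}

    def test_zero_iterations_reproducible(self):
        pool, tweets, table = _planted_pool()
        params = ws.SwarmParams(n_iterations=0)
        a = ws.optimize_keywords(pool, tweets, table, params, seed=11)
        b = ws.optimize_keywords(pool, tweets, table, params, seed=11)
        assert {str(k) for k in a} == {str(k) for k in b}

    def test_result_at_least_as_fit_as_full_pool(self):
        pool, tweets, table = _planted_pool()
        out = ws.optimize_keywords(pool, tweets, table, seed=11)
        cands = pool.sorted_keywords()
        fitness = KeywordFitness(cands, tweets, table)
        kept = {str(k) for k in out}
        mask = np.array([str(c) in kept for c in cands])
        assert fitness(mask) >= fitness(np.ones(len(cands), dtype=bool))

    def test_seed_reproducibility(self):
        pool, tweets, table = _planted_pool()
        a = ws.optimize_keywords(pool, tweets, table, seed=42)
        b = ws.optimize_keywords(pool, tweets, table, seed=42)
        assert {str(k) for k in a} == {str(k) for k in b}


class TestKeywordSet:
    def test_dedup_on_token_multiset(self):
        ks = ws.KeywordSet()
        ks.add("stress workplace", "panel")
        ks.add("workplace stress", "seed")
        assert len(ks) == 1
        (kw,) = list(ks)
        assert ks.provenance_of(kw) == "panel"  # first insertion wins

    def test_file_round_trip(self, tmp_path):
        ks = ws.KeywordSet()
        ks.add("workplace stress", "seed")
        ks.add("office good", "optimized")
        path = tmp_path / "kw.txt"
        ks.write(path)
        back = ws.KeywordSet.read(path)
        assert {str(k) for k in back} == {str(k) for k in ks}
        for kw in back:
            assert back.provenance_of(kw) == ks.provenance_of(kw)
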