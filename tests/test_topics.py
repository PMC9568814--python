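import numpy as np
import pytest

import worksent as ws
from worksent.preprocessing import ProcessedTweet


def _docs(token_lists):
    return [ProcessedTweet(f"d{i}", tuple(toks)) for i, toks in enumerate(token_lists)]


class TestBuildBow:
    def test_hand_countable(self):
        bow = ws.build_bow(_docs([["a", "b"], ["b", "c"]]))
        assert len(bow.vocab) == 3
        assert bow.matrix.sum() == 4
        col_b = bow.token2id["b"]
        assert bow.matrix[:, col_b].sum() == 2

    def test_single_doc_counts(self):
        bow = ws.build_bow(_docs([["a", "a", "a"]]))
        assert bow.matrix.toarray().tolist() == [[3]]

    def test_vocabulary_is_token_union(self, small_synthetic):
        _, corpus, _ = small_synthetic
        processed, _ = ws.preprocess_corpus(corpus[:100])
        nonempty = [p for p in processed if p.tokens]
        bow = ws.build_bow(nonempty)
        assert set(bow.vocab) == set().union(*(set(p.tokens) for p in nonempty))

    def test_empty_doc_keeps_empty_row(self):
        bow = ws.build_bow(_docs([["a"], []]))
        assert bow.matrix.getrow(1).nnz == 0 and bow.n_docs == 2

    def test_all_empty_is_fatal(self):
        with pytest.raises(ValueError):
            ws.build_bow(_docs([[], []]))


def _uniform_model(k, topic_word, n_docs=4, seed=0):
    topic_word = np.asarray(topic_word, dtype=float)
    topic_word = topic_word / topic_word.sum(axis=1, keepdims=True)
    vocab = [f"w{j}" for j in range(topic_word.shape[1])]
    doc_topic = np.full((n_docs, k), 1.0 / k)
    return ws.TopicModel(k, topic_word, doc_topic, vocab, seed)


class TestTopicDistances:
    def test_identical_topics_distance_zero(self):
        m = _uniform_model(2, [[0.5, 0.5, 0.0], [0.5, 0.5, 0.0]])
        assert ws.topic_distance_matrix(m)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_distance_one(self):
        m = _uniform_model(2, [[1.0, 0.0], [0.0, 1.0]])
        assert ws.topic_distance_matrix(m)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        tw = rng.dirichlet(np.ones(20), size=3)
        m = _uniform_model(3, tw)
        dist = ws.topic_distance_matrix(m)

        def js(p, q):  # independent evaluation of the divergence formula
            mmid = 0.5 * (p + q)
            kl = lambda a, b: np.sum(np.where(a > 0, a * np.log2(a / b), 0.0))
            return np.sqrt(0.5 * kl(p, mmid) + 0.5 * kl(q, mmid))

        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else js(tw[i] / tw[i].sum(), tw[j] / tw[j].sum())
                assert dist[i, j] == pytest.approx(expected, abs=1e-9)
        assert np.allclose(dist, dist.T) and np.all(np.diag(dist) == 0)


class TestSelectOptimalK:
    def _tied_curve(self):
        # coherence ties at K in {25, 28, 30}; K=28 has the least topic overlap
        points = [(k, 0.50) for k in range(24, 32)]
        points = [(k, 0.54) if k in (25, 28, 30) else (k, s) for k, s in points]
        models = {}
        rng = np.random.default_rng(0)
        for k, _ in points:
            if k == 28:  # nearly disjoint topics: high mean pairwise distance
                tw = np.eye(k) + 1e-6
            else:  # heavily overlapping topics
                base = rng.dirichlet(np.ones(k))
                tw = np.tile(base, (k, 1)) + 1e-6
            models[k] = _uniform_model(k, tw)
        return ws.CoherenceCurve(points), models

    def test_overlap_breaks_coherence_tie(self):
        curve, models = self._tied_curve()
        assert ws.select_optimal_k(curve, models) == 28

    def test_permutation_invariance(self):
        curve, models = self._tied_curve()
        reversed_curve = ws.CoherenceCurve(list(reversed(curve.points)))
        assert ws.select_optimal_k(reversed_curve, models) == 28

    def test_single_point(self):
        m = _uniform_model(2, [[1.0, 0.0], [0.0, 1.0]])
        assert ws.select_optimal_k(ws.CoherenceCurve([(2, 0.3)]), {2: m}) == 2

    def test_strict_argmax_without_ties(self):
        points = [(k, 0.1 * k) for k in range(2, 6)]
        models = {k: _uniform_model(k, np.eye(k) + 1e-6) for k, _ in points}
        assert ws.select_optimal_k(ws.CoherenceCurve(points), models) == max(
            k for k, s in points if s == max(s for _, s in points)
        )


class TestTopWords:
    def test_top_by_weight(self):
        m = _uniform_model(2, [[0.4, 0.3, 0.15, 0.1, 0.05], [0.2] * 5])
        top = ws.top_words(m, 0, n=3)
        assert [w for w, _ in top] == ["w0", "w1", "w2"]

    def test_tie_breaks_lexicographically(self):
        m = _uniform_model(2, [[0.25, 0.25, 0.25, 0.25], [0.4, 0.3, 0.2, 0.1]])
        assert [w for w, _ in ws.top_words(m, 0, n=4)] == ["w0", "w1", "w2", "w3"]

    def test_n_larger_than_vocab_returns_all(self):
        m = _uniform_model(2, [[0.6, 0.4], [0.5, 0.5]])
        assert len(ws.top_words(m, 0, n=10)) == 2

    def test_bad_topic_id_rejected(self):
        m = _uniform_model(2, [[0.6, 0.4], [0.5, 0.5]])
        with pytest.raises(ValueError):
            ws.top_words(m, 5)


class TestScanAndFit:
    @pytest.fixture(scope="class")
    def fitted(self, small_synthetic):
        _, corpus, _ = small_synthetic
        processed, _ = ws.preprocess_corpus(corpus)
        bow = ws.build_bow([p for p in processed if p.tokens])
        return bow, ws.scan_topic_counts(bow, 2, 4, seed=9)

    def test_curve_cardinality_and_normalization(self, fitted):
        bow, scan = fitted
        assert scan.curve.ks() == [2, 3, 4]
        for model in scan.models.values():
            assert np.allclose(model.topic_word.sum(axis=1), 1.0, atol=1e-6)

    def test_scan_is_deterministic_under_seed(self, fitted):
        bow, scan = fitted
        again = ws.scan_topic_counts(bow, 2, 4, seed=9)
        assert again.curve.points == scan.curve.points

    def test_oversized_k_skipped_with_warning(self, caplog):
        bow = ws.build_bow(_docs([["a", "b"], ["b", "c"], ["c", "a"]]))
        with caplog.at_level("WARNING"):
            scan = ws.scan_topic_counts(bow, 2, 5, seed=0)
        assert scan.curve.ks() == [2, 3] and "skipping" in caplog.text
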