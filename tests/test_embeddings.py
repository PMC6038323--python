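"""Embedding training, document merging, linear maps and baselines."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bilex.corpus import ComparableCorpus, Lexicon
from bilex.embeddings import (
    BilingualEmbedding,
    EmbeddingTable,
    cosine,
    fit_translation_matrix,
    merge_documents,
    sim_baseline_predict,
    train_bwesg,
    train_monolingual,
)

token = st.sampled_from(["s1", "s2", "s3", "t1", "t2"])


class TestMergeDocuments:
    def test_ratio_pattern_4_2(self):
        out = merge_documents(["s"] * 4, ["t"] * 2, mode="ratio")
        assert out == ["s", "s", "t", "s", "s", "t"]

    def test_ratio_shorter_side_source(self):
        out = merge_documents(["s"] * 2, ["t"] * 4, mode="ratio")
        assert out == ["t", "t", "s", "t", "t", "s"]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(token, min_size=1, max_size=20),
        st.lists(token, min_size=1, max_size=20),
        st.sampled_from(["ratio", "shuffle"]),
    )
    def test_conserves_token_multiset(self, a, b, mode):
        out = merge_documents(a, b, mode=mode, seed=3)
        assert sorted(out) == sorted(a + b)

    def test_shuffle_deterministic_per_seed(self):
        a, b = ["a", "b", "c"], ["x", "y"]
        assert merge_documents(a, b, "shuffle", seed=9) == merge_documents(a, b, "shuffle", seed=9)

    def test_empty_document_raises(self):
        with pytest.raises(ValueError):
            merge_documents([], ["x"])


class TestEmbeddingTable:
    def test_word2vec_text_round_trip(self, tmp_path):
        table = EmbeddingTable(["blood cell", "nerve"], np.arange(6.0).reshape(2, 3))
        p = tmp_path / "vec.txt"
        table.save(p)
        header = p.read_text(encoding="utf-8").splitlines()[0]
        assert header == "2 3"
        loaded = EmbeddingTable.load(p)
        assert loaded.terms == ["blood cell", "nerve"]  # alias round-trips
        assert np.allclose(loaded.matrix, table.matrix)

    def test_missing_term_raises(self):
        table = EmbeddingTable(["a"], np.ones((1, 2)))
        with pytest.raises(KeyError):
            table["b"]

    def test_cosine_properties(self):
        u = np.array([1.0, 2.0])
        v = np.array([-2.0, 0.5])
        assert cosine(u, u) == pytest.approx(1.0)
        assert cosine(u, v) == pytest.approx(cosine(v, u))


def _rotation(d, seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    return q


class TestTranslationMatrix:
    def test_exact_recovery_on_rotated_space(self):
        d, n_train, n_test = 20, 60, 30
        rng = np.random.default_rng(0)
        src = rng.normal(size=(n_train + n_test, d))
        rot = _rotation(d, 1)
        tgt = src @ rot
        s_terms = [f"s{i}" for i in range(len(src))]
        t_terms = [f"t{i}" for i in range(len(src))]
        ts = EmbeddingTable(s_terms, src)
        tt = EmbeddingTable(t_terms, tgt)
        train_pairs = Lexicon({(f"s{i}", f"t{i}") for i in range(n_train)})
        lin = fit_translation_matrix(train_pairs, ts, tt)
        assert np.allclose(src[:n_train] @ lin.matrix, tgt[:n_train], atol=1e-6)
        held = [f"s{i}" for i in range(n_train, n_train + n_test)]
        preds = sim_baseline_predict(held, ts, tt, lin, mode="top")
        assert all(t == f"t{s[1:]}" for s, t, _ in preds)

    def test_identity_spaces_give_identity_map(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(30, 10))
        terms = [f"w{i}" for i in range(30)]
        table = EmbeddingTable(terms, m)
        lin = fit_translation_matrix(Lexicon({(t, t) for t in terms}), table, table)
        assert np.allclose(lin.matrix, np.eye(10), atol=1e-8)

    def test_underdetermined_warns_and_returns_min_norm(self, caplog):
        import logging

        table = EmbeddingTable(["a", "b"], np.random.default_rng(3).normal(size=(2, 10)))
        with caplog.at_level(logging.WARNING, logger="bilex.embeddings"):
            lin = fit_translation_matrix(Lexicon({("a", "a")}), table, table)
        assert "underdetermined" in caplog.text
        assert lin.matrix.shape == (10, 10)

    def test_no_usable_pairs_raises(self):
        table = EmbeddingTable(["a"], np.ones((1, 4)))
        with pytest.raises(ValueError):
            fit_translation_matrix(Lexicon({("x", "y")}), table, table)


class TestSimBaseline:
    def test_identical_vector_wins_top_mode(self):
        ts = EmbeddingTable(["s"], np.array([[1.0, 0.0]]))
        tt = EmbeddingTable(["good", "bad"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        preds = sim_baseline_predict(["s"], ts, tt, mode="top")
        assert preds == [("s", "good", pytest.approx(1.0))]

    def test_threshold_above_one_empties_all_mode(self):
        ts = EmbeddingTable(["s"], np.array([[1.0, 0.0]]))
        tt = EmbeddingTable(["x"], np.array([[1.0, 0.0]]))
        assert sim_baseline_predict(["s"], ts, tt, mode="all", threshold=1.0 + 1e-9) == []


class TestSgnsTraining:
    def test_dimension_and_coverage(self):
        docs = [["a", "b", "c", "a", "b"] * 4]
        table = train_monolingual(docs, d=8, window=2, subsample=0, seed=0, epochs=2)
        assert len(table) == 3
        assert all(table[t].shape == (8,) for t in table.terms)

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            train_monolingual([[]], d=4)

    def test_shared_context_words_are_close(self):
        # two words used in identical contexts should end up closer in
        # cosine than the average unrelated word pair
        rng = np.random.default_rng(0)
        ctx = [f"c{i}" for i in range(6)]
        docs = []
        for _ in range(300):
            frame = [ctx[int(i)] for i in rng.integers(0, 6, size=4)]
            w = "x" if rng.random() < 0.5 else "y"
            docs.append(frame[:2] + [w] + frame[2:])
            docs.append(["u" + str(int(rng.integers(0, 6)))] * 3)
        table = train_monolingual(docs, d=16, window=2, subsample=0, seed=1, epochs=8)
        sim_xy = cosine(table["x"], table["y"])
        others = [cosine(table["x"], table[f"u{i}"]) for i in range(6)]
        assert sim_xy > np.mean(others)

    def test_bwesg_covers_both_languages_and_rejects_bad_window(self):
        pairs = [(["a", "b"] * 10, ["p", "q"] * 10)]
        corpus = ComparableCorpus(pairs, ("en", "nl"))
        bil = train_bwesg(corpus, d=6, window=4, subsample=0, seed=0, epochs=1)
        assert set(bil.source.terms) == {"a", "b"}
        assert set(bil.target.terms) == {"p", "q"}
        with pytest.raises(ValueError):
            train_bwesg(corpus, d=6, window=0)

    def test_planted_translation_pair_above_random_baseline(self):
        # aligned documents about one "topic" mention the pair constantly;
        # cross-lingual cosine of the pair should beat random pairs
        rng = np.random.default_rng(5)
        pairs = []
        fill_s = [f"fs{i}" for i in range(8)]
        fill_t = [f"ft{i}" for i in range(8)]
        for di in range(60):
            use = di % 2 == 0
            ds = [("term" if use else fill_s[int(rng.integers(8))]) for _ in range(30)]
            dt = [("woord" if use else fill_t[int(rng.integers(8))]) for _ in range(30)]
            ds += [fill_s[int(i)] for i in rng.integers(0, 8, size=10)]
            dt += [fill_t[int(i)] for i in rng.integers(0, 8, size=10)]
            pairs.append((ds, dt))
        corpus = ComparableCorpus(pairs, ("en", "nl"))
        bil = train_bwesg(corpus, d=12, window=30, subsample=0, seed=2, epochs=4)
        gold = cosine(bil.source["term"], bil.target["woord"])
        randoms = [cosine(bil.source["term"], bil.target[f"ft{i}"]) for i in range(8)]
        assert gold > np.mean(randoms)
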