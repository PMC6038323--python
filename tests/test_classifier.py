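"""The pair classifier: encoding, scoring, sampling, training, tuning."""

from __future__ import annotations

import numpy as np
import pytest

from bilex.classifier import (
    PAD,
    UNK,
    CharVocab,
    ModelConfig,
    PairFeaturizer,
    PairScorer,
    TrainedModel,
    build_char_vocabs,
    classify,
    cross_entropy_loss,
    encode_char_pair,
    forward_score,
    predictions_from_scores,
    sample_negatives,
    train,
    tune_threshold,
    word_pair_representation,
)
from bilex.corpus import Lexicon, SplitLexicon, split_lexicon
from bilex.embeddings import EmbeddingTable
from bilex.evaluation import evaluate
from bilex.network import sigmoid


class TestCharVocab:
    def test_inventory_is_exactly_corpus_characters(self):
        cv = build_char_vocabs(["ab", "ba"], ["xy"])
        assert cv.chars_s == ["a", "b"]
        assert cv.chars_t == ["x", "y"]

    def test_phrase_contributes_space_character(self):
        cv = build_char_vocabs(["blood cell"], ["bloedcel"])
        assert " " in cv.chars_s
        assert cv.index_source(" ") != UNK

    def test_unseen_character_maps_to_unk(self):
        cv = build_char_vocabs(["ab"], ["xy"])
        assert cv.index_source("z") == UNK
        assert cv.index_target("a") == UNK


class TestEncodeCharPair:
    CV = build_char_vocabs(["blood cell"], ["bloedcel"])

    def test_blood_cell_bloedcel_padding(self):
        src, tgt = encode_char_pair("blood cell", "bloedcel", self.CV)
        assert len(src) == len(tgt) == 10
        assert list(tgt[-2:]) == [PAD, PAD]
        assert PAD not in src

    def test_equal_length_no_padding(self):
        src, tgt = encode_char_pair("cell", "cell", build_char_vocabs(["cell"], ["cell"]))
        assert PAD not in src and PAD not in tgt

    def test_short_source_padded(self):
        src, tgt = encode_char_pair("b", "bcd", build_char_vocabs(["b"], ["bcd"]))
        assert list(src[1:]) == [PAD, PAD]

    def test_empty_term_raises(self):
        with pytest.raises(ValueError):
            encode_char_pair("", "x", self.CV)


class TestWordRepresentation:
    def test_concatenation_matches_lookup_oracle(self):
        rng = np.random.default_rng(0)
        ts = EmbeddingTable(["s"], rng.normal(size=(1, 5)))
        tt = EmbeddingTable(["t"], rng.normal(size=(1, 5)))
        rep = word_pair_representation(("s", "t"), ts, tt)
        assert rep.shape == (10,)
        assert np.allclose(rep, np.concatenate([ts["s"], tt["t"]]))

    def test_zero_source_vector(self):
        ts = EmbeddingTable(["s"], np.zeros((1, 4)))
        tt = EmbeddingTable(["t"], np.ones((1, 4)))
        rep = word_pair_representation(("s", "t"), ts, tt)
        assert np.all(rep[:4] == 0)

    def test_missing_embedding_raises(self):
        ts = EmbeddingTable(["s"], np.zeros((1, 4)))
        with pytest.raises(KeyError):
            word_pair_representation(("nope", "s"), ts, ts)


def _tiny_char_model(hidden_layers=2, cells=6, seed=0):
    cv = build_char_vocabs(["ab", "ba", "abc"], ["xy", "yx", "xyz"])
    cfg = ModelConfig(feature_set="charpairs", lstm_cells=cells,
                      hidden_layers=hidden_layers, epochs=0, seed=seed)
    feat = PairFeaturizer(cfg, cv)
    scorer = PairScorer(cfg, feat, np.random.default_rng(seed))
    return TrainedModel(cfg, scorer, feat)


class TestForwardScore:
    def test_zero_output_layer_scores_half(self):
        model = _tiny_char_model()
        model.scorer.ffn.Wo[...] = 0
        model.scorer.ffn.bo[...] = 0
        assert forward_score(("ab", "xy"), model) == pytest.approx(0.5)

    def test_h0_wires_representation_to_output(self):
        model = _tiny_char_model(hidden_layers=0)
        pairs = [("ab", "xy")]
        rc = model.char_pair_representation(pairs)
        expect = sigmoid(rc @ model.scorer.ffn.Wo + model.scorer.ffn.bo)[:, 0]
        assert np.allclose(model.score_pairs(pairs), expect)

    def test_hand_computed_two_unit_network(self):
        # H=1 network on a 2-feature input, all weights set by hand
        cfg = ModelConfig(feature_set="ed_norm", hidden_layers=1, hidden_width=2, epochs=0)
        feat = PairFeaturizer(cfg)
        scorer = PairScorer(cfg, feat, np.random.default_rng(0))
        scorer.ffn.Ws[0][...] = [[1.0, -2.0]]
        scorer.ffn.bs[0][...] = [0.5, 0.0]
        scorer.ffn.Wo[...] = [[2.0], [-1.0]]
        scorer.ffn.bo[...] = 0.25
        x = feat.encode_batch([("blood", "bloed")])["ed"]  # ed_norm = 0.2
        h = 1 / (1 + np.exp(-(x @ [[1.0, -2.0]] + [0.5, 0.0])))
        expect = 1 / (1 + np.exp(-(h @ [[2.0], [-1.0]] + 0.25)))
        score, _ = scorer.forward({"ed": x})
        assert score[0] == pytest.approx(float(expect[0, 0]))

    def test_scores_strictly_inside_unit_interval(self):
        model = _tiny_char_model()
        s = model.score_pairs([("ab", "xy"), ("abc", "xyz"), ("ba", "yx")])
        assert np.all((s > 0) & (s < 1))

    def test_eval_mode_is_deterministic(self):
        model = _tiny_char_model()
        a = model.score_pairs([("ab", "xy")])
        b = model.score_pairs([("ab", "xy")])
        assert np.array_equal(a, b)


class TestSampleNegatives:
    VS = [f"s{i}" for i in range(20)]
    VT = [f"t{i}" for i in range(20)]
    LEX = Lexicon({("s0", "t0"), ("s1", "t1")})

    def test_exactly_2ns_negatives(self):
        negs = sample_negatives(("s0", "t0"), 5, self.VS, self.VT, self.LEX, 0)
        assert len(negs) == 10
        assert sum(1 for s, _ in negs if s == "s0") == 5
        assert sum(1 for _, t in negs if t == "t0") == 5

    def test_training_pairs_excluded(self):
        for seed in range(30):
            negs = sample_negatives(("s0", "t0"), 8, self.VS, self.VT, self.LEX, seed)
            assert not (set(negs) & self.LEX.entries)

    def test_deterministic_per_seed(self):
        a = sample_negatives(("s0", "t0"), 5, self.VS, self.VT, self.LEX, 42)
        b = sample_negatives(("s0", "t0"), 5, self.VS, self.VT, self.LEX, 42)
        assert a == b

    def test_vocabulary_too_small_raises(self):
        with pytest.raises(ValueError):
            sample_negatives(("s0", "t0"), 5, ["a"], ["b"], self.LEX, 0)


class TestLoss:
    def test_examples(self):
        assert cross_entropy_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(0.6931, abs=1e-4)
        assert cross_entropy_loss(np.array([0.999999]), np.array([1.0])) < 1e-5


def _toy_split(n=40, seed=0):
    rng = np.random.default_rng(seed)
    entries = set()
    for i in range(n):
        w = "".join("abcdef"[int(j)] for j in rng.integers(0, 6, size=6))
        entries.add((w, w[::-1]))
    return split_lexicon(Lexicon(entries), seed)


class TestTraining:
    def test_zero_epochs_returns_initialised_model(self):
        split = _toy_split()
        cfg = ModelConfig(feature_set="charpairs", lstm_cells=4, epochs=0, seed=0)
        cv = build_char_vocabs([s for s, _ in split.train.entries],
                               [t for _, t in split.train.entries])
        model = train(split, cfg, char_vocab=cv)
        assert model.loss_history == []

    def test_loss_decreases_on_learnable_data(self):
        split = _toy_split()
        cfg = ModelConfig(feature_set="charpairs", lstm_cells=12, epochs=4,
                          n_negative=2, seed=1)
        cv = build_char_vocabs([s for s, _ in split.union().entries],
                               [t for _, t in split.union().entries])
        model = train(split, cfg, char_vocab=cv)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_embeddings_frozen_during_training(self):
        split = _toy_split(30, seed=2)
        terms_s = sorted({s for s, _ in split.union().entries})
        terms_t = sorted({t for _, t in split.union().entries})
        rng = np.random.default_rng(3)
        ts = EmbeddingTable(terms_s, rng.normal(size=(len(terms_s), 8)))
        tt = EmbeddingTable(terms_t, rng.normal(size=(len(terms_t), 8)))
        before_s, before_t = ts.matrix.copy(), tt.matrix.copy()
        cfg = ModelConfig(feature_set="word", epochs=3, n_negative=2, d=8, seed=4)
        train(split, cfg, table_s=ts, table_t=tt)
        assert np.array_equal(ts.matrix, before_s)
        assert np.array_equal(tt.matrix, before_t)

    def test_separable_ed_feature_reaches_perfect_f1(self):
        # cognate-style positives (distance 0) vs long random negatives:
        # the 1-feature logistic model (H=0) must separate them perfectly
        split = _toy_split(40, seed=5)
        entries = {(s, s) for s, _ in split.union().entries}  # identical pairs
        split = split_lexicon(Lexicon(entries), 5)
        cfg = ModelConfig(feature_set="ed_norm", epochs=25, n_negative=3, seed=5)
        assert cfg.hidden_layers == 0
        model = train(split, cfg)
        test_pairs = sorted(split.test.entries)
        negs = [(s, t[::-1] + "qq") for s, t in test_pairs]
        pos_scores = model.score_pairs(test_pairs)
        neg_scores = model.score_pairs(negs)
        assert pos_scores.min() > neg_scores.max()
        t = float(neg_scores.max())
        preds = [(s, tt_) for (s, tt_), sc in zip(test_pairs, pos_scores) if sc > t]
        assert evaluate(preds, split.test, "all").f1 == 1.0


class TestThresholdTuning:
    def _model_with_scores(self, scores_by_pair):
        class Stub(TrainedModel):
            def __init__(self):
                self.threshold = None
                self.scores = scores_by_pair

            def score_pairs(self, pairs, batch_size=256):
                return np.array([self.scores[p] for p in pairs])

        stub = Stub()
        stub.featurizer = type("F", (), {"usable": staticmethod(lambda p: True)})()
        return stub

    def test_peaked_curve_returns_peak(self):
        gold = Lexicon({("a", "x")})
        scores = {("a", "x"): 0.55, ("a", "y"): 0.35}
        model = self._model_with_scores(scores)
        # t <= 0.3 keeps both (F1 2/3); t in {0.4, 0.5} keeps only the
        # correct pair (F1 1); t >= 0.6 keeps nothing -> peak at 0.4
        t = tune_threshold(model, gold, {"a": ["x", "y"]})
        assert t == pytest.approx(0.4)

    def test_flat_curve_returns_smallest_t(self):
        gold = Lexicon({("a", "x")})
        model = self._model_with_scores({("a", "x"): 0.95})
        assert tune_threshold(model, gold, {"a": ["x"]}) == pytest.approx(0.1)

    def test_matches_exhaustive_grid_oracle(self):
        rng = np.random.default_rng(9)
        gold = Lexicon({(f"s{i}", f"t{i}") for i in range(8)})
        cands = {f"s{i}": [f"t{j}" for j in range(8)] for i in range(8)}
        scores = {(s, t): float(rng.random()) for s in cands for t in cands[s]}
        model = self._model_with_scores(scores)
        t = tune_threshold(model, gold, cands)
        # independent exhaustive scan
        best = None
        for tt_ in [round(0.1 * k, 1) for k in range(1, 11)]:
            preds = [(s, c) for s in cands for c in cands[s] if scores[(s, c)] > tt_]
            f1 = evaluate(preds, gold, "all").f1
            if best is None or f1 > best[1]:
                best = (tt_, f1)
        assert t == pytest.approx(best[0])

    def test_empty_validation_raises(self):
        model = self._model_with_scores({})
        with pytest.raises(ValueError):
            tune_threshold(model, Lexicon(set()), {})


class TestClassify:
    def _scored_model(self, scores):
        class Stub(TrainedModel):
            def __init__(self):
                self.threshold = 0.7
                self._s = scores

            def score_pairs(self, pairs, batch_size=256):
                return np.array([self._s[p] for p in pairs])

        stub = Stub()
        stub.featurizer = type("F", (), {"usable": staticmethod(lambda p: True)})()
        return stub

    def test_all_mode_returns_every_pair_above_threshold(self):
        model = self._scored_model({("s", "a"): 0.9, ("s", "b"): 0.8, ("s", "c"): 0.1})
        preds = classify("s", ["a", "b", "c"], model, mode="all")
        assert {(s, t) for s, t, _ in preds} == {("s", "a"), ("s", "b")}

    def test_all_below_threshold_returns_empty(self):
        model = self._scored_model({("s", "a"): 0.2})
        assert classify("s", ["a"], model, mode="all") == []

    def test_top_mode_without_threshold_returns_exactly_one(self):
        model = self._scored_model({("s", "a"): 0.2, ("s", "b"): 0.4})
        preds = classify("s", ["a", "b"], model, mode="top", threshold=0.0)
        assert len(preds) == 1 and preds[0][1] == "b"

    def test_empty_candidates(self):
        model = self._scored_model({})
        assert classify("s", [], model) == []


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        split = _toy_split(30, seed=6)
        cfg = ModelConfig(feature_set="charpairs", lstm_cells=6, epochs=1,
                          n_negative=2, seed=6)
        cv = build_char_vocabs([s for s, _ in split.union().entries],
                               [t for _, t in split.union().entries])
        model = train(split, cfg, char_vocab=cv)
        model.threshold = 0.4
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedModel.load(path)
        pairs = sorted(split.test.entries)[:5]
        assert np.allclose(loaded.score_pairs(pairs), model.score_pairs(pairs))
        assert loaded.threshold == 0.4
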