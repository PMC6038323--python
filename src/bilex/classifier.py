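"""Translation-pair classification with word- and character-level encoders.

A candidate (source term, target term) pair is scored in (0,1) by a neural
network f; the pair is accepted when f exceeds a threshold t tuned on a
validation set, which both balances precision against recall and lets one
source keep several translations.

Feature sets:

* ``charpairs`` — the learned character-level encoder: the two character
  sequences are aligned position-by-position (the shorter term padded at
  the end, spaces treated as ordinary characters), each position's pair of
  one-hot characters is concatenated and fed to a two-layer LSTM; the
  second layer's hidden output at the final position is the pair
  representation.  Dropout (keep 0.5) is applied on the encoder's output
  connections during training only.
* ``word`` — the concatenation of the two terms' fixed, pre-trained word
  embeddings (the embedding tables are never updated during training).
* ``combined`` — word representation concatenated with the character
  representation; embeddings stay frozen while the character encoder and
  the feed-forward head train jointly.
* ``ed_norm`` / ``log_ed_rank`` / ``ed_both`` — handcrafted edit-distance
  features; being 1–2 dimensional they use no hidden layers (a logistic
  model on the features).

On top of the chosen representation sits a feed-forward head of H sigmoid
layers plus a sigmoid output unit.  Training minimises summed cross-entropy
over the seed-lexicon positives and 2*N_s uniformly sampled negatives per
positive (N_s random targets against the positive's source and N_s random
sources against its target, resampled whenever a sampled pair happens to
be in the training lexicon), with the Adam optimizer at default settings.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import candidates as cand_mod
from .corpus import Lexicon, SplitLexicon
from .embeddings import EmbeddingTable
from .evaluation import evaluate, f1_score
from .network import (
    Adam,
    FeedForward,
    LSTMLayer,
    binary_cross_entropy,
    dropout_mask,
)

logger = logging.getLogger(__name__)

PAD = 0
UNK = 1

THRESHOLD_GRID = tuple(round(0.1 * k, 1) for k in range(1, 11))

_FEATURE_SETS = ("charpairs", "word", "combined", "ed_norm", "log_ed_rank", "ed_both")


# ---------------------------------------------------------------------------
# Character vocabulary and pair encoding


@dataclass
class CharVocab:
    """Per-language character inventories with shared PAD/UNK symbols.

    Indices: 0 = PAD, 1 = UNK, then the sorted corpus characters.  The
    space character inside phrases is an ordinary inventory member.
    """

    chars_s: list[str]
    chars_t: list[str]

    def __post_init__(self):
        self._idx_s = {c: i + 2 for i, c in enumerate(self.chars_s)}
        self._idx_t = {c: i + 2 for i, c in enumerate(self.chars_t)}

    @property
    def n_source(self) -> int:
        return len(self.chars_s) + 2

    @property
    def n_target(self) -> int:
        return len(self.chars_t) + 2

    def index_source(self, ch: str) -> int:
        return self._idx_s.get(ch, UNK)

    def index_target(self, ch: str) -> int:
        return self._idx_t.get(ch, UNK)


def build_char_vocabs(vocab_s: Iterable[str], vocab_t: Iterable[str]) -> CharVocab:
    """Character inventories of exactly the characters in the vocabularies."""
    cs = sorted({ch for term in vocab_s for ch in term})
    ct = sorted({ch for term in vocab_t for ch in term})
    return CharVocab(cs, ct)


def encode_char_pair(
    source_term: str, target_term: str, char_vocab: CharVocab
) -> tuple[np.ndarray, np.ndarray]:
    """Index sequences padded to the common length max(len_s, len_t).

    Position i of the encoded pair carries (source char i or PAD,
    target char i or PAD); padding appears only at the end of the shorter
    term.
    """
    if not source_term or not target_term:
        raise ValueError("cannot encode an empty term")
    m = max(len(source_term), len(target_term))
    src = np.full(m, PAD, dtype=np.int64)
    tgt = np.full(m, PAD, dtype=np.int64)
    for i, ch in enumerate(source_term):
        src[i] = char_vocab.index_source(ch)
    for i, ch in enumerate(target_term):
        tgt[i] = char_vocab.index_target(ch)
    return src, tgt


def word_pair_representation(
    pair: tuple[str, str], table_s: EmbeddingTable, table_t: EmbeddingTable
) -> np.ndarray:
    """Concatenation of the two fixed word embeddings (length 2d)."""
    s, t = pair
    return np.concatenate([table_s[s], table_t[t]])


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class ModelConfig:
    """Hyper-parameters of the pair classifier.

    ``lstm_cells`` defaults to 512 for the character-only model and 256
    for the combined model; ``epochs`` defaults to 150 (word), 250
    (charpairs/combined) or 25 (edit-distance features); ``hidden_layers``
    defaults to 2 except for the 1–2 dimensional edit-distance features,
    which use none.  ``n_negative`` is N_s, the negatives sampled per side
    per positive (2*N_s negatives in total).
    """

    feature_set: str = "combined"
    lstm_layers: int = 2
    lstm_cells: int | None = None
    hidden_layers: int | None = None
    hidden_width: int | None = None
    dropout_keep: float = 0.5
    d: int = 50
    batch_size: int = 10
    epochs: int | None = None
    n_negative: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.feature_set not in _FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.lstm_cells is None:
            self.lstm_cells = 256 if self.feature_set == "combined" else 512
        if self.hidden_layers is None:
            self.hidden_layers = 0 if self.feature_set in ("ed_norm", "log_ed_rank", "ed_both") else 2
        if self.epochs is None:
            self.epochs = {
                "word": 150,
                "charpairs": 250,
                "combined": 250,
                "ed_norm": 25,
                "log_ed_rank": 25,
                "ed_both": 25,
            }[self.feature_set]
        if self.hidden_layers < 0:
            raise ValueError("hidden_layers must be >= 0")
        if self.lstm_layers != 2:
            raise ValueError("the character encoder is a two-layer LSTM")

    @property
    def uses_char(self) -> bool:
        return self.feature_set in ("charpairs", "combined")

    @property
    def uses_word(self) -> bool:
        return self.feature_set in ("word", "combined")

    @property
    def uses_ed(self) -> bool:
        return self.feature_set in ("ed_norm", "log_ed_rank", "ed_both")


# ---------------------------------------------------------------------------
# Featurization


class PairFeaturizer:
    """Turns (source, target) string pairs into network input batches."""

    def __init__(
        self,
        config: ModelConfig,
        char_vocab: CharVocab | None = None,
        table_s: EmbeddingTable | None = None,
        table_t: EmbeddingTable | None = None,
        target_vocab_terms: Sequence[str] | None = None,
    ):
        self.config = config
        self.char_vocab = char_vocab
        self.table_s = table_s
        self.table_t = table_t
        self.target_vocab_terms = list(target_vocab_terms) if target_vocab_terms else None
        self._rank_cache: dict[str, dict[str, int]] = {}
        if config.uses_char and char_vocab is None:
            raise ValueError(f"feature set {config.feature_set!r} needs a CharVocab")
        if config.uses_word and (table_s is None or table_t is None):
            raise ValueError(f"feature set {config.feature_set!r} needs embedding tables")
        if config.feature_set in ("log_ed_rank", "ed_both") and self.target_vocab_terms is None:
            raise ValueError("log(ED_rank) features need the target vocabulary")

    @property
    def char_input_dim(self) -> int:
        return self.char_vocab.n_source + self.char_vocab.n_target

    @property
    def word_dim(self) -> int:
        return self.table_s.d + self.table_t.d

    @property
    def ed_dim(self) -> int:
        return {"ed_norm": 1, "log_ed_rank": 1, "ed_both": 2}.get(self.config.feature_set, 0)

    def usable(self, pair: tuple[str, str]) -> bool:
        s, t = pair
        if not s or not t:
            return False
        if self.config.uses_word and (s not in self.table_s or t not in self.table_t):
            return False
        return True

    def _ranks_for(self, source: str) -> dict[str, int]:
        if source not in self._rank_cache:
            self._rank_cache[source] = cand_mod.ed_ranks(source, self.target_vocab_terms)
        return self._rank_cache[source]

    def encode_batch(self, pairs: Sequence[tuple[str, str]]) -> dict:
        cfg = self.config
        batch: dict = {"pairs": list(pairs)}
        if cfg.uses_char:
            encoded = [encode_char_pair(s, t, self.char_vocab) for s, t in pairs]
            lengths = [len(e[0]) for e in encoded]
            T = max(lengths)
            B = len(pairs)
            n_s = self.char_vocab.n_source
            x = np.zeros((B, T, self.char_input_dim))
            mask = np.zeros((B, T))
            rows = np.arange(T)
            for bi, ((src, tgt), m) in enumerate(zip(encoded, lengths)):
                x[bi, rows[:m], src] = 1.0
                x[bi, rows[:m], n_s + tgt] = 1.0
                mask[bi, :m] = 1.0
            batch["char_x"] = x
            batch["char_mask"] = mask
        if cfg.uses_word:
            batch["word"] = np.stack(
                [word_pair_representation(p, self.table_s, self.table_t) for p in pairs]
            )
        if cfg.uses_ed:
            feats = []
            for s, t in pairs:
                row = []
                if cfg.feature_set in ("ed_norm", "ed_both"):
                    row.append(cand_mod.ed_norm(s, t))
                if cfg.feature_set in ("log_ed_rank", "ed_both"):
                    ranks = self._ranks_for(s)
                    if t not in ranks:
                        raise KeyError(f"target {t!r} not in vocabulary for rank feature")
                    row.append(math.log(ranks[t]))
                feats.append(row)
            batch["ed"] = np.array(feats)
        return batch


# ---------------------------------------------------------------------------
# The scoring network


class PairScorer:
    """LSTM character encoder (optional) + feed-forward head."""

    def __init__(self, config: ModelConfig, featurizer: PairFeaturizer, rng: np.random.Generator):
        self.config = config
        self.lstm1 = self.lstm2 = None
        r0_dim = 0
        if config.uses_word:
            r0_dim += featurizer.word_dim
        if config.uses_char:
            self.lstm1 = LSTMLayer(featurizer.char_input_dim, config.lstm_cells, rng)
            self.lstm2 = LSTMLayer(config.lstm_cells, config.lstm_cells, rng)
            r0_dim += config.lstm_cells
        if config.uses_ed:
            r0_dim += featurizer.ed_dim
        self.r0_dim = r0_dim
        self.ffn = FeedForward(r0_dim, config.hidden_layers, config.hidden_width, rng)

    def params(self) -> list[np.ndarray]:
        out = []
        if self.lstm1 is not None:
            out.extend(self.lstm1.params())
            out.extend(self.lstm2.params())
        out.extend(self.ffn.params())
        return out

    def char_representation(self, batch: dict, train: bool = False,
                            rng: np.random.Generator | None = None):
        x, mask = batch["char_x"], batch["char_mask"]
        h1, c1 = self.lstm1.forward(x, mask)
        if train:
            d1 = dropout_mask(h1.shape, self.config.dropout_keep, rng)
        else:
            d1 = None
        h1d = h1 * d1 if d1 is not None else h1
        h2, c2 = self.lstm2.forward(h1d, mask)
        rc = h2[:, -1]
        cache = (c1, c2, d1)
        return rc, cache

    def forward(self, batch: dict, train: bool = False,
                rng: np.random.Generator | None = None):
        cfg = self.config
        parts = []
        char_cache = None
        rc_dropped = None
        if cfg.uses_word:
            parts.append(batch["word"])
        if cfg.uses_char:
            rc, char_cache = self.char_representation(batch, train, rng)
            if train:
                d2 = dropout_mask(rc.shape, cfg.dropout_keep, rng)
            else:
                d2 = None
            rc_dropped = rc * d2 if d2 is not None else rc
            char_cache = char_cache + (d2,)
            parts.append(rc_dropped)
        if cfg.uses_ed:
            parts.append(batch["ed"])
        r0 = np.concatenate(parts, axis=1) if len(parts) > 1 else parts[0]
        score, ffn_cache = self.ffn.forward(r0)
        return score, (batch, char_cache, ffn_cache)

    def backward(self, dlogit: np.ndarray, cache):
        batch, char_cache, ffn_cache = cache
        cfg = self.config
        dr0, ffn_grads = self.ffn.backward(dlogit, ffn_cache)
        grads: list[np.ndarray] = []
        offset = 0
        if cfg.uses_word:
            offset += batch["word"].shape[1]
        if cfg.uses_char:
            c1, c2, d1, d2 = char_cache
            drc = dr0[:, offset:offset + cfg.lstm_cells]
            if d2 is not None:
                drc = drc * d2
            B, T = batch["char_mask"].shape
            dh2 = np.zeros((B, T, cfg.lstm_cells))
            dh2[:, -1] = drc
            dh1d, g2 = self.lstm2.backward(dh2, c2)
            if d1 is not None:
                dh1d = dh1d * d1
            _, g1 = self.lstm1.backward(dh1d, c1)
            grads.extend(g1)
            grads.extend(g2)
        grads.extend(ffn_grads)
        return grads


# ---------------------------------------------------------------------------
# Negative sampling


def sample_negatives(
    positive: tuple[str, str],
    n_s: int,
    vocab_s_terms: Sequence[str],
    vocab_t_terms: Sequence[str],
    train_lexicon: Lexicon,
    seed_or_rng,
    max_resample: int = 1000,
) -> list[tuple[str, str]]:
    """2*N_s noise pairs for one positive: N_s random targets paired with
    the positive's source and N_s random sources paired with its target.

    A sampled pair that occurs in the training lexicon is resampled.
    Reproducible per seed.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    s, t = positive
    if len(vocab_t_terms) <= n_s or len(vocab_s_terms) <= n_s:
        raise ValueError("vocabulary too small for the requested number of negatives")
    train_pairs = train_lexicon.entries
    out: list[tuple[str, str]] = []
    for terms, fixed, fix_source in ((vocab_t_terms, s, True), (vocab_s_terms, t, False)):
        got = 0
        tries = 0
        while got < n_s:
            idx = int(rng.integers(len(terms)))
            pair = (fixed, terms[idx]) if fix_source else (terms[idx], fixed)
            tries += 1
            if pair in train_pairs:
                if tries > max_resample:
                    raise ValueError("cannot sample negatives outside the training lexicon")
                continue
            out.append(pair)
            got += 1
    return out


def cross_entropy_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Summed cross-entropy over positives and negatives (clamped at 1e-7)."""
    return binary_cross_entropy(scores, labels)


# ---------------------------------------------------------------------------
# Trained model


@dataclass
class TrainedModel:
    config: ModelConfig
    scorer: PairScorer
    featurizer: PairFeaturizer
    threshold: float | None = None
    loss_history: list[float] = field(default_factory=list)

    def score_pairs(self, pairs: Sequence[tuple[str, str]], batch_size: int = 256) -> np.ndarray:
        """Classification scores in (0,1), deterministic (dropout off)."""
        if not pairs:
            return np.zeros(0)
        out = []
        for start in range(0, len(pairs), batch_size):
            chunk = pairs[start:start + batch_size]
            batch = self.featurizer.encode_batch(chunk)
            scores, _ = self.scorer.forward(batch, train=False)
            out.append(scores)
        return np.concatenate(out)

    def char_pair_representation(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        """The character encoder's output r_c for each pair (eval mode)."""
        if not self.config.uses_char:
            raise ValueError("model has no character encoder")
        batch = self.featurizer.encode_batch(pairs)
        rc, _ = self.scorer.char_representation(batch, train=False)
        return rc

    def save(self, path) -> None:
        """Single-file checkpoint: config, parameters, char vocab,
        threshold, embedding fingerprints."""
        meta = {
            "config": asdict(self.config),
            "threshold": self.threshold,
            "loss_history": self.loss_history,
            "char_vocab": (
                {"chars_s": self.featurizer.char_vocab.chars_s,
                 "chars_t": self.featurizer.char_vocab.chars_t}
                if self.featurizer.char_vocab
                else None
            ),
            "embedding_fingerprints": {
                "source": _fingerprint(self.featurizer.table_s),
                "target": _fingerprint(self.featurizer.table_t),
            },
            "target_vocab_terms": self.featurizer.target_vocab_terms,
        }
        arrays = {f"p{i}": p for i, p in enumerate(self.scorer.params())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path, table_s: EmbeddingTable | None = None,
             table_t: EmbeddingTable | None = None) -> "TrainedModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        config = ModelConfig(**meta["config"])
        cv = CharVocab(**meta["char_vocab"]) if meta["char_vocab"] else None
        fp = meta["embedding_fingerprints"]
        for table, want, side in ((table_s, fp["source"], "source"), (table_t, fp["target"], "target")):
            if want is not None and table is not None and _fingerprint(table) != want:
                logger.warning("%s embedding fingerprint differs from checkpoint", side)
        feat = PairFeaturizer(config, cv, table_s, table_t, meta["target_vocab_terms"])
        scorer = PairScorer(config, feat, np.random.default_rng(config.seed))
        for i, p in enumerate(scorer.params()):
            p[...] = data[f"p{i}"]
        return cls(config, scorer, feat, meta["threshold"], meta["loss_history"])


def _fingerprint(table: EmbeddingTable | None) -> str | None:
    if table is None:
        return None
    return f"{len(table)}x{table.d}:{float(np.sum(table.matrix)):.6g}"


def forward_score(pair: tuple[str, str], model: TrainedModel) -> float:
    """Classification score of one pair (strictly inside (0,1))."""
    return float(model.score_pairs([pair])[0])


# ---------------------------------------------------------------------------
# Training


def train(
    split: SplitLexicon,
    config: ModelConfig,
    char_vocab: CharVocab | None = None,
    table_s: EmbeddingTable | None = None,
    table_t: EmbeddingTable | None = None,
    vocab_s_terms: Sequence[str] | None = None,
    vocab_t_terms: Sequence[str] | None = None,
    log_every: int = 0,
) -> TrainedModel:
    """Mini-batch training of the pair classifier on a split lexicon.

    Word embedding tables are fixed throughout; the character encoder and
    feed-forward head train jointly.  Per-epoch mean loss is recorded in
    the returned model's ``loss_history``.  ``epochs = 0`` returns the
    initialised model unchanged.
    """
    feat = PairFeaturizer(config, char_vocab, table_s, table_t, vocab_t_terms)
    rng = np.random.default_rng(config.seed)
    scorer = PairScorer(config, feat, rng)
    model = TrainedModel(config, scorer, feat)
    positives = [p for p in sorted(split.train.entries) if feat.usable(p)]
    if not positives:
        raise ValueError("no usable training pairs")
    dropped = len(split.train.entries) - len(positives)
    if dropped:
        logger.warning("train: %d training pairs unusable under feature set %s",
                       dropped, config.feature_set)
    if vocab_s_terms is None:
        vocab_s_terms = sorted({s for s, _ in positives})
    if vocab_t_terms is None:
        vocab_t_terms = sorted({t for _, t in positives})
    if config.uses_word:
        vocab_s_terms = [w for w in vocab_s_terms if w in table_s]
        vocab_t_terms = [w for w in vocab_t_terms if w in table_t]
    opt = Adam(scorer.params())
    for epoch in range(config.epochs):
        examples: list[tuple[tuple[str, str], int]] = []
        for pos in positives:
            examples.append((pos, 1))
            for neg in sample_negatives(pos, config.n_negative, vocab_s_terms,
                                        vocab_t_terms, split.train, rng):
                examples.append((neg, 0))
        # batches bucket similar padded lengths (stable sort over a random
        # permutation) and run in random order: same shuffled SGD, less
        # wasted computation on batch padding
        order = rng.permutation(len(examples))
        lengths = np.array(
            [max(len(examples[i][0][0]), len(examples[i][0][1])) for i in order]
        )
        order = order[np.argsort(lengths, kind="stable")]
        batch_starts = rng.permutation(
            np.arange(0, len(order), config.batch_size)
        )
        total_loss = 0.0
        for start in batch_starts:
            idx = order[start:start + config.batch_size]
            pairs = [examples[i][0] for i in idx]
            labels = np.array([examples[i][1] for i in idx], dtype=float)
            batch = feat.encode_batch(pairs)
            scores, cache = scorer.forward(batch, train=True, rng=rng)
            total_loss += cross_entropy_loss(scores, labels)
            dlogit = scores - labels  # d(BCE)/d(pre-sigmoid output)
            grads = scorer.backward(dlogit, cache)
            opt.step(grads)
        mean_loss = total_loss / len(examples)
        if not np.isfinite(mean_loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: mean loss {mean_loss}"
            )
        model.loss_history.append(mean_loss)
        if log_every and (epoch + 1) % log_every == 0:
            logger.info("epoch %d/%d mean loss %.4f", epoch + 1, config.epochs, mean_loss)
    return model


# ---------------------------------------------------------------------------
# Threshold tuning and prediction


def predictions_from_scores(
    scored: Mapping[str, Sequence[tuple[str, float]]],
    threshold: float,
    mode: str = "all",
    require_threshold: bool = True,
) -> list[tuple[str, str, float]]:
    """Turn per-source candidate scores into thresholded predictions."""
    out = []
    for s, cands in scored.items():
        if not cands:
            continue
        if mode == "top":
            t_best, sc_best = max(cands, key=lambda c: (c[1], c[0]))
            if sc_best > threshold or not require_threshold:
                out.append((s, t_best, sc_best))
        else:
            out.extend((s, t, sc) for t, sc in cands if sc > threshold)
    return out


def score_candidates(
    model: TrainedModel, candidate_sets: Mapping[str, Iterable[str]]
) -> dict[str, list[tuple[str, float]]]:
    """Classifier scores for every (source, candidate) pair."""
    flat: list[tuple[str, str]] = []
    for s, cands in candidate_sets.items():
        flat.extend((s, t) for t in cands)
    usable = [p for p in flat if model.featurizer.usable(p)]
    scores = model.score_pairs(usable)
    scored: dict[str, list[tuple[str, float]]] = {s: [] for s in candidate_sets}
    for (s, t), sc in zip(usable, scores):
        scored[s].append((t, float(sc)))
    return scored


def tune_threshold(
    model: TrainedModel,
    validation: Lexicon,
    candidate_sets: Mapping[str, Iterable[str]],
    mode: str = "all",
    grid: Sequence[float] = THRESHOLD_GRID,
    known: Lexicon | None = None,
) -> float:
    """Grid-search t maximizing validation F1; ties go to the smallest t.

    ``known`` pairs (e.g. the training lexicon) are removed from the
    candidate pool first, mirroring the mining protocol at test time.
    """
    if not validation.entries:
        raise ValueError("empty validation set")
    if known is not None:
        candidate_sets = {
            s: [t for t in cands if (s, t) not in known.entries]
            for s, cands in candidate_sets.items()
        }
    scored = score_candidates(model, candidate_sets)
    best_t, best_f1 = None, -1.0
    for t in grid:
        preds = predictions_from_scores(scored, t, mode)
        rep = evaluate(preds, validation, mode)
        if rep.f1 > best_f1:
            best_t, best_f1 = t, rep.f1
    model.threshold = best_t
    return best_t


def classify(
    source_term: str,
    candidate_targets: Iterable[str],
    model: TrainedModel,
    mode: str = "all",
    threshold: float | None = None,
    require_threshold: bool = True,
) -> list[tuple[str, str, float]]:
    """Predicted translations of one source among its candidates.

    ``all`` mode returns every candidate scoring above the threshold;
    ``top`` mode the argmax candidate (also above the threshold unless
    ``require_threshold`` is off).  Empty candidate set -> no predictions.
    """
    t = model.threshold if threshold is None else threshold
    if t is None:
        raise ValueError("threshold not tuned; call tune_threshold first")
    cands = [c for c in candidate_targets if model.featurizer.usable((source_term, c))]
    if not cands:
        return []
    scores = model.score_pairs([(source_term, c) for c in cands])
    scored = {source_term: list(zip(cands, (float(x) for x in scores)))}
    return predictions_from_scores(scored, t, mode, require_threshold)
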