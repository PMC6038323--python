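"""Word-level representations for translation mining.

Two embedding regimes are supported:

* monolingual skip-gram with negative sampling (SGNS) per language, with a
  small context window (default 5), optionally bridged by a least-squares
  linear map fitted on training translation pairs;
* a pseudo-bilingual variant: each topic-aligned document pair is merged
  into one mixed-language pseudo-document (length-ratio interleaving or a
  seeded shuffle) and a single SGNS model with a large window (default 100)
  is trained over the result, so that translation pairs share contexts and
  land close together in one space.

The SGNS trainer is a compact vectorised numpy implementation of the
standard objective (sigmoid dot-product scoring, frequency^0.75 negative
sampling, word2vec-style frequency subsampling, linearly decaying learning
rate).  Contracts are the objective and hyper-parameters, not bit-exact
vectors; all downstream checks are tolerance- or rank-based.

Embeddings are serialised in word2vec text format ("count dim" header,
then one term and its coordinates per line); multi-word terms are written
with underscore-joined aliases.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import ComparableCorpus
from .phrases import alias_to_term, check_alias_bijection, phrase_alias

logger = logging.getLogger(__name__)

TokenDoc = list[str]


class EmbeddingTable:
    """term -> d-dimensional vector map for one language (or one view of a
    shared bilingual space)."""

    def __init__(self, terms: Sequence[str], matrix: np.ndarray, tag: str = ""):
        if len(terms) != matrix.shape[0]:
            raise ValueError("terms/matrix row mismatch")
        self.terms = list(terms)
        self.matrix = np.asarray(matrix, dtype=np.float64)
        self.tag = tag
        self.index = {t: i for i, t in enumerate(self.terms)}
        self._unit = None

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term: str) -> np.ndarray:
        try:
            return self.matrix[self.index[term]]
        except KeyError:
            raise KeyError(f"term {term!r} has no embedding") from None

    def unit_matrix(self) -> np.ndarray:
        if self._unit is None:
            norms = np.linalg.norm(self.matrix, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            self._unit = self.matrix / norms
        return self._unit

    def save(self, path: str | Path) -> None:
        check_alias_bijection(self.terms)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.terms)} {self.d}\n")
            for t, row in zip(self.terms, self.matrix):
                coords = " ".join(f"{x:.6g}" for x in row)
                fh.write(f"{phrase_alias(t)} {coords}\n")

    @classmethod
    def load(cls, path: str | Path, tag: str = "") -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, d = int(header[0]), int(header[1])
            terms, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                terms.append(alias_to_term(parts[0]))
                rows.append([float(x) for x in parts[1 : d + 1]])
        if len(terms) != n:
            raise ValueError(f"{path}: header promises {n} vectors, found {len(terms)}")
        return cls(terms, np.array(rows), tag)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


# ---------------------------------------------------------------------------
# SGNS trainer


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


def _train_sgns(
    docs: Sequence[TokenDoc],
    d: int,
    window: int,
    subsample: float,
    seed: int,
    epochs: int,
    negative: int,
    lr0: float = 0.025,
    batch: int = 4096,
) -> tuple[list[str], np.ndarray]:
    rng = np.random.default_rng(seed)
    counts = Counter(t for doc in docs for t in doc)
    if not counts:
        raise ValueError("empty vocabulary: no tokens to train on")
    types = sorted(counts, key=lambda t: (-counts[t], t))
    index = {t: i for i, t in enumerate(types)}
    freqs = np.array([counts[t] for t in types], dtype=np.float64)
    total = freqs.sum()

    # word2vec subsampling keep-probability for frequent tokens
    if subsample > 0:
        f = freqs / total
        keep = np.minimum(1.0, np.sqrt(subsample / f) + subsample / f)
    else:
        keep = np.ones_like(freqs)

    noise = freqs ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    w_in = (rng.random((len(types), d)) - 0.5) / d
    w_out = np.zeros((len(types), d))

    doc_ids = [np.array([index[t] for t in doc], dtype=np.int64) for doc in docs]

    pairs_done = 0
    est_total_pairs = None  # set from the first epoch's actual pair count
    for epoch in range(epochs):
        centers_all, ctx_all = [], []
        for ids in doc_ids:
            if subsample > 0:
                kept = ids[rng.random(len(ids)) < keep[ids]]
            else:
                kept = ids
            L = len(kept)
            if L < 2:
                continue
            # per-position reduced window b_i ~ U{1..window}; the ordered
            # pair (center i, context i+k) exists iff b_i >= k, and
            # (center i+k, context i) iff b_{i+k} >= k
            b = rng.integers(1, window + 1, size=L)
            for k in range(1, min(window, L - 1) + 1):
                fwd = b[: L - k] >= k
                if fwd.any():
                    centers_all.append(kept[:-k][fwd])
                    ctx_all.append(kept[k:][fwd])
                bwd = b[k:] >= k
                if bwd.any():
                    centers_all.append(kept[k:][bwd])
                    ctx_all.append(kept[:-k][bwd])
        if not centers_all:
            continue
        centers = np.concatenate(centers_all)
        contexts = np.concatenate(ctx_all)
        if est_total_pairs is None:
            est_total_pairs = len(centers) * epochs
        order = rng.permutation(len(centers))
        centers, contexts = centers[order], contexts[order]
        for start in range(0, len(centers), batch):
            c = centers[start : start + batch]
            x = contexts[start : start + batch]
            lr = max(lr0 * (1 - pairs_done / est_total_pairs), lr0 * 1e-2)
            pairs_done += len(c)
            # noise words are shared across the mini-batch so the negative
            # term becomes two dense matmuls instead of a scatter per pair;
            # the pool is larger than the per-pair count to compensate for
            # the sharing, and each pair's negative coefficient is scaled
            # back to `negative` expected noise contrasts
            pool = max(4 * negative, 64)
            negs = np.unique(np.searchsorted(noise_cdf, rng.random(pool)))
            u = w_in[c]
            vx = w_out[x]
            vn = w_out[negs]
            coef_pos = _sigmoid(np.einsum("bd,bd->b", u, vx)) - 1.0
            coef_neg = _sigmoid(u @ vn.T) * (negative / len(negs))  # (B, K)
            du = coef_pos[:, None] * vx + coef_neg @ vn
            np.add.at(w_in, c, -lr * du)
            np.add.at(w_out, x, -lr * coef_pos[:, None] * u)
            w_out[negs] -= lr * (coef_neg.T @ u)
    return types, w_in


def train_monolingual(
    docs: Sequence[TokenDoc],
    d: int = 50,
    window: int = 5,
    subsample: float = 1e-4,
    seed: int = 0,
    epochs: int = 5,
    negative: int = 5,
    tag: str = "",
) -> EmbeddingTable:
    """Skip-gram-with-negative-sampling embeddings for one corpus side.

    ``docs`` is the retokenized corpus (phrases as single tokens).  Every
    token type receives a vector.  Deterministic for a fixed seed.
    """
    types, w_in = _train_sgns(docs, d, window, subsample, seed, epochs, negative)
    return EmbeddingTable(types, w_in, tag)


# ---------------------------------------------------------------------------
# Pseudo-bilingual (merged-document) embeddings


def merge_documents(
    doc_s: TokenDoc, doc_t: TokenDoc, mode: str = "ratio", seed: int | None = None
) -> TokenDoc:
    """Merge an aligned document pair into one pseudo-document.

    ``ratio`` mode interleaves in original order, emitting
    ceil(|longer|/|shorter|) tokens of the longer side per token of the
    shorter side; ``shuffle`` mode permutes the concatenation with a fixed
    seed.  Token multisets are conserved exactly.
    """
    if not doc_s or not doc_t:
        raise ValueError("merge_documents requires two non-empty documents")
    if mode == "shuffle":
        rng = np.random.default_rng(0 if seed is None else seed)
        merged = list(doc_s) + list(doc_t)
        return [merged[i] for i in rng.permutation(len(merged))]
    if mode != "ratio":
        raise ValueError(f"unknown merge mode {mode!r}")
    if len(doc_s) >= len(doc_t):
        longer, shorter = list(doc_s), list(doc_t)
    else:
        longer, shorter = list(doc_t), list(doc_s)
    k = math.ceil(len(longer) / len(shorter))
    out: TokenDoc = []
    li = 0
    for si in range(len(shorter)):
        out.extend(longer[li : li + k])
        li += k
        out.append(shorter[si])
    out.extend(longer[li:])
    return out


@dataclass
class BilingualEmbedding:
    """Two per-language views of one shared embedding space."""

    source: EmbeddingTable
    target: EmbeddingTable

    def cross_similarities(self, source_term: str) -> dict[str, float] | None:
        """Cosine of ``source_term`` against every embedded target term."""
        if source_term not in self.source:
            return None
        v = self.source[source_term]
        nv = np.linalg.norm(v)
        if nv == 0:
            return None
        sims = self.target.unit_matrix() @ (v / nv)
        return dict(zip(self.target.terms, sims.tolist()))


_LANG_SEP = "‖"  # internal language prefix separator, stripped on lookup


def train_bwesg(
    corpus: ComparableCorpus,
    d: int = 50,
    window: int = 100,
    subsample: float = 1e-4,
    seed: int = 0,
    epochs: int = 5,
    negative: int = 5,
    merge_mode: str = "ratio",
) -> BilingualEmbedding:
    """Shared-space embeddings from merged topic-aligned document pairs.

    Tokens are internally prefixed with their language tag so homographs
    across languages cannot collide; the prefix is stripped in the
    returned per-language views.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    ls, lt = corpus.language_tags
    merged_docs = []
    for i, (s, t) in enumerate(corpus.pairs):
        ps = [f"{ls}{_LANG_SEP}{w}" for w in s]
        pt = [f"{lt}{_LANG_SEP}{w}" for w in t]
        merged_docs.append(
            merge_documents(ps, pt, mode=merge_mode, seed=None if seed is None else seed + i)
        )
    types, w_in = _train_sgns(merged_docs, d, window, subsample, seed, epochs, negative)
    s_terms, s_rows, t_terms, t_rows = [], [], [], []
    for term, row in zip(types, w_in):
        lang, _, bare = term.partition(_LANG_SEP)
        if lang == ls:
            s_terms.append(bare)
            s_rows.append(row)
        else:
            t_terms.append(bare)
            t_rows.append(row)
    return BilingualEmbedding(
        EmbeddingTable(s_terms, np.array(s_rows), tag="bilingual:" + ls),
        EmbeddingTable(t_terms, np.array(t_rows), tag="bilingual:" + lt),
    )


# ---------------------------------------------------------------------------
# Linear translation map and similarity baselines


@dataclass
class LinearMap:
    """d x d least-squares map from the source space into the target space.

    Applied on row vectors: predicted target vector = x @ matrix.
    """

    matrix: np.ndarray

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return x @ self.matrix


def fit_translation_matrix(pairs, table_s: EmbeddingTable, table_t: EmbeddingTable) -> LinearMap:
    """Least-squares M minimizing sum ||x_i M - z_i||^2 over training pairs."""
    entries = pairs.entries if hasattr(pairs, "entries") else pairs
    usable = [(s, t) for s, t in entries if s in table_s and t in table_t]
    if not usable:
        raise ValueError("no training pair has embeddings on both sides")
    if len(usable) < table_s.d:
        logger.warning(
            "only %d usable pairs for a %d-dim map: underdetermined, "
            "minimum-norm least-squares solution returned",
            len(usable),
            table_s.d,
        )
    X = np.array([table_s[s] for s, _ in usable])
    Z = np.array([table_t[t] for _, t in usable])
    M, *_ = np.linalg.lstsq(X, Z, rcond=None)
    return LinearMap(M)


def sim_baseline_predict(
    source_terms: Iterable[str],
    table_s: EmbeddingTable,
    table_t: EmbeddingTable,
    linear_map: LinearMap | None = None,
    mode: str = "top",
    threshold: float = 0.0,
) -> list[tuple[str, str, float]]:
    """Similarity-driven translation prediction (cosine in a shared space).

    ``top`` mode returns the argmax-cosine target per source; ``all`` mode
    every target with cosine above ``threshold``.  Sources without an
    embedding are skipped with a warning.
    """
    if mode not in ("top", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    unit_t = table_t.unit_matrix()
    out = []
    for s in source_terms:
        if s not in table_s:
            logger.warning("sim_baseline_predict: %r has no embedding; skipped", s)
            continue
        v = table_s[s]
        if linear_map is not None:
            v = linear_map(v)
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        sims = unit_t @ (v / nv)
        if mode == "top":
            j = int(np.argmax(sims))
            out.append((s, table_t.terms[j], float(sims[j])))
        else:
            for j in np.flatnonzero(sims > threshold):
                out.append((s, table_t.terms[int(j)], float(sims[int(j)])))
    return out
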