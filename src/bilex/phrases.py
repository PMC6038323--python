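"""Collocation-based phrase extraction and vocabulary construction.

Multi-word terms (e.g. "autoimmune disease") are found by iteratively
scoring adjacent token bigrams,

    score(w_i, w_j) = (Count(w_i, w_j) - delta) / (Count(w_i) * Count(w_j)) * |V|,

merging every bigram whose score exceeds a per-language threshold into a
single phrase token, and repeating so that merged phrases can combine with
neighbouring words in later iterations.  The discount ``delta`` suppresses
phrases built from very infrequent words.  After k iterations phrases span
at most k+1 words (4 iterations -> 5-grams).

Phrase tokens are stored with single internal spaces; an underscore-joined
alias is available wherever a whitespace-free token is needed (embedding
training), with a bijective mapping enforced.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

TokenDoc = list[str]


@dataclass
class PhraseConfig:
    threshold: float
    delta: float
    iterations: int = 4

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass
class Vocabulary:
    """Map term -> corpus frequency for one language.

    Single-word terms respect a minimum count; phrase terms (internal
    spaces) are exempt by default.  A word that occurs in the corpus only
    inside an extracted phrase is absent (no standalone representation
    could be learned for it).
    """

    terms: dict[str, int]
    language: str = ""

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def count(self, term: str) -> int:
        return self.terms.get(term, 0)

    def words(self) -> list[str]:
        return [t for t in self.terms if " " not in t]

    def phrases(self) -> list[str]:
        return [t for t in self.terms if " " in t]

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term, count in sorted(self.terms.items()):
                fh.write(f"{term}\t{count}\n")

    @classmethod
    def load(cls, path: str | Path, language: str = "") -> "Vocabulary":
        terms = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if line:
                term, count = line.rsplit("\t", 1)
                terms[term] = int(count)
        return cls(terms, language)


def phrase_alias(term: str) -> str:
    """Whitespace-free alias of a (possibly multi-word) term."""
    return term.replace(" ", "_")


def alias_to_term(alias: str) -> str:
    return alias.replace("_", " ")


def check_alias_bijection(terms: Iterable[str]) -> None:
    seen: dict[str, str] = {}
    for term in terms:
        a = phrase_alias(term)
        if a in seen and seen[a] != term:
            raise ValueError(f"underscore alias collision: {seen[a]!r} vs {term!r}")
        seen[a] = term


def bigram_score(count_ij: int, count_i: int, count_j: int, delta: float, v_size: int) -> float:
    """Collocation score of an adjacent bigram; linear in vocabulary size."""
    if count_i <= 0 or count_j <= 0:
        raise ValueError("unigram counts must be positive")
    return (count_ij - delta) / (count_i * count_j) * v_size


def _n_words(token: str) -> int:
    return token.count(" ") + 1


def extract_phrases(
    docs: Sequence[TokenDoc], config: PhraseConfig
) -> tuple[list[TokenDoc], set[str]]:
    """Iteratively merge high-scoring adjacent bigrams into phrase tokens.

    Merging is greedy left-to-right and non-overlapping within each
    iteration (ties go to the leftmost bigram); a merge at iteration k is
    allowed only if the resulting phrase spans at most k+1 words.  Returns
    the retokenized documents and the set of extracted phrase tokens.
    Joining every phrase token's words back reproduces the input exactly.
    """
    docs = [list(d) for d in docs]
    for it in range(1, config.iterations + 1):
        uni = Counter(itertools.chain.from_iterable(docs))
        big = Counter()
        for d in docs:
            big.update(zip(d, d[1:]))
        v_size = len(uni)
        max_words = it + 1
        merges = set()
        for (a, b), c_ab in big.items():
            if _n_words(a) + _n_words(b) > max_words:
                continue
            if bigram_score(c_ab, uni[a], uni[b], config.delta, v_size) > config.threshold:
                merges.add((a, b))
        if not merges:
            break
        new_docs = []
        for d in docs:
            out, i = [], 0
            while i < len(d):
                if i + 1 < len(d) and (d[i], d[i + 1]) in merges:
                    out.append(d[i] + " " + d[i + 1])
                    i += 2
                else:
                    out.append(d[i])
                    i += 1
            new_docs.append(out)
        docs = new_docs
    phrase_set = {t for d in docs for t in d if " " in t}
    return docs, phrase_set


def expand_phrases(docs: Sequence[TokenDoc]) -> list[TokenDoc]:
    """Undo retokenization: split phrase tokens back into their words."""
    return [[w for tok in d for w in tok.split(" ")] for d in docs]


def build_vocabulary(
    docs: Sequence[TokenDoc],
    min_count: int = 5,
    language: str = "",
    phrase_min_count: int = 1,
) -> Vocabulary:
    """Build the vocabulary from a retokenized corpus.

    Counts are taken after retokenization, so a word absorbed entirely
    into phrases (the "new york"/"york" rule) is excluded.
    """
    counts = Counter(itertools.chain.from_iterable(docs))
    terms = {
        t: c
        for t, c in counts.items()
        if c >= (phrase_min_count if " " in t else min_count)
    }
    check_alias_bijection(terms)
    return Vocabulary(terms, language)


def phrase_recall(lexicon_terms: Iterable[str], vocab: Vocabulary, phrases_only: bool = True) -> float:
    """Fraction of (multi-word) lexicon terms present in the vocabulary."""
    terms = [t for t in set(lexicon_terms) if (" " in t) or not phrases_only]
    if not terms:
        return 0.0
    return sum(1 for t in terms if t in vocab) / len(terms)


def tune_extraction(
    docs: Sequence[TokenDoc],
    lexicon_terms: Iterable[str],
    delta_grid: Sequence[float],
    threshold_grid: Sequence[float],
    iterations: int = 4,
    min_count: int = 5,
) -> PhraseConfig:
    """Grid-search (delta, threshold) maximizing training-lexicon phrase recall.

    Ties are broken towards the *higher* threshold (fewer, cleaner
    phrases).  When every setting has recall 0 the highest threshold is
    returned with a warning.
    """
    delta_grid = list(delta_grid)
    threshold_grid = list(threshold_grid)
    if not delta_grid or not threshold_grid:
        raise ValueError("empty tuning grid")
    terms = list(lexicon_terms)
    best = None  # (recall, threshold, delta, config)
    for delta in delta_grid:
        for thr in threshold_grid:
            cfg = PhraseConfig(threshold=thr, delta=delta, iterations=iterations)
            retok, _ = extract_phrases(docs, cfg)
            vocab = build_vocabulary(retok, min_count=min_count)
            rec = phrase_recall(terms, vocab)
            key = (rec, thr)
            if best is None or key > (best[0], best[1]):
                best = (rec, thr, delta, cfg)
    if best[0] == 0.0:
        logger.warning("tune_extraction: no setting recovered any lexicon phrase")
    return best[3]
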