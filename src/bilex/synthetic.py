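"""Synthetic comparable corpora and gold lexicons with controllable signal.

The generator emulates the data regime of biomedical translation mining
from topic-aligned document pairs:

* a gold lexicon in which a controllable fraction of targets are
  *cognates* — produced from the source term by a deterministic ordered
  set of orthographic rewrite rules (suffix and substring substitutions
  emulating shared Greek/Latin roots, e.g. "-tion" -> "-tie") — while the
  remainder are orthographically unrelated random words; a controllable
  fraction of sources carries a second translation, and a configurable
  number of entries are two-word phrases on both sides;
* a comparable corpus of topic-aligned document pairs: each pair samples
  one topic, each topic owns a subset of lexicon entries, and the two
  sides draw the source resp. target terms of those entries under a
  Zipf-like frequency law mixed with per-language filler words, so that
  translation pairs co-occur across aligned documents (the distributional
  signal) without the texts being parallel.  Planted phrase pairs are
  always emitted as adjacent tokens, and phrase component words never
  occur outside their phrase.  Every lexicon term is topped up to at
  least ``min_count`` corpus occurrences, so corpus filtering retains the
  whole lexicon by construction.

Both languages draw from a shared Latin alphabet but disjoint word
inventories; the orthographic rules guarantee the non-cognate/cognate
contrast in edit distance that the character-level models should exploit.
All randomness flows from one integer seed; outputs are byte-identical
for equal seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import ComparableCorpus, Lexicon, SplitLexicon, split_lexicon

_CONSONANTS = "bcdfghklmnprstvz"
_VOWELS = "aeiou"
_SUFFIXES = ["tion", "ology", "osis", "itis", "ic", "al", "ine", "gram", "pathy", "ectomy"]


@dataclass
class RuleSet:
    """Ordered, deterministic orthographic rewrite rules.

    Each rule is ("suffix"|"sub", pattern, replacement): suffix rules fire
    once at the end of a word, substitution rules replace every occurrence.
    Rules apply in list order to each word of a term independently.
    """

    rules: list[tuple[str, str, str]]

    def apply(self, term: str) -> str:
        words = []
        for w in term.split(" "):
            for kind, pat, rep in self.rules:
                if kind == "suffix":
                    if w.endswith(pat):
                        w = w[: len(w) - len(pat)] + rep
                elif kind == "sub":
                    w = w.replace(pat, rep)
                else:
                    raise ValueError(f"unknown rule kind {kind!r}")
            words.append(w)
        return " ".join(words)


def default_rules() -> RuleSet:
    """Rewrite rules emulating shared-root EN->NL orthography shifts."""
    return RuleSet(
        [
            ("suffix", "tion", "tie"),
            ("suffix", "ology", "ologie"),
            ("suffix", "osis", "ose"),
            ("suffix", "itis", "itis"),
            ("suffix", "ic", "iek"),
            ("suffix", "al", "aal"),
            ("suffix", "ine", "ien"),
            ("suffix", "gram", "gram"),
            ("suffix", "pathy", "pathie"),
            ("suffix", "ectomy", "ektomie"),
            ("sub", "c", "k"),
            ("sub", "y", "ij"),
        ]
    )


@dataclass
class GenConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give ~5,000 gold pairs with the multi-translation share and
    phrase share in the ballpark of real seed lexicons, 80% cognates, and
    a corpus large enough that every lexicon term clears the min_count=5
    vocabulary filter.
    """

    n_pairs: int = 4200
    cognate_rate: float = 0.8
    polysemy_rate: float = 0.2
    n_docs: int = 240
    doc_length: int = 400
    n_topics: int = 24
    zipf_exponent: float = 1.05
    phrase_pair_count: int = 200
    n_filler: int = 300
    # biomedical-style terms are long; short words would create dense
    # edit-distance neighbourhoods full of false cognates (random pairs
    # indistinguishable from rule images), making the labels ill-defined
    word_min_syllables: int = 4
    word_max_syllables: int = 6
    lexical_fraction: float = 0.55
    min_count: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("cognate_rate", "polysemy_rate", "lexical_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_pairs", "n_docs", "doc_length", "n_topics"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.phrase_pair_count > self.n_pairs:
            raise ValueError("phrase_pair_count cannot exceed n_pairs")


def _random_word(rng: np.random.Generator, min_syll: int = 2, max_syll: int = 4,
                 suffix_prob: float = 0.0) -> str:
    n = int(rng.integers(min_syll, max_syll + 1))
    chars = []
    for _ in range(n):
        chars.append(_CONSONANTS[int(rng.integers(len(_CONSONANTS)))])
        chars.append(_VOWELS[int(rng.integers(len(_VOWELS)))])
    w = "".join(chars)
    if rng.random() < suffix_prob:
        w += _SUFFIXES[int(rng.integers(len(_SUFFIXES)))]
    return w


def _fresh_word(rng, taken: set[str], **kw) -> str:
    for _ in range(10_000):
        w = _random_word(rng, **kw)
        if w not in taken:
            taken.add(w)
            return w
    raise RuntimeError("word space exhausted; reduce n_pairs or lengthen words")


@dataclass
class SyntheticLexicon:
    lexicon: Lexicon
    cognate_sources: list[str]
    phrase_sources: list[str]


def generate_lexicon(config: GenConfig, rules: RuleSet | None = None) -> SyntheticLexicon:
    """Gold lexicon with rule-derived cognates and planted phrase pairs.

    Exactly ``round(cognate_rate * n_pairs)`` base targets are
    ``rules(source)``; ``round(polysemy_rate * n_pairs)`` sources get a
    second, orthographically unrelated translation; ``phrase_pair_count``
    base entries are two-word on both sides.
    """
    if rules is None:
        rules = default_rules()
    rng = np.random.default_rng(config.seed)
    taken_s: set[str] = set()
    taken_t: set[str] = set()
    entries: set[tuple[str, str]] = set()
    cognate_sources: list[str] = []
    phrase_sources: list[str] = []
    n_cognate = round(config.cognate_rate * config.n_pairs)
    sources: list[str] = []
    syll = dict(min_syll=config.word_min_syllables, max_syll=config.word_max_syllables)
    for i in range(config.n_pairs):
        is_phrase = i < config.phrase_pair_count
        cognate = len(cognate_sources) < n_cognate

        def make_source() -> str:
            if is_phrase:
                return (_fresh_word(rng, taken_s, suffix_prob=0.5, **syll) + " "
                        + _fresh_word(rng, taken_s, suffix_prob=0.5, **syll))
            return _fresh_word(rng, taken_s, suffix_prob=0.6, **syll)

        s = make_source()
        if cognate:
            # regenerate the source on the (rare) rule-image collision so
            # that target == rules(source) holds exactly for every cognate
            for _ in range(1000):
                t = rules.apply(s)
                if t not in taken_t:
                    break
                s = make_source()
            else:
                raise RuntimeError("could not realise a collision-free cognate target")
            taken_t.add(t)
            cognate_sources.append(s)
        else:
            if is_phrase:
                t = (_fresh_word(rng, taken_t, **syll) + " "
                     + _fresh_word(rng, taken_t, **syll))
            else:
                t = _fresh_word(rng, taken_t, suffix_prob=0.3, **syll)
        entries.add((s, t))
        sources.append(s)
        if is_phrase:
            phrase_sources.append(s)
    n_poly = round(config.polysemy_rate * config.n_pairs)
    poly_idx = rng.choice(len(sources), size=n_poly, replace=False) if n_poly else []
    cognate_set = set(cognate_sources)
    for i in poly_idx:
        s = sources[int(i)]
        if s in cognate_set:
            # second translation of a shared-root source is a rule-image
            # variant (same stem, different inflection), keeping the
            # cognate share of all pairs at cognate_rate
            base = rules.apply(s)
            for var in ("en", "es", "er", "eren"):
                t2 = base + var
                if t2 not in taken_t:
                    break
            taken_t.add(t2)
        elif " " in s:
            t2 = (_fresh_word(rng, taken_t, **syll) + " "
                  + _fresh_word(rng, taken_t, **syll))
        else:
            t2 = _fresh_word(rng, taken_t, suffix_prob=0.3, **syll)
        entries.add((s, t2))
    if cognate_sources and not any(rules.apply(s) != s for s in cognate_sources):
        raise ValueError("degenerate rule set: no generated form is changed by any rule")
    return SyntheticLexicon(Lexicon(entries), cognate_sources, phrase_sources)


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def generate_corpus(
    synth: SyntheticLexicon, config: GenConfig
) -> ComparableCorpus:
    """Topic-structured comparable corpus realising the lexicon.

    Aligned sides draw the source resp. target terms of the same topic
    under a shared Zipf law, so translation pairs co-occur in merged
    pseudo-documents; the remaining token budget is per-language filler.
    """
    rng = np.random.default_rng(config.seed + 1)
    entries = sorted(synth.lexicon.entries)
    # group entries by source so a polysemous source stays in one topic
    by_source: dict[str, list[str]] = {}
    for s, t in entries:
        by_source.setdefault(s, []).append(t)
    source_list = sorted(by_source)
    source_list = [source_list[int(i)] for i in rng.permutation(len(source_list))]
    topics: list[list[tuple[str, str]]] = [[] for _ in range(config.n_topics)]
    for i, s in enumerate(source_list):
        for t in by_source[s]:
            topics[i % config.n_topics].append((s, t))
    taken = {w for s, t in entries for w in s.split() + t.split()}
    fillers_s = [_fresh_word(rng, taken) for _ in range(config.n_filler)]
    fillers_t = [_fresh_word(rng, taken) for _ in range(config.n_filler)]
    filler_w = _zipf_weights(config.n_filler, config.zipf_exponent)

    emit_counts: dict[tuple[str, int], int] = {}

    # Documents are built as lists of emission *units* (one term each, so a
    # phrase's words stay adjacent inside its unit) and unit order is
    # shuffled before flattening: repeated emissions can then not create
    # systematic spurious adjacencies that the phrase extractor would merge.
    def emit(units: list[tuple[str, ...]], n_tokens: list[int], term: str, side: int) -> None:
        toks = tuple(term.split(" "))
        units.append(toks)
        n_tokens[0] += len(toks)
        emit_counts[(term, side)] = emit_counts.get((term, side), 0) + 1

    unit_docs: list[tuple[list[tuple[str, ...]], list[tuple[str, ...]]]] = []
    topic_of_doc: list[int] = []
    for di in range(config.n_docs):
        topic = di % config.n_topics
        topic_of_doc.append(topic)
        t_entries = topics[topic]
        n_t = len(t_entries)
        zw = _zipf_weights(n_t, config.zipf_exponent) if n_t else None
        units_s: list[tuple[str, ...]] = []
        units_t: list[tuple[str, ...]] = []
        len_s, len_t = [0], [0]
        budget = config.doc_length
        while len_s[0] < budget or len_t[0] < budget:
            if n_t and rng.random() < config.lexical_fraction:
                k = int(rng.choice(n_t, p=zw))
                s, t = t_entries[k]
                if len_s[0] < budget:
                    emit(units_s, len_s, s, 0)
                if len_t[0] < budget:
                    emit(units_t, len_t, t, 1)
            else:
                if len_s[0] < budget:
                    emit(units_s, len_s,
                         fillers_s[int(rng.choice(config.n_filler, p=filler_w))], 0)
                if len_t[0] < budget:
                    emit(units_t, len_t,
                         fillers_t[int(rng.choice(config.n_filler, p=filler_w))], 1)
        unit_docs.append((units_s, units_t))

    # top-up so every lexicon term reaches min_count corpus occurrences
    docs_of_topic: dict[int, list[int]] = {}
    for di, tp in enumerate(topic_of_doc):
        docs_of_topic.setdefault(tp, []).append(di)
    for tp, t_entries in enumerate(topics):
        home_docs = docs_of_topic.get(tp)
        if not home_docs:
            raise ValueError("document budget too small: topic without documents")
        for s, t in t_entries:
            for term, side in ((s, 0), (t, 1)):
                need = config.min_count - emit_counts.get((term, side), 0)
                for j in range(max(0, need)):
                    units = unit_docs[home_docs[j % len(home_docs)]][side]
                    emit(units, [0], term, side)

    pairs: list[tuple[list[str], list[str]]] = []
    for units_s, units_t in unit_docs:
        ps = rng.permutation(len(units_s))
        pt = rng.permutation(len(units_t))
        pairs.append(
            ([w for i in ps for w in units_s[int(i)]],
             [w for i in pt for w in units_t[int(i)]])
        )
    return ComparableCorpus(pairs, ("src", "tgt"))


@dataclass
class Benchmark:
    corpus: ComparableCorpus
    split: SplitLexicon
    lexicon: Lexicon
    cognate_sources: list[str]
    phrase_sources: list[str]
    config: GenConfig


def generate_benchmark(config: GenConfig, rules: RuleSet | None = None) -> Benchmark:
    """Corpus + 80/20/20 splits + cognate subset, fully seeded."""
    synth = generate_lexicon(config, rules)
    corpus = generate_corpus(synth, config)
    split = split_lexicon(synth.lexicon, config.seed)
    return Benchmark(corpus, split, synth.lexicon, synth.cognate_sources,
                     synth.phrase_sources, config)


def write_benchmark(bench: Benchmark, outdir) -> None:
    """Emit the directory layout and TSVs that corpus_io consumes."""
    from pathlib import Path

    out = Path(outdir)
    (out / "source").mkdir(parents=True, exist_ok=True)
    (out / "target").mkdir(parents=True, exist_ok=True)
    width = len(str(len(bench.corpus.pairs)))
    for i, (s, t) in enumerate(bench.corpus.pairs):
        (out / "source" / f"doc{i:0{width}d}.txt").write_text(" ".join(s) + "\n", encoding="utf-8")
        (out / "target" / f"doc{i:0{width}d}.txt").write_text(" ".join(t) + "\n", encoding="utf-8")
    from .corpus import write_lexicon

    write_lexicon(bench.lexicon, out / "lexicon.tsv")
    for name, lex in (("train", bench.split.train), ("validation", bench.split.validation),
                      ("test", bench.split.test)):
        write_lexicon(lex, out / f"lexicon.{name}.tsv")
    (out / "cognate_sources.txt").write_text(
        "\n".join(bench.cognate_sources) + "\n", encoding="utf-8"
    )
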