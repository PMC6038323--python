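"""Comparable-corpus and seed-lexicon I/O, preprocessing, and splitting.

A *comparable corpus* is an ordered collection of document pairs whose two
sides discuss the same topic in two languages without being sentence-level
translations of each other.  The *seed lexicon* is a set of known
(source term, target term) translation pairs used as supervision; terms may
be multi-word phrases with single internal spaces.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

TokenDoc = list[str]


@dataclass
class ComparableCorpus:
    """Index-aligned (source document, target document) token-sequence pairs."""

    pairs: list[tuple[TokenDoc, TokenDoc]]
    language_tags: tuple[str, str] = ("src", "tgt")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def source_docs(self) -> list[TokenDoc]:
        return [s for s, _ in self.pairs]

    @property
    def target_docs(self) -> list[TokenDoc]:
        return [t for _, t in self.pairs]


@dataclass
class Lexicon:
    """A set of (source term, target term) translation pairs.

    A source term may appear in several entries (multiple translations);
    exact duplicate entries are collapsed by set semantics.
    """

    entries: set[tuple[str, str]] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(sorted(self.entries))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.entries

    def sources(self) -> set[str]:
        return {s for s, _ in self.entries}

    def targets(self) -> set[str]:
        return {t for _, t in self.entries}

    def translations_of(self, source: str) -> set[str]:
        return {t for s, t in self.entries if s == source}


@dataclass
class SplitLexicon:
    """Disjoint train/validation/test partition of a lexicon (80/20 of 80/20)."""

    train: Lexicon
    validation: Lexicon
    test: Lexicon
    seed: int

    def union(self) -> Lexicon:
        return Lexicon(self.train.entries | self.validation.entries | self.test.entries)


class AlignmentError(ValueError):
    """Raised when source and target document collections cannot be aligned."""


def _list_documents(path: Path) -> list[Path]:
    if path.is_dir():
        return sorted(p for p in path.iterdir() if p.is_file())
    # Manifest: one document path per line, relative paths resolved
    # against the manifest's directory.
    out = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line:
            out.append((path.parent / line) if not Path(line).is_absolute() else Path(line))
    return out


def read_corpus(
    source: str | Path,
    target: str | Path,
    language_tags: tuple[str, str] = ("src", "tgt"),
) -> ComparableCorpus:
    """Read an aligned corpus from two directories or two manifest files.

    Directories are paired by sorted file name; manifests by line order.
    Raises :class:`AlignmentError` when the two sides have unequal counts.
    """
    src_files = _list_documents(Path(source))
    tgt_files = _list_documents(Path(target))
    if len(src_files) != len(tgt_files):
        raise AlignmentError(
            f"{len(src_files)} source documents vs {len(tgt_files)} target documents"
        )
    if not src_files:
        logger.warning("read_corpus: no documents found (%s, %s)", source, target)
    pairs = []
    for sf, tf in zip(src_files, tgt_files):
        try:
            s_text = sf.read_text(encoding="utf-8")
            t_text = tf.read_text(encoding="utf-8")
        except OSError as exc:
            raise IOError(f"cannot read document {exc.filename}") from exc
        pairs.append((s_text.split("\n"), t_text.split("\n")))
    # Raw documents enter as line lists; preprocess() turns them into tokens.
    return ComparableCorpus(
        [([w for line in s for w in line.split()], [w for line in t for w in line.split()])
         for s, t in pairs],
        language_tags,
    )


def tokenize(text: str) -> TokenDoc:
    """Whitespace tokenization, lowercasing, edge punctuation stripping.

    Leading/trailing non-alphanumeric characters are removed from each
    token; internal hyphens and apostrophes are preserved.
    """
    out = []
    for raw in text.split():
        tok = _strip_token(raw.lower())
        if tok:
            out.append(tok)
    return out


def _strip_token(tok: str) -> str:
    start, end = 0, len(tok)
    while start < end and not tok[start].isalnum():
        start += 1
    while end > start and not tok[end - 1].isalnum():
        end -= 1
    return tok[start:end]


def preprocess(corpus: ComparableCorpus) -> ComparableCorpus:
    """Lowercase and re-tokenize every document; order is preserved.

    Idempotent: applying it twice equals applying it once.
    """
    pairs = []
    for i, (s, t) in enumerate(corpus.pairs):
        ps = tokenize(" ".join(s))
        pt = tokenize(" ".join(t))
        if not ps or not pt:
            logger.warning("preprocess: document pair %d has an empty side", i)
        pairs.append((ps, pt))
    return ComparableCorpus(pairs, corpus.language_tags)


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a two-column (source TAB target) UTF-8 TSV seed lexicon.

    Entries are lowercased to match corpus preprocessing and whitespace
    inside terms is normalised to single spaces.  Duplicates collapse.
    """
    entries: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(cols)}")
            s = " ".join(cols[0].lower().split())
            t = " ".join(cols[1].lower().split())
            if not s or not t:
                raise ValueError(f"{path}:{lineno}: empty term")
            entries.add((s, t))
    return Lexicon(entries)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s, t in lexicon:
            fh.write(f"{s}\t{t}\n")


def filter_lexicon(lexicon: Lexicon, vocab_s, vocab_t) -> Lexicon:
    """Keep entries whose source is in ``vocab_s`` and target in ``vocab_t``.

    ``vocab_s``/``vocab_t`` may be :class:`~bilex.phrases.Vocabulary`
    instances or any container supporting ``in``.
    """
    return Lexicon({(s, t) for s, t in lexicon.entries if s in vocab_s and t in vocab_t})


def split_lexicon(lexicon: Lexicon, seed: int) -> SplitLexicon:
    """Random 80/20 test split, then 80/20 validation split of the training side.

    The split is over entries, so two translations of one source may land
    in different parts.  Deterministic for a fixed seed.
    """
    if len(lexicon) < 5:
        raise ValueError(f"lexicon too small to split ({len(lexicon)} entries, need >= 5)")
    entries = sorted(lexicon.entries)
    rng = random.Random(seed)
    rng.shuffle(entries)
    n = len(entries)
    n_test = math.floor(0.2 * n)
    n_trainval = n - n_test
    n_val = math.floor(0.2 * n_trainval)
    test = entries[:n_test]
    val = entries[n_test:n_test + n_val]
    train = entries[n_test + n_val:]
    return SplitLexicon(Lexicon(set(train)), Lexicon(set(val)), Lexicon(set(test)), seed)


@dataclass
class LexiconStats:
    n_entries: int
    n_retained: int
    retention_pct: float
    phrase_phrase_pct: float
    word_phrase_pct: float
    word_word_pct: float
    multi_translation_source_pct: float
    mean_source_frequency: float
    mean_target_frequency: float


def retention_pct(n_retained: int, n_total: int) -> float:
    """Percentage of lexicon entries retained after corpus filtering."""
    if n_total <= 0:
        return 0.0
    return 100.0 * n_retained / n_total


def lexicon_stats(lexicon: Lexicon, vocab_s, vocab_t) -> LexiconStats:
    """Descriptive statistics of a lexicon w.r.t. the corpus vocabularies.

    Shares of phrase/word pair classes, multi-translation sources and mean
    corpus frequencies are computed on the retained (in-vocabulary) subset.
    """
    retained = filter_lexicon(lexicon, vocab_s, vocab_t)
    n, r = len(lexicon), len(retained)
    pp = wp = ww = 0
    for s, t in retained.entries:
        s_phrase = " " in s
        t_phrase = " " in t
        if s_phrase and t_phrase:
            pp += 1
        elif s_phrase or t_phrase:
            wp += 1
        else:
            ww += 1
    srcs: dict[str, int] = {}
    for s, _ in retained.entries:
        srcs[s] = srcs.get(s, 0) + 1
    multi = sum(1 for c in srcs.values() if c > 1)

    def _freq(vocab, term):
        try:
            return vocab.count(term)
        except AttributeError:
            return 0

    s_freqs = [_freq(vocab_s, s) for s, _ in retained.entries]
    t_freqs = [_freq(vocab_t, t) for _, t in retained.entries]
    pct = lambda k: 100.0 * k / r if r else 0.0
    return LexiconStats(
        n_entries=n,
        n_retained=r,
        retention_pct=retention_pct(r, n),
        phrase_phrase_pct=pct(pp),
        word_phrase_pct=pct(wp),
        word_word_pct=pct(ww),
        multi_translation_source_pct=100.0 * multi / len(srcs) if srcs else 0.0,
        mean_source_frequency=float(sum(s_freqs) / len(s_freqs)) if s_freqs else 0.0,
        mean_target_frequency=float(sum(t_freqs) / len(t_freqs)) if t_freqs else 0.0,
    )
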