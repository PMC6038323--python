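"""End-to-end orchestration: corpus -> vocabularies -> embeddings ->
classifier -> candidate generation -> threshold tuning -> evaluation.

These helpers compose the module-level operations into the standard
experiment flow; the CLI is a thin wrapper around them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import classifier as clf
from .candidates import CandidateSet, candidate_recall, generate_candidates
from .corpus import ComparableCorpus, Lexicon, SplitLexicon, filter_lexicon, preprocess, split_lexicon
from .embeddings import BilingualEmbedding, EmbeddingTable, train_bwesg, train_monolingual
from .evaluation import EvalReport, evaluate
from .phrases import PhraseConfig, Vocabulary, build_vocabulary, extract_phrases, tune_extraction

logger = logging.getLogger(__name__)

DEFAULT_DELTA_GRID = (3.0, 5.0, 10.0)
DEFAULT_THRESHOLD_GRID = (2.0, 6.0, 10.0, 50.0)


@dataclass
class Prepared:
    """Corpus-side artifacts shared by every model family."""

    corpus: ComparableCorpus  # retokenized: phrase tokens contain spaces
    vocab_s: Vocabulary
    vocab_t: Vocabulary
    phrase_config_s: PhraseConfig
    phrase_config_t: PhraseConfig
    lexicon: Lexicon  # filtered to in-vocabulary entries
    split: SplitLexicon
    retention_pct: float


def prepare(
    corpus: ComparableCorpus,
    lexicon: Lexicon,
    seed: int,
    min_count: int = 5,
    phrase_iterations: int = 4,
    delta_grid: Sequence[float] = DEFAULT_DELTA_GRID,
    threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> Prepared:
    """Preprocess, extract phrases (tuned per language), build vocabularies,
    filter the lexicon to in-vocabulary pairs and split it 80/20/20."""
    corpus = preprocess(corpus)
    src_terms = [s for s, _ in lexicon.entries]
    tgt_terms = [t for _, t in lexicon.entries]
    cfg_s = tune_extraction(corpus.source_docs, src_terms, delta_grid, threshold_grid,
                            iterations=phrase_iterations, min_count=min_count)
    cfg_t = tune_extraction(corpus.target_docs, tgt_terms, delta_grid, threshold_grid,
                            iterations=phrase_iterations, min_count=min_count)
    retok_s, _ = extract_phrases(corpus.source_docs, cfg_s)
    retok_t, _ = extract_phrases(corpus.target_docs, cfg_t)
    vocab_s = build_vocabulary(retok_s, min_count, corpus.language_tags[0])
    vocab_t = build_vocabulary(retok_t, min_count, corpus.language_tags[1])
    filtered = filter_lexicon(lexicon, vocab_s, vocab_t)
    retention = 100.0 * len(filtered) / len(lexicon) if len(lexicon) else 0.0
    logger.info("lexicon retention after filtering: %.2f%% (%d of %d)",
                retention, len(filtered), len(lexicon))
    split = split_lexicon(filtered, seed)
    retok = ComparableCorpus(list(zip(retok_s, retok_t)), corpus.language_tags)
    return Prepared(retok, vocab_s, vocab_t, cfg_s, cfg_t, filtered, split, retention)


def build_embeddings(
    prepared: Prepared,
    d: int = 50,
    mono_window: int = 5,
    bwesg_window: int = 100,
    epochs: int = 5,
    seed: int = 0,
    subsample: float = 1e-4,
) -> tuple[EmbeddingTable, EmbeddingTable, BilingualEmbedding]:
    """Monolingual SGNS tables for both sides plus the merged-document
    bilingual space used for cosine candidate generation."""
    mono_s = train_monolingual(prepared.corpus.source_docs, d, mono_window, subsample,
                               seed, epochs, tag=prepared.corpus.language_tags[0])
    mono_t = train_monolingual(prepared.corpus.target_docs, d, mono_window, subsample,
                               seed + 1, epochs, tag=prepared.corpus.language_tags[1])
    bilingual = train_bwesg(prepared.corpus, d, bwesg_window, subsample, seed + 2, epochs)
    return mono_s, mono_t, bilingual


def candidate_sets_for(
    sources: Iterable[str],
    prepared: Prepared,
    n_c: int = 5,
    bilingual: BilingualEmbedding | None = None,
) -> dict[str, CandidateSet]:
    targets = sorted(prepared.vocab_t.terms)
    return {s: generate_candidates(s, n_c, targets, bilingual) for s in sorted(set(sources))}


def train_and_tune(
    prepared: Prepared,
    config: clf.ModelConfig,
    table_s: EmbeddingTable | None = None,
    table_t: EmbeddingTable | None = None,
    bilingual: BilingualEmbedding | None = None,
    n_c: int = 5,
    tune_mode: str = "all",
    validation_candidates: Mapping[str, CandidateSet] | None = None,
) -> tuple[clf.TrainedModel, dict[str, CandidateSet]]:
    """Train the classifier on the training split and tune its threshold
    on validation-split candidates."""
    char_vocab = None
    if config.uses_char:
        char_vocab = clf.build_char_vocabs(prepared.vocab_s.terms, prepared.vocab_t.terms)
    model = clf.train(
        prepared.split,
        config,
        char_vocab=char_vocab,
        table_s=table_s,
        table_t=table_t,
        vocab_s_terms=sorted(prepared.vocab_s.terms),
        vocab_t_terms=sorted(prepared.vocab_t.terms),
    )
    if validation_candidates is None:
        validation_candidates = candidate_sets_for(
            prepared.split.validation.sources(), prepared, n_c, bilingual
        )
    clf.tune_threshold(model, prepared.split.validation,
                       {s: cs.candidates for s, cs in validation_candidates.items()},
                       mode=tune_mode, known=prepared.split.train)
    return model, dict(validation_candidates)


@dataclass
class TestEvaluation:
    reports: dict[str, EvalReport]
    candidate_sets: dict[str, CandidateSet]
    candidate_recall: float
    predictions: dict[str, list[tuple[str, str, float]]]


def evaluate_on_test(
    model: clf.TrainedModel,
    prepared: Prepared,
    n_c: int = 5,
    bilingual: BilingualEmbedding | None = None,
    modes: Sequence[str] = ("top", "all"),
    test_candidates: Mapping[str, CandidateSet] | None = None,
    exclude_known: bool = True,
) -> TestEvaluation:
    """Generate candidates for the test split, classify, and report
    precision/recall/F1 in the requested modes.

    With ``exclude_known`` (default) predicted pairs that already belong
    to the training or validation seed lexicon are dropped before
    scoring: the task is mining *new* translation pairs, and an
    entry-level split can place one translation of a source in train and
    another in test, so re-proposing a pair the system was trained on is
    prior knowledge, not a discovery (nor an error).
    """
    gold = prepared.split.test
    if test_candidates is None:
        test_candidates = candidate_sets_for(gold.sources(), prepared, n_c, bilingual)
    known = (
        prepared.split.train.entries | prepared.split.validation.entries
        if exclude_known
        else set()
    )
    # known pairs leave the candidate pool before selection, so top mode
    # picks the best *novel* candidate rather than abstaining
    cand_lists = {
        s: [t for t in cs.candidates if (s, t) not in known]
        for s, cs in test_candidates.items()
    }
    scored = clf.score_candidates(model, cand_lists)
    reports: dict[str, EvalReport] = {}
    predictions: dict[str, list[tuple[str, str, float]]] = {}
    for mode in modes:
        preds = clf.predictions_from_scores(scored, model.threshold, mode)
        predictions[mode] = preds
        reports[mode] = evaluate(preds, gold, mode)
    return TestEvaluation(
        reports=reports,
        candidate_sets=dict(test_candidates),
        candidate_recall=candidate_recall(dict(test_candidates), gold),
        predictions=predictions,
    )
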