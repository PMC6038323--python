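# Methods

`bilex` mines term translations from a *comparable* bilingual corpus —
document pairs that share topic without being mutual translations — plus a
seed lexicon of known translation pairs. This note records the model, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Task formulation

Translation mining is framed as binary classification over term pairs.
With source and target vocabularies V^S and V^T (single words and
extracted phrases), a scoring network f(p^S, p^T) ∈ (0, 1) is trained on
seed-lexicon positives, and a pair is accepted when f exceeds a threshold
t tuned on validation F1. The threshold both trades precision against
recall and lets one source keep several translations (*all* mode); *top*
mode instead proposes only the argmax-scoring candidate, matching the
Accuracy@1 convention of similarity-based BLI.

Training minimises the summed cross-entropy over the positive pairs and,
for each positive, 2·N_s noise pairs: N_s uniformly sampled target terms
paired with the positive's source and N_s sampled sources paired with its
target (resampled when a draw happens to be a known translation). The
optimizer is Adam at its standard defaults with mini-batches of 10
examples. Scores are clamped to [1e-7, 1 − 1e-7] inside the loss.

## Representations

**Word level.** A pair's word representation is the concatenation of the
two terms' d-dimensional embeddings (d = 50 by default). Embeddings are
trained in advance and *frozen*; the classifier never updates them. Two
regimes are provided: per-language skip-gram with negative sampling
(window 5), optionally bridged by a least-squares linear map fitted on the
training pairs; and a pseudo-bilingual space obtained by merging each
aligned document pair into one mixed-language pseudo-document (length-ratio
interleaving by default; a seeded shuffle is available) and training one
skip-gram model with window 100 over the result.

**Character level.** The two character sequences are aligned position by
position — the shorter term is padded at its end, the space inside phrases
is an ordinary character — and the concatenated one-hot pair at each
position feeds a two-layer LSTM. The second layer's hidden output at the
final position is the pair representation. Dropout (keep probability 0.5)
is applied to the encoder's output connections during training only:
between layer 1 and layer 2, and on the final representation. "Output at
the final state" is the hidden output, not the cell state. One shared
PAD/UNK index pair serves both languages' inventories; characters unseen
at training time map to UNK.

**Head.** The chosen representation(s), concatenated, pass through H
sigmoid hidden layers (H = 2 by default) and a sigmoid output unit. The
hidden width defaults to the input width — it preserves capacity without
introducing a new hyper-parameter and is configurable. The handcrafted
baselines (length-normalised edit distance; the log of the target's rank
in the edit-distance-sorted target vocabulary; their concatenation) use
H = 0, a logistic model, because the features are 1–2 dimensional.
Parameters are initialised uniformly in ±0.08 with the forget-gate bias at
1; all randomness flows from one integer seed.

## Vocabularies and phrases

Vocabularies hold every word occurring at least five times plus phrases
found by iterative collocation merging: adjacent bigrams scoring

    score(w_i, w_j) = (Count(w_i, w_j) − δ) / (Count(w_i) · Count(w_j)) · |V|

above a per-language threshold are merged greedily left-to-right
(leftmost-first on ties, non-overlapping within an iteration), merged
tokens are treated as single tokens afterwards, and four iterations allow
phrases of up to five words (a merge at iteration k may span at most k+1
words). |V| is the current iteration's type count — merged tokens are
re-treated as ordinary tokens, so the vocabulary size they see is the
retokenized one. (δ, threshold) are grid-searched per language to maximise
recall of the training lexicon's multi-word terms; ties prefer the higher
threshold (fewer, cleaner phrases). A word that survives only inside
phrases is dropped from the vocabulary, since no standalone vector could
be trained for it. Counting for min_count happens after retokenization.
Phrases are stored with single internal spaces; serialisation to
word2vec text format uses underscore aliases with a bijection check.

## Candidate generation and evaluation protocol

Scoring all of V^S × V^T is quadratic, so each source term receives at
most 2·N_c candidates: the N_c edit-distance-nearest target terms plus
the N_c cosine-nearest in the merged bilingual space, deduplicated (the
union is not topped up, keeping provenance clean; N_c = 5 by default).
Edit-distance ties and rank ties break lexicographically, making ranks
deterministic. Precision counts predicted pairs that are gold; recall
counts gold pairs found, one per gold entry; gold pairs whose source never
received useful candidates are recall failures — candidate generation is
part of the system. Pairs already present in the training or validation
lexicon are removed from the candidate pool before prediction: with an
entry-level split, one translation of a source can sit in train while
another sits in test, and re-proposing a pair the system was supervised
on is prior knowledge rather than a mined discovery (or an error). The
same exclusion applies during threshold tuning.

Top-mode prediction applies the threshold as well as the argmax; a
no-threshold top mode is available for Accuracy@1-style comparisons.
Threshold tuning optimises all-mode F1 by default, the mode that rewards
finding multiple translations; the grid is 0.1 to 1.0 in steps of 0.1
with ties to the smallest t.

## The numpy implementation

No tensor-autodiff framework is used: the two-layer LSTM (exact
backpropagation through time over masked, batch-padded sequences), the
feed-forward head, inverted dropout and Adam are implemented directly in
numpy and verified against central finite differences in the test suite.
Batches pad to the longest pair in the batch; positions past a pair's own
padded length are masked so the state freezes there, which makes the
hidden state at the batch's final timestep equal to each pair's own final
state.

The skip-gram trainer is likewise a compact vectorised numpy
implementation of SGNS: per-position reduced windows (b ~ U{1..window}),
word2vec-style frequency subsampling (threshold 1e-4), unigram^0.75 noise
distribution, linearly decaying learning rate from 0.025. One deliberate
deviation from the reference algorithm: noise words are shared across a
mini-batch (a pool of max(4·k, 64) draws for k nominal negatives, with
the per-pair negative gradient rescaled to k), which turns the negative
term into two dense matrix products instead of a scatter per pair. Shared
noise is a standard variance-for-speed trade; all downstream checks are
rank- or tolerance-based, never bit-exact vector comparisons. Embedding
epochs default to 5; neither epochs nor negative count is prescribed by
the model definition, both are configurable and recorded in run metadata.

Unit-cost Levenshtein distance is computed by the `edlib` library; the
test suite checks it against an independent quadratic dynamic-programming
oracle and the metric axioms.

## Synthetic benchmarks

The real corpora this method targets are not redistributable, so the
package ships a generator that emulates their structure:

* **Lexicon.** Source terms are pronounceable random words of 3–5
  syllables (biomedical terms are long; short words would create dense
  edit-distance neighbourhoods that no real lexicon has), 60% carrying a
  Greek/Latin-style suffix from a small pool. A configurable fraction of
  targets are *cognates*: deterministic images of the source under an
  ordered rule set (suffix rewrites such as "-tion" → "-tie", substring
  substitutions such as "c" → "k"), mimicking shared-root orthography.
  The rest are unrelated random words. A configurable fraction of sources
  receives a second translation — a rule-image variant (same stem,
  different inflection) for cognate sources, an unrelated word otherwise —
  and a configurable number of entries are two-word phrases on both
  sides.
* **Corpus.** Documents are built per topic; each topic owns a slice of
  the lexicon, and aligned sides draw the source resp. target terms of
  the same topic under a shared Zipf law mixed with per-language filler
  words. This gives translation pairs strongly correlated corpus
  statistics and merged-document co-occurrence (the distributional
  signal) without parallel text. Documents are assembled from shuffled
  emission units so phrase words stay adjacent while repeated emissions
  cannot create spurious collocations; every lexicon term is topped up to
  min_count occurrences, so corpus filtering retains the full lexicon by
  construction.

Two frozen study conditions (in `bilex.benchmarks`) drive the evaluation:
a *cognate benchmark* (~5,040 pairs, cognate rate 0.8, polysemy 0.2,
phrase share ~5%) where the character encoder must carry the task, and a
*mixed benchmark* (~440 pairs, cognate rate 0.5, fine-grained topics of
~10 entries) where neither signal suffices alone. Model sizes are scaled
to one-CPU minutes: 64 LSTM cells (48 for the combined model) instead of
512/256, and per-family epoch budgets of 12 (charpairs, cognate
benchmark), 35/45/25 (charpairs/combined/word, mixed benchmark) instead
of 150–250 — the combined model converges slowest, as with the full-size
schedule, and receives the most passes. These sizes were fixed while
designing the benchmarks and are not tuned per run.

**What passing shows — and does not.** The synthetic data has noiseless
labels, a closed vocabulary, rule-perfect cognates and topic structure
far cleaner than real comparable corpora; absolute F1 here is therefore
much higher than on real biomedical text and not comparable to it. What
the benchmarks do establish: the encoder can learn an orthographic
correspondence from pairs alone, the combined model does not lose to its
best single component when both signals are present, candidate recall is
monotone in N_c, and every pipeline stage composes end to end
deterministically under a fixed seed.

## Known limitations

* Uniform negative sampling never shows the classifier hard negatives,
  so scores saturate near 1 for edit-close non-translations; the tuned
  threshold compensates only coarsely (grid step 0.1).
* The similarity-based baselines and candidate cosine recall depend on
  embedding quality, which at synthetic-corpus scale (tens of thousands
  of tokens) is far below what the full-size corpora would give.
* The LSTM processes position-aligned character pairs; insertions early
  in a word shift the alignment for the whole suffix, which makes
  length-changing rewrites and long phrase pairs the hardest inputs,
  especially at small cell counts.
* Transliteration (non-Latin scripts) and word-level auxiliary signals
  (burstiness, temporal variation) are out of scope.
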