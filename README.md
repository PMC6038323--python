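# bilex

Bilingual lexicon induction (BLI) from comparable corpora, for the setting
where general-purpose dictionaries exist but domain terminology — think
biomedical English↔Dutch — is missing. Given document-aligned comparable
text and a seed lexicon of known translation pairs, `bilex` mines new
single-word and multi-word translation pairs.

## The model

Translation mining is framed as binary classification over term pairs
(p^S, p^T) ∈ V^S × V^T. A neural scorer f produces a value in (0, 1) and
a pair is accepted when f(p^S, p^T) > t, with t tuned on validation F1 —
which naturally supports sources with several translations. The scorer
combines two signals:

* **word level** — the concatenation W^S·x^S ‖ W^T·x^T of the terms'
  fixed, pre-trained embeddings (monolingual skip-gram or pseudo-bilingual
  merged-document embeddings);
* **character level** — the two character sequences, padded to equal
  length and concatenated position-wise as one-hot pairs, are encoded by a
  two-layer LSTM whose final hidden state is the pair representation.
  This learns orthographic correspondences (shared Greek/Latin roots,
  e.g. *angiography : angiografie*) instead of relying on handcrafted
  edit-distance features — which are also provided as baselines.

Both representations feed a feed-forward head r_h_i = σ(W_i·r_h_{i−1} +
b_i), score = σ(W_o·r_H + b_o). Training minimises cross-entropy over
seed positives plus 2·N_s uniformly sampled negatives per positive (Adam,
mini-batches of 10). Vocabularies include multi-word phrases extracted by
iterative collocation merging with score (Count(w_i,w_j) − δ) /
(Count(w_i)·Count(w_j)) · |V|. At prediction time each source receives
2·N_c candidates (edit-distance-nearest ∪ cosine-nearest) rather than the
full target vocabulary.

Everything numerical — the LSTM with exact backpropagation through time,
the feed-forward head, Adam, and the skip-gram embedding trainer — is
implemented in numpy and verified against finite differences and
independent oracles in the test suite. See `docs/methods.md` for the full
account, including the synthetic benchmark generator that stands in for
the non-redistributable corpora this method targets.

## Worked example

```python
from bilex import benchmarks

run = benchmarks.run_experiment(
    benchmarks.cognate_benchmark_config(seed=1), ("charpairs",), seed=1
)
ev = run.evaluations["charpairs"]
print(f"candidate recall  {ev.candidate_recall:.3f}")
print(f"tuned threshold   {run.models['charpairs'].threshold}")
print(ev.reports["top"])
print(ev.reports["all"])
```

prints (one CPU, a few minutes):

```
candidate recall  0.822
tuned threshold   0.9
[top] P=0.9910 R=0.7669 F1=0.8647 (pred=780, gold=1008)
[all] P=0.9581 R=0.7937 F1=0.8681 (pred=835, gold=1008)
```

Reading: on a synthetic benchmark of ~5,000 gold pairs, 80% of them
orthographic cognates, the character-pair encoder alone reaches F1 0.865
when proposing one candidate per test source (*top*) and 0.868 when
proposing every candidate above the tuned threshold (*all*, the mode that
credits multiple translations per source). Candidate recall 0.822 is the
recall ceiling imposed by the 2·N_c = 10-candidate shortlist — the
orthographically unrelated 20% of pairs are only reachable through the
embedding-based half of the shortlist.

The same pipeline is scriptable from the shell:

```bash
bilex simulate --out bench --seed 1 --n-pairs 400 --n-docs 120
bilex train --source bench/source --target bench/target \
      --lexicon bench/lexicon.tsv --feature-set charpairs \
      --epochs 8 --lstm-cells 48 --seed 1 --out model
bilex predict --model-dir model --source bench/source --target bench/target \
      --lexicon bench/lexicon.tsv --seed 1 --out preds.tsv
bilex evaluate --predictions preds.tsv --gold bench/lexicon.test.tsv --mode all
```

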