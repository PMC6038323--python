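"""Precision / recall / F1 evaluation in *top* and *all* modes.

*top* mode proposes at most one translation per source term (the practice
behind Accuracy@1 in earlier work); *all* mode accepts every pair whose
classifier score exceeds the tuned threshold, which credits systems for
finding multiple translations of the same source.  Each gold pair counts
once in the recall denominator; gold pairs whose source never received
candidates are recall failures, not exclusions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

from .corpus import Lexicon


@dataclass
class EvalReport:
    mode: str
    precision: float
    recall: float
    f1: float
    n_predicted: int
    n_gold: int
    n_correct: int

    def as_dict(self) -> dict:
        return asdict(self)

    def as_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def __str__(self) -> str:
        return (
            f"[{self.mode}] P={self.precision:.4f} R={self.recall:.4f} "
            f"F1={self.f1:.4f} (pred={self.n_predicted}, gold={self.n_gold})"
        )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _pairs(predictions: Iterable) -> set[tuple[str, str]]:
    out = set()
    for p in predictions:
        s, t = p[0], p[1]  # tolerate (s, t, score, ...) rows
        out.add((s, t))
    return out


def evaluate(predictions: Iterable, gold: Lexicon, mode: str = "all") -> EvalReport:
    """Score predicted (source, target) pairs against a gold lexicon.

    Every predicted source must belong to the gold split under evaluation;
    in top mode at most one prediction per source is allowed.
    """
    if mode not in ("top", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    pred = _pairs(predictions)
    gold_pairs = set(gold.entries)
    gold_sources = {s for s, _ in gold_pairs}
    pred_sources = [s for s, _ in pred]
    stray = set(pred_sources) - gold_sources
    if stray:
        raise ValueError(f"predictions for sources outside the evaluated split: {sorted(stray)[:5]}")
    if mode == "top":
        per_source: dict[str, int] = {}
        for s in pred_sources:
            per_source[s] = per_source.get(s, 0) + 1
        multi = [s for s, c in per_source.items() if c > 1]
        if multi:
            raise ValueError(f"top mode allows one prediction per source; violated for {multi[:5]}")
    correct = pred & gold_pairs
    precision = len(correct) / len(pred) if pred else 0.0
    recall = len(correct) / len(gold_pairs) if gold_pairs else 0.0
    return EvalReport(
        mode=mode,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        n_predicted=len(pred),
        n_gold=len(gold_pairs),
        n_correct=len(correct),
    )


def frequency_stratified(
    predictions: Iterable,
    gold: Lexicon,
    vocab_s,
    vocab_t,
    cutoffs: Sequence[int],
    mode: str = "all",
) -> dict[int, EvalReport | None]:
    """Evaluate restricted to pairs whose terms are at least ``c`` frequent.

    For each cutoff c only gold pairs (and predictions) whose source and
    target corpus frequencies are >= c are kept; an empty stratum yields
    ``None`` (undefined).
    """
    pred = _pairs(predictions)
    out: dict[int, EvalReport | None] = {}
    for c in cutoffs:
        keep = lambda s, t: vocab_s.count(s) >= c and vocab_t.count(t) >= c
        g = Lexicon({(s, t) for s, t in gold.entries if keep(s, t)})
        if not g.entries:
            out[c] = None
            continue
        sources = g.sources()
        p = {(s, t) for s, t in pred if s in sources and keep(s, t)}
        out[c] = evaluate(p, g, mode)
    return out


def subset_eval(predictions: Iterable, gold: Lexicon, subset: Iterable[str], mode: str = "all") -> EvalReport:
    """Evaluation restricted to gold pairs whose source is in ``subset``.

    Used e.g. for the shared-root (cognate) subset analysis.
    """
    subset = set(subset)
    if not subset:
        raise ValueError("empty subset")
    g = Lexicon({(s, t) for s, t in gold.entries if s in subset})
    pred = {(s, t) for s, t in _pairs(predictions) if s in subset}
    return evaluate(pred, g, mode)


def strata_tsv(reports: Mapping[int, EvalReport | None], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cutoff\tprecision\trecall\tf1\tn_gold\n")
        for c in sorted(reports):
            r = reports[c]
            if r is None:
                fh.write(f"{c}\tNA\tNA\tNA\t0\n")
            else:
                fh.write(f"{c}\t{r.precision:.4f}\t{r.recall:.4f}\t{r.f1:.4f}\t{r.n_gold}\n")
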