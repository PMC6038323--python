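"""Edit-distance features and candidate generation for translation mining.

Scoring every pair in V^S x V^T is quadratic in the vocabularies, so at
prediction time each source term gets a shortlist of at most 2*N_c target
candidates: the N_c targets nearest by unit-cost edit distance plus the
N_c nearest by cosine in a shared bilingual embedding space, deduplicated.

This module also provides the handcrafted character-level features used as
baselines: the length-normalised edit distance ED_norm and log(ED_rank),
the log of a target's 1-based rank in the edit-distance-sorted target
vocabulary (the nearest target has feature value log(1) = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np


def levenshtein(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance; spaces count as ordinary characters."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def ed_norm(a: str, b: str) -> float:
    """Edit distance divided by the average character length of the pair."""
    if not a or not b:
        raise ValueError("ed_norm requires non-empty strings")
    return levenshtein(a, b) / ((len(a) + len(b)) / 2)


def ed_ranks(source: str, target_vocab: Sequence[str]) -> dict[str, int]:
    """1-based rank of every target by edit distance to ``source``.

    Ties are broken lexicographically so ranks are deterministic and
    language-independent.
    """
    order = sorted(target_vocab, key=lambda t: (levenshtein(source, t), t))
    return {t: i + 1 for i, t in enumerate(order)}


def log_ed_rank(source: str, target: str, target_vocab: Sequence[str]) -> float:
    """log of the edit-distance rank of ``target`` among all targets."""
    ranks = ed_ranks(source, target_vocab)
    if target not in ranks:
        raise KeyError(f"target term {target!r} not in vocabulary")
    return math.log(ranks[target])


@dataclass
class CandidateSet:
    """Shortlisted target candidates for one source term."""

    source: str
    candidates: list[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)  # target -> {"edit-distance","cosine"}
    edit_distance: dict[str, int] = field(default_factory=dict)
    cosine: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


def generate_candidates(
    source: str,
    n_c: int,
    target_vocab: Sequence[str],
    bilingual=None,
) -> CandidateSet:
    """Union of the N_c edit-nearest and N_c cosine-nearest target terms.

    ``bilingual`` is a :class:`~bilex.embeddings.BilingualEmbedding` (or
    ``None``, in which case only edit-distance candidates are produced and
    the set size is at most N_c).  Duplicates collapse, so the result may
    hold fewer than 2*N_c targets.
    """
    targets = list(target_vocab)
    if n_c > len(targets):
        import logging

        logging.getLogger(__name__).warning(
            "N_c=%d exceeds target vocabulary size %d; capping", n_c, len(targets)
        )
        n_c = len(targets)
    dists = {t: levenshtein(source, t) for t in targets}
    by_ed = sorted(targets, key=lambda t: (dists[t], t))[:n_c]
    cand = CandidateSet(source, [], {}, {}, {})
    for t in by_ed:
        cand.candidates.append(t)
        cand.provenance.setdefault(t, set()).add("edit-distance")
        cand.edit_distance[t] = dists[t]
    if bilingual is not None:
        sims = bilingual.cross_similarities(source)
        if sims is not None:
            embedded = [t for t in targets if t in sims]
            by_cos = sorted(embedded, key=lambda t: (-sims[t], t))[:n_c]
            for t in by_cos:
                if t not in cand.provenance:
                    cand.candidates.append(t)
                cand.provenance.setdefault(t, set()).add("cosine")
                cand.cosine[t] = float(sims[t])
    for t in cand.candidates:
        cand.edit_distance.setdefault(t, dists[t])
    return cand


def candidate_recall(
    candidate_sets: dict[str, CandidateSet], gold
) -> float:
    """Fraction of gold pairs whose target appears in its source's shortlist.

    Gold sources with no candidate set count as misses: candidate
    generation is part of the system under evaluation.
    """
    entries = list(gold.entries) if hasattr(gold, "entries") else list(gold)
    if not entries:
        return 0.0
    hits = sum(
        1
        for s, t in entries
        if s in candidate_sets and t in set(candidate_sets[s].candidates)
    )
    return hits / len(entries)


def dump_candidates(candidate_sets: dict[str, CandidateSet], path) -> None:
    """TSV dump: source, candidate, provenance, edit distance, cosine."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sorted(candidate_sets):
            cs = candidate_sets[s]
            for t in cs.candidates:
                prov = "+".join(sorted(cs.provenance.get(t, set())))
                cos = cs.cosine.get(t, float("nan"))
                fh.write(f"{s}\t{t}\t{prov}\t{cs.edit_distance.get(t, '')}\t{cos:.4f}\n")
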