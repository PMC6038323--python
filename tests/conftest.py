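"""Shared fixtures: one tiny synthetic benchmark reused across modules."""

from __future__ import annotations

import pytest

from bilex import pipeline
from bilex.synthetic import GenConfig, generate_benchmark


@pytest.fixture(scope="session")
def tiny_config() -> GenConfig:
    return GenConfig(
        n_pairs=120,
        cognate_rate=0.8,
        polysemy_rate=0.2,
        phrase_pair_count=10,
        n_docs=32,
        doc_length=150,
        n_topics=8,
        n_filler=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_benchmark(tiny_config):
    return generate_benchmark(tiny_config)


@pytest.fixture(scope="session")
def tiny_prepared(tiny_benchmark):
    return pipeline.prepare(tiny_benchmark.corpus, tiny_benchmark.lexicon, seed=11)
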