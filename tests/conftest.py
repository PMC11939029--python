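import numpy as np
import pytest

from rhetsec import (CorpusSpec, EmbeddingMatrix, EmbeddingSimSpec,
                     generate_abstract_corpus, simulate_embeddings)

# Benchmark constants used across the suite (fixed from one-off pilot runs
# at the seeds stated in the tests, before the assertions were frozen).
HIGH_SEPARATION = 2.0     # near-orthogonal class means at spread 0.05
TIGHT_SPREAD = 0.05
COLLAPSE_SEPARATION = 1.0  # reduced separation used in the entropy experiments
COLLAPSE_SPREAD = 0.2
HEAD_LR = 1e-2            # step size for freshly initialised numpy heads


@pytest.fixture(scope="session")
def small_corpus():
    """120-sentence balanced zh corpus."""
    return generate_abstract_corpus(CorpusSpec(counts_per_class=(30,) * 4, seed=3))


@pytest.fixture(scope="session")
def small_corpus_en():
    return generate_abstract_corpus(
        CorpusSpec(counts_per_class=(25,) * 4, language="en", seed=4))


def sim_matrix(separation, spread, seed, n_per_class=500, dim=64):
    values, labels = simulate_embeddings(EmbeddingSimSpec(
        n_per_class=(n_per_class,) * 4, dim=dim,
        within_class_spread=spread, class_separation=separation, seed=seed))
    emb = EmbeddingMatrix(values=values,
                          ids=[f"s{i:06d}" for i in range(len(values))])
    return emb, labels


@pytest.fixture(scope="session")
def benchmark_embeddings():
    """The well-separated clustering benchmark (seed 1)."""
    return sim_matrix(HIGH_SEPARATION, TIGHT_SPREAD, seed=1)
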