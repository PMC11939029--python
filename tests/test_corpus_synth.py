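"""Synthetic corpus and embedding-simulator contracts."""

from collections import Counter

import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

from rhetsec import (CLASSES, CorpusSpec, EmbeddingSimSpec,
                     generate_abstract_corpus, generate_duplicate_pairs,
                     evaluate_clustering, simulate_embeddings, split_corpus)
from rhetsec.corpus_synth import PARAPHRASES, TEMPLATES

from conftest import HIGH_SEPARATION, TIGHT_SPREAD


@pytest.mark.parametrize("counts", [
    (3750, 3750, 3750, 3750),   # balanced 15,000-sentence corpus
    (3537, 4140, 3826, 3497),   # imbalanced 15,000-sentence corpus
])
def test_class_counts_exact(counts):
    records = generate_abstract_corpus(CorpusSpec(counts_per_class=counts, seed=7))
    assert len(records) == 15000
    tally = Counter(r.label for r in records)
    assert tuple(tally[c] for c in CLASSES) == counts


def test_single_class_degenerate():
    records = generate_abstract_corpus(CorpusSpec(counts_per_class=(0, 0, 0, 1), seed=0))
    assert len(records) == 1
    assert records[0].label == "conclusion"


def test_generation_deterministic():
    spec = CorpusSpec(counts_per_class=(40, 40, 40, 40), language="en", seed=9)
    a = generate_abstract_corpus(spec)
    b = generate_abstract_corpus(spec)
    assert a == b


def test_abstracts_are_section_ordered():
    records = generate_abstract_corpus(CorpusSpec(counts_per_class=(50,) * 4, seed=2))
    order = {c: i for i, c in enumerate(CLASSES)}
    by_abstract = {}
    for r in records:
        by_abstract.setdefault(r.abstract_id, []).append(r)
    for sents in by_abstract.values():
        sents.sort(key=lambda r: r.sentence_index)
        section_seq = [order[r.label] for r in sents]
        assert section_seq == sorted(section_seq)
    # (abstract_id, sentence_index) pairs unique
    keys = [(r.abstract_id, r.sentence_index) for r in records]
    assert len(set(keys)) == len(keys)


def test_label_noise_preserves_total_and_flips_floor():
    spec = CorpusSpec(counts_per_class=(100,) * 4, seed=5, label_noise_rate=0.13)
    clean = generate_abstract_corpus(CorpusSpec(counts_per_class=(100,) * 4, seed=5))
    noisy = generate_abstract_corpus(spec)
    assert len(noisy) == len(clean) == 400
    flipped = sum(a.label != b.label for a, b in zip(clean, noisy))
    assert flipped == int(0.13 * 400)  # floor
    for a, b in zip(clean, noisy):
        assert a.text == b.text


def test_template_banks_are_large_and_paired():
    for lang in ("zh", "en"):
        for cls in CLASSES:
            assert len(TEMPLATES[lang][cls]) >= 20
            assert len(PARAPHRASES[lang][cls]) == len(TEMPLATES[lang][cls])


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        CorpusSpec(counts_per_class=(1, 1, 1, 1), language="fr")
    with pytest.raises(ValueError):
        generate_abstract_corpus(CorpusSpec(counts_per_class=(0, 0, 0, 0)))


def test_duplicate_pairs_share_topic_but_differ():
    pairs = generate_duplicate_pairs(50, language="en", seed=1)
    assert len(pairs) == 50
    assert all(a != b for a, b in pairs)
    assert pairs == generate_duplicate_pairs(50, language="en", seed=1)


# ---------------------------------------------------------------------------
# Embedding simulator
# ---------------------------------------------------------------------------

def test_simulator_empty():
    values, labels = simulate_embeddings(EmbeddingSimSpec(n_per_class=(0, 0, 0, 0), dim=16))
    assert values.shape == (0, 16) and labels.shape == (0,)


def test_simulator_rows_unit_norm_and_seeded():
    spec = EmbeddingSimSpec(n_per_class=(50,) * 4, dim=32,
                            within_class_spread=0.2, class_separation=1.0, seed=8)
    v1, l1 = simulate_embeddings(spec)
    v2, _ = simulate_embeddings(spec)
    assert np.allclose(np.linalg.norm(v1, axis=1), 1.0)
    assert np.array_equal(v1, v2)
    assert np.bincount(l1).tolist() == [50] * 4


def _qda_holdout_accuracy(separation, spread=0.3, seed=2, n_per_class=2500):
    values, labels = simulate_embeddings(EmbeddingSimSpec(
        n_per_class=(n_per_class,) * 4, dim=64,
        within_class_spread=spread, class_separation=separation, seed=seed))
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(values))
    half = len(values) // 2
    clf = QuadraticDiscriminantAnalysis(reg_param=0.1)
    clf.fit(values[idx[:half]], labels[idx[:half]])
    return clf.score(values[idx[half:]], labels[idx[half:]])


def test_zero_separation_is_chance_level():
    # identical class means: a quadratic-discriminant oracle sits at 1/4
    acc = _qda_holdout_accuracy(0.0, spread=0.1)
    se3 = 3 * np.sqrt(0.25 * 0.75 / 5000)
    assert abs(acc - 0.25) < se3


def test_bayes_proxy_accuracy_monotone_in_separation():
    accs = [_qda_holdout_accuracy(s) for s in (0.0, 0.2, 1.0)]
    assert accs[0] <= accs[1] <= accs[2]


def test_high_separation_kmeans_recovers_classes():
    values, labels = simulate_embeddings(EmbeddingSimSpec(
        n_per_class=(500,) * 4, dim=64, within_class_spread=TIGHT_SPREAD,
        class_separation=HIGH_SEPARATION, seed=1))
    pred = KMeans(4, random_state=0, n_init=10).fit_predict(values)
    _, rep = evaluate_clustering(labels, pred)
    assert rep.accuracy >= 0.99


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def test_split_counts_and_atomicity(small_corpus):
    train, test = split_corpus(small_corpus, 0.8, 0.2, seed=3)
    assert len(train) + len(test) == len(small_corpus)
    assert not ({r.abstract_id for r in train} & {r.abstract_id for r in test})
    n_abs = len({r.abstract_id for r in small_corpus})
    n_train = len({r.abstract_id for r in train})
    assert n_train == round(0.8 * n_abs)


def test_split_rejects_degenerate_fractions(small_corpus):
    with pytest.raises(ValueError):
        split_corpus(small_corpus, 1.0, 0.0)
    with pytest.raises(ValueError):
        split_corpus(small_corpus, 0.6, 0.6)
    with pytest.raises(ValueError):
        split_corpus(small_corpus[:3], 0.5, 0.5)  # single abstract


def test_split_seed_changes_partition(small_corpus):
    t1, _ = split_corpus(small_corpus, 0.5, 0.5, seed=1)
    t2, _ = split_corpus(small_corpus, 0.5, 0.5, seed=2)
    ids1 = {r.abstract_id for r in t1}
    ids2 = {r.abstract_id for r in t2}
    assert ids1 != ids2
    # both valid halves
    n_abs = len({r.abstract_id for r in small_corpus})
    assert len(ids1) == len(ids2) == round(0.5 * n_abs)
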