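"""Neighbor mining, the clustering objective, and head training."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhetsec import (EmbeddingMatrix, NeighborTable, ScanConfig, assign,
                     kmeans_baseline, mine_neighbors, scan_loss, train_scan,
                     usage_entropy)
from rhetsec.docscan import ClusterHead

from conftest import HEAD_LR, sim_matrix


def _emb(values):
    values = np.asarray(values, dtype=float)
    return EmbeddingMatrix(values=values,
                           ids=[f"r{i}" for i in range(len(values))],
                           normalize=False)


# ---------------------------------------------------------------------------
# mine_neighbors
# ---------------------------------------------------------------------------

def test_identical_vectors_are_mutual_nearest():
    e = _emb([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    table = mine_neighbors(e, k=1)
    assert table.indices[0, 0] == 1
    assert table.indices[1, 0] == 0


def test_neighbors_match_exhaustive_cosine():
    angles = np.deg2rad([0, 10, 90, 180, 200])
    vecs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    table = mine_neighbors(_emb(vecs), k=2)
    # brute force over all 25 pairwise dot products
    sims = vecs @ vecs.T
    np.fill_diagonal(sims, -np.inf)
    for i in range(5):
        expected = sorted(range(5), key=lambda j: (-sims[i, j], j))[:2]
        assert table.indices[i].tolist() == expected


def test_neighbor_tie_breaks_to_lower_index():
    # duplicates at indices 2 and 7 tie as a neighbor of every other point
    angles = [0.2, 1.5, 0.3, 1.8, 2.1, 2.4, 2.7, 0.3]  # 2 and 7 duplicate
    vecs = np.stack([[np.cos(t), np.sin(t)] for t in angles])
    table = mine_neighbors(_emb(vecs), k=1)
    assert table.indices[0, 0] == 2  # tie between 2 and 7 goes to 2


def test_mine_neighbors_validation():
    e = _emb(np.eye(3))
    with pytest.raises(ValueError):
        mine_neighbors(e, k=3)
    with pytest.raises(ValueError):
        mine_neighbors(e, k=0)
    with pytest.raises(ValueError):
        NeighborTable(indices=np.array([[0], [0]]))  # self-neighbor


# ---------------------------------------------------------------------------
# scan_loss
# ---------------------------------------------------------------------------

def brute_force_scan_loss(anchors, neighbors, lam):
    """Independent scalar evaluation of the clustering objective."""
    B, k, C = neighbors.shape
    consistency = 0.0
    for b in range(B):
        for j in range(k):
            dot = sum(anchors[b][c] * neighbors[b][j][c] for c in range(C))
            consistency -= math.log(max(dot, 1e-12))
    consistency /= B
    entropy = 0.0
    for c in range(C):
        p = sum(anchors[b][c] for b in range(B)) / B
        if p > 0:
            entropy += p * math.log(max(p, 1e-12))
    return consistency + lam * entropy


def test_one_hot_consistent_batch_is_zero():
    a = np.array([[1.0, 0.0, 0.0, 0.0]])
    n = a[:, None, :]
    assert scan_loss(a, n, entropy_weight=2.0) == pytest.approx(0.0, abs=1e-12)


def test_uniform_usage_entropy_closed_form():
    # 4 anchors, each a different one-hot: consistency 0, usage uniform over C=4
    a = np.eye(4)
    n = a[:, None, :]
    val = scan_loss(a, n, entropy_weight=1.0)
    assert val == pytest.approx(-math.log(4), abs=1e-12)


def test_uniform_probability_batch_hand_value():
    # B=2, k=1, everything uniform over C=2, lambda=0.5:
    # consistency = -log(1/2); entropy term = 0.5 * (2 * 0.5 * log 0.5)
    a = np.full((2, 2), 0.5)
    n = np.full((2, 1, 2), 0.5)
    expected = -math.log(0.5) + 0.5 * math.log(0.5)
    assert scan_loss(a, n, 0.5) == pytest.approx(expected, abs=1e-12)
    assert scan_loss(a, n, 0.5) == pytest.approx(
        brute_force_scan_loss(a, n, 0.5), abs=1e-12)


@st.composite
def _prob_batches(draw):
    B = draw(st.integers(1, 5))
    k = draw(st.integers(1, 4))
    C = draw(st.integers(2, 6))
    raw_a = draw(st.lists(st.lists(st.floats(0.01, 10), min_size=C, max_size=C),
                          min_size=B, max_size=B))
    raw_n = draw(st.lists(
        st.lists(st.lists(st.floats(0.01, 10), min_size=C, max_size=C),
                 min_size=k, max_size=k), min_size=B, max_size=B))
    a = np.array(raw_a)
    a /= a.sum(axis=1, keepdims=True)
    n = np.array(raw_n)
    n /= n.sum(axis=2, keepdims=True)
    lam = draw(st.floats(0, 5))
    return a, n, lam


@settings(max_examples=100, deadline=None, derandomize=True)
@given(_prob_batches())
def test_scan_loss_matches_brute_force(batch):
    a, n, lam = batch
    assert scan_loss(a, n, lam) == pytest.approx(
        brute_force_scan_loss(a, n, lam), abs=1e-8)


def test_scan_loss_nonnegative_without_entropy():
    # dot of two distributions is <= 1, so -log dot >= 0
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = rng.dirichlet(np.ones(4), size=3)
        n = rng.dirichlet(np.ones(4), size=(3, 2))
        assert scan_loss(a, n, 0.0) >= 0.0


def test_scan_loss_shape_validation():
    a = np.full((2, 4), 0.25)
    n = np.full((3, 1, 4), 0.25)
    with pytest.raises(ValueError):
        scan_loss(a, n, 1.0)
    with pytest.raises(ValueError):
        scan_loss(a, np.full((2, 1, 4), 0.25), -1.0)


# ---------------------------------------------------------------------------
# train_scan / assign
# ---------------------------------------------------------------------------

def test_zero_epochs_returns_seeded_initialization(benchmark_embeddings):
    emb, _ = benchmark_embeddings
    table = mine_neighbors(emb, 5)
    cfg = ScanConfig(epochs=0, seed=42)
    head = train_scan(emb, table, cfg)
    ref = ClusterHead.initialize(emb.dim, cfg)
    assert np.array_equal(head.W1, ref.W1)
    assert np.array_equal(head.W2, ref.W2)
    assert head.loss_trajectory == []


def test_head_outputs_are_distributions(benchmark_embeddings):
    emb, _ = benchmark_embeddings
    head = ClusterHead.initialize(emb.dim, ScanConfig(seed=0))
    probs = head.probabilities(emb.values * 100)
    assert np.all(probs >= 0)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_assign_matches_scalar_forward_pass(benchmark_embeddings):
    emb, _ = benchmark_embeddings
    head = ClusterHead.initialize(emb.dim, ScanConfig(seed=3))
    labels = assign(head, emb)
    for i in [0, 17, 512, 1999]:
        x = emb.values[i]
        h = [max(0.0, float(x @ head.W1[j]) + head.b1[j]) for j in range(len(head.b1))]
        logits = [sum(h[j] * head.W2[c, j] for j in range(len(h))) + head.b2[c]
                  for c in range(4)]
        assert labels[i] == int(np.argmax(logits))


def test_assign_is_permutation_equivariant(benchmark_embeddings):
    emb, _ = benchmark_embeddings
    head = ClusterHead.initialize(emb.dim, ScanConfig(seed=3))
    labels = assign(head, emb)
    rng = np.random.default_rng(0)
    perm = rng.permutation(emb.n)
    permuted = EmbeddingMatrix(values=emb.values[perm],
                               ids=[emb.ids[i] for i in perm])
    assert np.array_equal(assign(head, permuted), labels[perm])


def test_train_scan_improves_over_initialization():
    emb, labels = sim_matrix(2.0, 0.05, seed=1, n_per_class=100)
    table = mine_neighbors(emb, 5)
    cfg = ScanConfig(epochs=10, learning_rate=HEAD_LR, seed=1)
    head = train_scan(emb, table, cfg)
    assert head.loss_trajectory[-1] < head.loss_trajectory[0]
    assert usage_entropy(assign(head, emb), 4) > 0.9 * math.log(4)


# ---------------------------------------------------------------------------
# k-means baseline
# ---------------------------------------------------------------------------

def test_kmeans_single_cluster(benchmark_embeddings):
    emb, _ = benchmark_embeddings
    assert np.all(kmeans_baseline(emb, 1) == 0)


def test_kmeans_two_separated_blobs():
    rng = np.random.default_rng(0)
    a = rng.normal([10, 0], 0.1, size=(50, 2))
    b = rng.normal([-10, 0], 0.1, size=(50, 2))
    emb = _emb(np.vstack([a, b]))
    labels = kmeans_baseline(emb, 2, seed=1)
    assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
    assert labels[0] != labels[50]


def test_kmeans_deterministic(benchmark_embeddings):
    emb, _ = benchmark_embeddings
    assert np.array_equal(kmeans_baseline(emb, 4, seed=7),
                          kmeans_baseline(emb, 4, seed=7))
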