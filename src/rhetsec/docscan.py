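"""SCAN-loss clustering of sentence embeddings.

The clustering stage rests on a simple inductive bias: a sentence and
its nearest neighbors in embedding space usually play the same
rhetorical role.  A softmax cluster head f(.) is trained to honour that
bias by minimising

    L = -(1/|D|) * sum_x sum_{k in N_x} log( f(x) . f(k) )
        + lambda * sum_i p_i log p_i

where N_x are the k mined nearest neighbors of x and p is the mean
assigned cluster distribution.  The first (consistency) term rewards
giving a point and its neighbors the same confident cluster
distribution; the second (entropy) term, scaled by lambda, penalises
concentrating probability mass on few clusters — without it the head
can collapse every point into a single cluster.  Natural logarithms are
used throughout and dot products are clipped below at 1e-12 before the
log.

The head is a small MLP trained over frozen embeddings; a k-means
baseline on the same embeddings is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._nn import Adam, glorot, he, relu, softmax
from .encoding import EmbeddingMatrix

__all__ = ["NeighborTable", "ScanConfig", "ClusterHead",
           "mine_neighbors", "scan_loss", "train_scan", "assign",
           "kmeans_baseline", "usage_entropy"]

_CLIP = 1e-12


@dataclass
class NeighborTable:
    """n x k indices of each row's nearest neighbors (cosine metric)."""

    indices: np.ndarray
    metric: str = "cosine"

    def __post_init__(self):
        n, k = self.indices.shape
        if np.any((self.indices < 0) | (self.indices >= n)):
            raise ValueError("neighbor indices out of range")
        if np.any(self.indices == np.arange(n)[:, None]):
            raise ValueError("a row may not be its own neighbor")

    @property
    def k(self) -> int:
        return self.indices.shape[1]


@dataclass(frozen=True)
class ScanConfig:
    num_clusters: int = 4
    entropy_weight: float = 2.0
    k: int = 5
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 5e-5
    dropout: float = 0.5
    hidden_width: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.num_clusters < 2:
            raise ValueError("num_clusters must be >= 2")
        if self.entropy_weight < 0:
            raise ValueError("entropy_weight must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class ClusterHead:
    """MLP dim -> hidden -> C ending in a softmax; outputs are valid
    probability distributions for any finite input."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    config: ScanConfig
    loss_trajectory: list[float] = field(default_factory=list)

    @classmethod
    def initialize(cls, dim: int, cfg: ScanConfig) -> "ClusterHead":
        rng = np.random.default_rng(cfg.seed)
        return cls(W1=he(rng, cfg.hidden_width, dim), b1=np.zeros(cfg.hidden_width),
                   W2=glorot(rng, cfg.num_clusters, cfg.hidden_width),
                   b2=np.zeros(cfg.num_clusters), config=cfg)

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.W1.shape[1]:
            raise ValueError(f"dimension mismatch: head expects {self.W1.shape[1]}, got {X.shape[1]}")
        h = relu(X @ self.W1.T + self.b1)
        return softmax(h @ self.W2.T + self.b2)


# ---------------------------------------------------------------------------
# Neighbor mining
# ---------------------------------------------------------------------------

def mine_neighbors(emb: EmbeddingMatrix, k: int) -> NeighborTable:
    """Exact k-nearest-neighbor table under cosine similarity.

    Rows must be unit-normalized (cosine = dot product).  Self is
    excluded; ties break toward the lower index.
    """
    X = emb.values
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} requires at least k+1={k + 1} points, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite embedding rows")
    sims = X @ X.T
    np.fill_diagonal(sims, -np.inf)
    # stable sort on -sim keeps lower indices first among ties
    order = np.argsort(-sims, axis=1, kind="stable")
    return NeighborTable(indices=order[:, :k])


# ---------------------------------------------------------------------------
# SCAN loss
# ---------------------------------------------------------------------------

def scan_loss(anchor_probs: np.ndarray, neighbor_probs: np.ndarray,
              entropy_weight: float) -> float:
    """Evaluate the clustering objective on one batch.

    ``anchor_probs`` is B x C; ``neighbor_probs`` is B x k x C with
    row j holding the head's distributions for anchor j's k neighbors.
    The cluster-usage vector p is the column mean of the anchor
    probabilities.  Returns consistency + entropy_weight * sum p_i ln p_i
    with the conventions 0 ln 0 := 0 and dot products clipped at 1e-12.
    """
    if entropy_weight < 0:
        raise ValueError("entropy_weight must be >= 0")
    if anchor_probs.ndim != 2 or neighbor_probs.ndim != 3 \
            or neighbor_probs.shape[0] != anchor_probs.shape[0] \
            or neighbor_probs.shape[2] != anchor_probs.shape[1]:
        raise ValueError("anchor/neighbor shape mismatch")
    B = anchor_probs.shape[0]
    dots = np.einsum("bc,bkc->bk", anchor_probs, neighbor_probs)
    consistency = -np.sum(np.log(np.clip(dots, _CLIP, None))) / B
    p = anchor_probs.mean(axis=0)
    ent = np.sum(np.where(p > 0, p * np.log(np.clip(p, _CLIP, None)), 0.0))
    return float(consistency + entropy_weight * ent)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _forward(params: dict[str, np.ndarray], X: np.ndarray, dropout: float,
             rng: np.random.Generator | None):
    """Forward pass returning probabilities and the cache for backprop."""
    z1 = X @ params["W1"].T + params["b1"]
    h = relu(z1)
    if rng is not None and dropout > 0:
        mask = (rng.random(h.shape) >= dropout) / (1 - dropout)
        h = h * mask
    else:
        mask = None
    logits = h @ params["W2"].T + params["b2"]
    probs = softmax(logits)
    return probs, (X, z1, h, mask)


def _backward(params, dlogits, cache, grads):
    X, z1, h, mask = cache
    grads["W2"] += dlogits.T @ h
    grads["b2"] += dlogits.sum(axis=0)
    dh = dlogits @ params["W2"]
    if mask is not None:
        dh = dh * mask
    dz1 = dh * (z1 > 0)
    grads["W1"] += dz1.T @ X
    grads["b1"] += dz1.sum(axis=0)


def train_scan(emb: EmbeddingMatrix, neighbors: NeighborTable,
               cfg: ScanConfig = ScanConfig()) -> ClusterHead:
    """Train the cluster head by mini-batch Adam on the SCAN objective.

    Each batch holds a set of anchors plus all their k neighbors; the
    cluster-usage vector p is computed per batch.  The consistency term
    is averaged over each anchor's k neighbors during training (the
    stochastic one-neighbor-per-step treatment common in this
    literature, in expectation): with the neighbor *sum*, consistency
    outweighs the entropy regulariser by a factor k and training
    reliably merges clusters even where the entropy-weighted optimum
    separates them.  The evaluation objective ``scan_loss`` keeps the
    summed form.  ``epochs=0`` returns the seeded initialization
    untouched.  Raises on divergence to a non-finite loss.
    """
    n, dim = emb.values.shape
    if n == 0:
        raise ValueError("empty embedding matrix")
    if neighbors.indices.shape[0] != n:
        raise ValueError("neighbor table does not match embeddings")
    head = ClusterHead.initialize(dim, cfg)
    if cfg.epochs == 0:
        return head
    params = {"W1": head.W1, "b1": head.b1, "W2": head.W2, "b2": head.b2}
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    X = emb.values
    N = neighbors.indices
    k = neighbors.k
    lam = cfg.entropy_weight

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            B = len(idx)
            a_probs, a_cache = _forward(params, X[idx], cfg.dropout, rng)
            nb_idx = N[idx].reshape(-1)
            n_probs_flat, n_cache = _forward(params, X[nb_idx], cfg.dropout, rng)
            n_probs = n_probs_flat.reshape(B, k, -1)

            dots = np.clip(np.einsum("bc,bkc->bk", a_probs, n_probs), _CLIP, None)
            p = a_probs.mean(axis=0)
            loss = -np.sum(np.log(dots)) / (B * k) \
                + lam * np.sum(np.where(p > 0, p * np.log(np.clip(p, _CLIP, None)), 0.0))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"SCAN training diverged to non-finite loss at epoch {epoch}")
            epoch_loss += loss
            n_batches += 1

            # gradients wrt probabilities (consistency averaged over neighbors)
            inv = 1.0 / dots  # (B, k)
            da = -np.einsum("bk,bkc->bc", inv, n_probs) / (B * k)
            da += lam * (np.log(np.clip(p, _CLIP, None)) + 1.0) / B
            dn = -np.einsum("bk,bc->bkc", inv, a_probs) / (B * k)
            # through the softmax: dlogit = p * (g - sum(g*p))
            da_logit = a_probs * (da - np.sum(da * a_probs, axis=1, keepdims=True))
            dn_flat = dn.reshape(B * k, -1)
            dn_logit = n_probs_flat * (dn_flat - np.sum(dn_flat * n_probs_flat, axis=1, keepdims=True))

            grads = {key: np.zeros_like(v) for key, v in params.items()}
            _backward(params, da_logit, a_cache, grads)
            _backward(params, dn_logit, n_cache, grads)
            opt.step(grads)
        head.loss_trajectory.append(epoch_loss / n_batches)
    return head


def assign(head: ClusterHead, emb: EmbeddingMatrix) -> np.ndarray:
    """Hard cluster assignment: argmax of f(x), ties to the lowest id."""
    probs = head.probabilities(emb.values)
    return np.argmax(probs, axis=1)


def usage_entropy(assignment: np.ndarray, num_clusters: int) -> float:
    """Shannon entropy (nats) of the hard cluster-usage histogram;
    0 for total collapse, ln(num_clusters) for perfectly even usage."""
    p = np.bincount(assignment, minlength=num_clusters) / len(assignment)
    return float(-np.sum(np.where(p > 0, p * np.log(np.clip(p, _CLIP, None)), 0.0)))


def kmeans_baseline(emb: EmbeddingMatrix, num_clusters: int, seed: int = 0) -> np.ndarray:
    """Seeded Lloyd k-means on the (unit-norm) embedding rows."""
    n = emb.values.shape[0]
    if num_clusters > n:
        raise ValueError("more clusters than points")
    km = KMeans(n_clusters=num_clusters, random_state=seed, n_init=10)
    return km.fit_predict(emb.values)
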