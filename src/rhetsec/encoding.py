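"""Sentence encoders and label-supervised encoder fine-tuning.

The default encoder is a deterministic hashed n-gram encoder: character
1-3-grams of the (token-truncated) sentence are hashed into a large
bucket space, TF-weighted, and projected to ``dim`` dimensions by a
seed-fixed Gaussian random projection, then L2-normalized.  It is a pure
function of (records, config) — no downloads, no model weights — and
behaves like a bag-of-character-n-grams embedding: sentences sharing
surface n-grams land near each other.  Any callable with the same
signature (e.g. a pretrained sentence-transformer wrapper) can be
plugged in wherever an encoder is accepted.

``finetune_encoder`` is the supervision step applied before clustering:
a linear adapter (initialised at identity) plus a softmax class probe
are trained with cross-entropy on labelled embeddings; the probe is
discarded and the adapter returned.  The adapter reorients the embedding
space toward the rhetorical function of a sentence and away from its
literal topical content.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, glorot, one_hot, softmax
from .corpus_synth import CLASSES, SentenceRecord

__all__ = ["EncoderConfig", "EmbeddingMatrix", "EncoderAdapter",
           "encode", "finetune_encoder"]


@dataclass(frozen=True)
class EncoderConfig:
    dim: int = 768
    max_tokens: int = 64
    hash_buckets: int = 2 ** 18
    normalize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.dim < 8:
            raise ValueError("dim must be >= 8")
        if self.max_tokens < 1:
            raise ValueError("max_tokens must be >= 1")
        if self.dim > self.hash_buckets:
            raise ValueError("dim must not exceed hash_buckets")

    def fingerprint(self) -> str:
        key = f"hashgram|dim={self.dim}|max_tokens={self.max_tokens}|buckets={self.hash_buckets}|norm={self.normalize}|seed={self.seed}"
        return hashlib.sha256(key.encode()).hexdigest()[:16]


@dataclass
class EmbeddingMatrix:
    """An n x d matrix of sentence embeddings row-aligned with ids."""

    values: np.ndarray
    ids: list[str]
    normalize: bool = True

    def __post_init__(self):
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids must align with rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def record_id(r: SentenceRecord) -> str:
    return f"{r.abstract_id}#{r.sentence_index}"


# ---------------------------------------------------------------------------
# Hashed n-gram encoder
# ---------------------------------------------------------------------------

def _has_cjk(text: str) -> bool:
    return any("一" <= ch <= "鿿" for ch in text)


def _truncate(text: str, max_tokens: int) -> str:
    # character tokens for CJK text, whitespace tokens otherwise
    if _has_cjk(text):
        return text[:max_tokens]
    return " ".join(text.split()[:max_tokens])


def _bucket(ngram: str, buckets: int) -> int:
    h = hashlib.blake2b(ngram.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(h, "little") % buckets


def _ngram_counts(text: str, buckets: int) -> dict[int, int]:
    counts: dict[int, int] = {}
    n = len(text)
    for size in (1, 2, 3):
        for i in range(n - size + 1):
            b = _bucket(text[i:i + size], buckets)
            counts[b] = counts.get(b, 0) + 1
    return counts


def _projection_column(seed: int, bucket: int, dim: int) -> np.ndarray:
    """The seed-fixed Gaussian projection vector for one hash bucket."""
    rng = np.random.Generator(np.random.Philox(key=(seed, bucket)))
    return rng.standard_normal(dim)


def encode(records: list[SentenceRecord], config: EncoderConfig = EncoderConfig()) -> EmbeddingMatrix:
    """Encode sentences with the hashed-n-gram random-projection encoder.

    Deterministic: same records and config give bit-identical output.
    """
    if not records:
        raise ValueError("cannot encode an empty record list")
    rows = []
    for r in records:
        text = _truncate(r.text, config.max_tokens)
        counts = _ngram_counts(text, config.hash_buckets)
        rows.append(counts)

    # Gaussian projection columns only for buckets that actually occur;
    # each column depends only on (seed, bucket id), so the embedding of a
    # sentence is independent of what else is in the batch.
    vocab = sorted(set().union(*[set(c) for c in rows]))
    proj = np.empty((len(vocab), config.dim))
    for j, b in enumerate(vocab):
        proj[j] = _projection_column(config.seed, b, config.dim)
    col_of = {b: j for j, b in enumerate(vocab)}

    values = np.zeros((len(records), config.dim))
    for i, counts in enumerate(rows):
        total = sum(counts.values())
        for b, c in counts.items():
            values[i] += (c / total) * proj[col_of[b]]
    if config.normalize:
        norms = np.linalg.norm(values, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        values = values / norms
    return EmbeddingMatrix(values=values, ids=[record_id(r) for r in records],
                           normalize=config.normalize)


# ---------------------------------------------------------------------------
# Label-supervised fine-tuning
# ---------------------------------------------------------------------------

@dataclass
class EncoderAdapter:
    """A linear map (dim x dim plus bias) learned on labelled embeddings.

    ``apply`` preserves dimension and re-normalizes rows when the source
    embeddings were normalized.
    """

    weight: np.ndarray
    bias: np.ndarray
    epochs: int = 0
    seed: int = 0
    initial_loss: float = float("nan")
    final_loss: float = float("nan")
    probe_accuracy: float = float("nan")

    @classmethod
    def identity(cls, dim: int, seed: int = 0) -> "EncoderAdapter":
        return cls(weight=np.eye(dim), bias=np.zeros(dim), epochs=0, seed=seed)

    def apply(self, emb: EmbeddingMatrix) -> EmbeddingMatrix:
        values = emb.values @ self.weight.T + self.bias
        if emb.normalize:
            norms = np.linalg.norm(values, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            values = values / norms
        return EmbeddingMatrix(values=values, ids=list(emb.ids), normalize=emb.normalize)


def finetune_encoder(train: list[SentenceRecord], base_embeddings: EmbeddingMatrix,
                     epochs: int = 30, seed: int = 0, learning_rate: float = 1e-2,
                     batch_size: int = 64) -> EncoderAdapter:
    """Train a linear adapter + 4-class softmax probe with cross-entropy.

    The probe is discarded; the adapter (initialised at identity, so
    ``epochs=0`` returns the identity map unchanged) is returned with its
    training metadata.  The adapter and probe are trained jointly from a
    fresh initialisation, so the default learning rate is sized for
    from-scratch training of a linear model, not transformer fine-tuning.
    """
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    labels = [r.label for r in train]
    if any(l is None for l in labels):
        raise ValueError("fine-tuning requires labels on every record")
    classes_present = set(labels)
    if len(classes_present) < 2:
        raise ValueError("fine-tuning requires at least 2 classes")
    y = np.array([CLASSES.index(l) for l in labels])
    X = base_embeddings.values
    n, dim = X.shape
    if n != len(train):
        raise ValueError("embeddings not aligned with records")

    rng = np.random.default_rng(seed)
    params = {
        "W": np.eye(dim),
        "b": np.zeros(dim),
        "P": glorot(rng, 4, dim),
        "pb": np.zeros(4),
    }
    if epochs == 0:
        return EncoderAdapter.identity(dim, seed=seed)

    opt = Adam(params, lr=learning_rate)
    Y = one_hot(y, 4)
    initial_loss = final_loss = None
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X[idx], Y[idx]
            z = xb @ params["W"].T + params["b"]
            logits = z @ params["P"].T + params["pb"]
            p = softmax(logits)
            loss = -np.mean(np.sum(yb * np.log(np.clip(p, 1e-12, None)), axis=1))
            epoch_loss += loss * len(idx)
            dlogits = (p - yb) / len(idx)
            grads = {
                "P": dlogits.T @ z,
                "pb": dlogits.sum(axis=0),
            }
            dz = dlogits @ params["P"]
            grads["W"] = dz.T @ xb
            grads["b"] = dz.sum(axis=0)
            opt.step(grads)
        epoch_loss /= n
        if initial_loss is None:
            initial_loss = epoch_loss
        final_loss = epoch_loss

    z = X @ params["W"].T + params["b"]
    pred = np.argmax(z @ params["P"].T + params["pb"], axis=1)
    return EncoderAdapter(weight=params["W"], bias=params["b"], epochs=epochs,
                          seed=seed, initial_loss=float(initial_loss),
                          final_loss=float(final_loss),
                          probe_accuracy=float(np.mean(pred == y)))
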