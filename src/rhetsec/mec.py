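"""Multi-encoder-cascade (MEC) supervised sentence classifier.

Given a sentence embedding V, three parallel "encoders" produce
augmented views of it:

1. a constant-shift perturbation  W = (V_1 + n, ..., V_d + n) with a
   small random scalar n drawn per sample during training;
2. an autoencoder  W = AE(V), a fully connected d -> h -> d network
   pretrained on duplicate sentence pairs so that it maps an embedding
   toward the embedding of a paraphrase;
3. a denoising autoencoder  W = DA(V + eps), eps ~ N(0, sigma^2 I),
   pretrained to reconstruct the clean embedding from a corrupted one.

The three views then cross-supervise each other through dynamic
convolution: for each view, the *other two* views are concatenated into
a 2-channel sequence and passed through a dynamic-convolution layer — a
1-D convolution whose effective kernels are an input-conditioned
softmax mixture of K candidate kernel banks — with multiple kernel
sizes, ReLU, max-pooling over positions, and a linear map back to d.
Each layer's output o_i is pulled toward its own view e_i by an MSE
term (weight gamma) added to the classification loss.  Finally the
three outputs are concatenated with the original V and classified by a
linear softmax layer with dropout.

The AE and DA are pretrained and frozen during classifier training; the
trainable parameters are the three dynamic-convolution layers and the
classifier.  Everything is deterministic given (data, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._nn import Adam, glorot, he, one_hot, relu, softmax
from .corpus_synth import CLASSES
from .encoding import EmbeddingMatrix

__all__ = ["MecConfig", "EncoderParams", "CorruptionResult", "DynamicConvLayer",
           "MecModel", "linear_perturb", "corrupt", "train_autoencoder",
           "train_denoising_autoencoder", "dynamic_conv", "train_mec", "predict"]


@dataclass(frozen=True)
class MecConfig:
    dim: int = 768
    perturb_scale: float = 0.01       # n ~ Uniform(-perturb_scale, +perturb_scale)
    dae_sigma: float = 0.1            # eps ~ N(0, sigma^2 I)
    ae_hidden: int = 256
    dc_kernel_sizes: tuple[int, ...] = (2, 3, 4)
    dc_total_filters: int = 256
    dc_candidate_kernels: int = 4
    supervision_weight: float = 0.1
    dropout: float = 0.5
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 5e-5
    seed: int = 0
    dc_mode: str = "dynamic"          # dynamic | bypass (o_i = e_i) | zero
    supervision_direction: str = "dc_to_encoder"  # or encoder_to_dc

    def __post_init__(self):
        if self.perturb_scale <= 0:
            raise ValueError("perturb_scale must be > 0")
        if self.dae_sigma < 0:
            raise ValueError("dae_sigma must be >= 0")
        if self.dc_mode not in ("dynamic", "bypass", "zero"):
            raise ValueError(f"unknown dc_mode {self.dc_mode!r}")
        if self.supervision_direction not in ("dc_to_encoder", "encoder_to_dc"):
            raise ValueError(f"unknown supervision_direction {self.supervision_direction!r}")
        if self.dc_candidate_kernels < 1:
            raise ValueError("dc_candidate_kernels must be >= 1")

    def filters_per_size(self) -> dict[int, int]:
        """Split total filters evenly across kernel sizes, remainder to the largest."""
        sizes = tuple(self.dc_kernel_sizes)
        base, rem = divmod(self.dc_total_filters, len(sizes))
        out = {s: base for s in sizes}
        out[max(sizes)] += rem
        return out


# ---------------------------------------------------------------------------
# The three encoder branches
# ---------------------------------------------------------------------------

def linear_perturb(V: np.ndarray, n: float) -> np.ndarray:
    """Add the same scalar n to every coordinate of V."""
    if not np.isfinite(n):
        raise ValueError("perturbation n must be finite")
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("V must be finite")
    return V + n


@dataclass(frozen=True)
class CorruptionResult:
    vn: np.ndarray
    eps: np.ndarray


def corrupt(V: np.ndarray, sigma: float, seed: int = 0) -> CorruptionResult:
    """Gaussian corruption VN = V + eps, eps ~ N(0, sigma^2 I), seeded."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    V = np.asarray(V, dtype=float)
    rng = np.random.default_rng(seed)
    eps = sigma * rng.standard_normal(V.shape) if sigma > 0 else np.zeros_like(V)
    return CorruptionResult(vn=V + eps, eps=eps)


@dataclass
class EncoderParams:
    """Fully connected map dim -> hidden -> dim (ReLU in the middle)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    final_loss: float = float("nan")
    initial_loss: float = float("nan")
    loss_trajectory: list[float] = field(default_factory=list)

    @classmethod
    def initialize(cls, dim: int, hidden: int, seed: int) -> "EncoderParams":
        rng = np.random.default_rng(seed)
        return cls(W1=he(rng, hidden, dim), b1=np.zeros(hidden),
                   W2=glorot(rng, dim, hidden), b2=np.zeros(dim))

    def forward(self, X: np.ndarray) -> np.ndarray:
        if X.shape[-1] != self.W1.shape[1]:
            raise ValueError("dimension mismatch")
        h = relu(X @ self.W1.T + self.b1)
        return h @ self.W2.T + self.b2


def _train_reconstruction(inputs: np.ndarray, targets_fn, dim: int, cfg: MecConfig,
                          epochs: int | None, learning_rate: float | None,
                          seed: int | None) -> EncoderParams:
    """Shared training loop for AE (fixed targets) and DA (fresh noise per epoch).

    ``targets_fn(rng, epoch)`` returns (X_epoch, Y_epoch).
    """
    epochs = cfg.epochs if epochs is None else epochs
    lr = cfg.learning_rate if learning_rate is None else learning_rate
    seed = cfg.seed if seed is None else seed
    enc = EncoderParams.initialize(dim, cfg.ae_hidden, seed)
    if epochs == 0:
        return enc
    params = {"W1": enc.W1, "b1": enc.b1, "W2": enc.W2, "b2": enc.b2}
    opt = Adam(params, lr=lr)
    rng = np.random.default_rng(seed + 1)
    n = inputs.shape[0]
    for epoch in range(epochs):
        X, Y = targets_fn(rng, epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            z1 = xb @ params["W1"].T + params["b1"]
            h = relu(z1)
            out = h @ params["W2"].T + params["b2"]
            diff = out - yb
            loss = float(np.mean(diff ** 2))
            epoch_loss += loss * len(idx)
            dout = 2.0 * diff / diff.size
            dh = dout @ params["W2"]
            dz1 = dh * (z1 > 0)
            opt.step({"W2": dout.T @ h, "b2": dout.sum(axis=0),
                      "W1": dz1.T @ xb, "b1": dz1.sum(axis=0)})
        enc.loss_trajectory.append(epoch_loss / n)
    enc.initial_loss = enc.loss_trajectory[0]
    enc.final_loss = enc.loss_trajectory[-1]
    return enc


def train_autoencoder(pairs: list[tuple[np.ndarray, np.ndarray]], cfg: MecConfig,
                      epochs: int | None = None, learning_rate: float | None = None,
                      seed: int | None = None) -> EncoderParams:
    """Train the autoencoder branch on duplicate embedding pairs.

    Minimises MSE between AE(first) and second over the pairs; the final
    recorded training loss is <= the initial one for any sane learning
    rate.
    """
    if not pairs:
        raise ValueError("need at least one duplicate pair")
    X = np.asarray([p[0] for p in pairs], dtype=float)
    Y = np.asarray([p[1] for p in pairs], dtype=float)
    if X.shape != Y.shape:
        raise ValueError("pair sides must have equal dimension")
    return _train_reconstruction(X, lambda rng, ep: (X, Y), X.shape[1], cfg,
                                 epochs, learning_rate, seed)


def train_denoising_autoencoder(vectors: np.ndarray, sigma: float, cfg: MecConfig,
                                epochs: int | None = None,
                                learning_rate: float | None = None,
                                seed: int | None = None) -> EncoderParams:
    """Train the denoising branch: reconstruct V from V + fresh Gaussian noise.

    Noise is redrawn every epoch; sigma=0 reduces to plain reconstruction.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    V = np.asarray(vectors, dtype=float)
    if V.size == 0:
        raise ValueError("empty input")

    def targets(rng, epoch):
        if sigma == 0:
            return V, V
        return V + sigma * rng.standard_normal(V.shape), V

    return _train_reconstruction(V, targets, V.shape[1], cfg, epochs,
                                 learning_rate, seed)


# ---------------------------------------------------------------------------
# Dynamic convolution
# ---------------------------------------------------------------------------

class DynamicConvLayer:
    """Dynamic 1-D convolution over a 2-channel, length-dim sequence.

    For each kernel size s the layer holds K candidate kernel banks of
    shape (filters_s, 2, s).  A gate — global average pool over
    positions, a linear map to K, softmax — mixes the candidates into
    one effective bank per input; convolution (valid padding), ReLU and
    max-pool over positions yield the filter features, and a final
    linear map returns a dim-vector.  With K=1 the gate weight is
    identically 1 and the layer is a standard convolution.
    """

    def __init__(self, dim: int, cfg: MecConfig, seed: int):
        self.dim = dim
        self.sizes = tuple(cfg.dc_kernel_sizes)
        self.filters = cfg.filters_per_size()
        self.K = cfg.dc_candidate_kernels
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for s in self.sizes:
            f = self.filters[s]
            self.params[f"bank{s}"] = rng.normal(0.0, np.sqrt(2.0 / (2 * s)),
                                                 size=(self.K, f, 2, s))
            self.params[f"cbias{s}"] = np.zeros(f)
            self.params[f"gateW{s}"] = glorot(rng, self.K, 2)
            self.params[f"gateb{s}"] = np.zeros(self.K)
        total = sum(self.filters.values())
        self.params["Wo"] = glorot(rng, dim, total)
        self.params["bo"] = np.zeros(dim)

    def forward(self, X: np.ndarray, want_cache: bool = False):
        """X is (B, 2*dim): the concatenation of the two sibling views."""
        if X.ndim != 2 or X.shape[1] != 2 * self.dim:
            raise ValueError(f"expected input of length {2 * self.dim}, got {X.shape}")
        B = X.shape[0]
        Xs = X.reshape(B, 2, self.dim)
        gap = Xs.mean(axis=2)  # (B, 2)
        feats, cache = [], {"Xs": Xs, "gap": gap}
        for s in self.sizes:
            f = self.filters[s]
            cols = np.lib.stride_tricks.sliding_window_view(Xs, s, axis=2)
            cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B, -1, 2 * s)
            gl = gap @ self.params[f"gateW{s}"].T + self.params[f"gateb{s}"]
            g = softmax(gl)  # (B, K)
            bank = self.params[f"bank{s}"].reshape(self.K, f, 2 * s)
            keff = np.tensordot(g, bank, axes=(1, 0))          # (B, f, 2s)
            conv = cols @ keff.transpose(0, 2, 1) + self.params[f"cbias{s}"]
            act = relu(conv)
            arg = act.argmax(axis=1)            # (B, f)
            pooled = np.take_along_axis(act, arg[:, None, :], axis=1)[:, 0, :]
            feats.append(pooled)
            cache[f"s{s}"] = (cols, g, keff, conv, arg, pooled)
        feat = np.concatenate(feats, axis=1)
        out = feat @ self.params["Wo"].T + self.params["bo"]
        cache["feat"] = feat
        return (out, cache) if want_cache else out

    def backward(self, dout: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Parameter gradients for a batch (inputs are frozen upstream)."""
        grads = {"Wo": dout.T @ cache["feat"], "bo": dout.sum(axis=0)}
        dfeat = dout @ self.params["Wo"]
        gap = cache["gap"]
        col0 = 0
        for s in self.sizes:
            f = self.filters[s]
            cols, g, keff, conv, arg, pooled = cache[f"s{s}"]
            dpool = dfeat[:, col0:col0 + f] * (pooled > 0)
            col0 += f
            dact = np.zeros_like(conv)
            np.put_along_axis(dact, arg[:, None, :], dpool[:, None, :], axis=1)
            dconv = dact * (conv > 0)
            grads[f"cbias{s}"] = dconv.sum(axis=(0, 1))
            dkeff = dconv.transpose(0, 2, 1) @ cols            # (B, f, 2s)
            bank = self.params[f"bank{s}"].reshape(self.K, f, 2 * s)
            grads[f"bank{s}"] = np.tensordot(g, dkeff, axes=(0, 0)).reshape(
                self.params[f"bank{s}"].shape)
            dg = np.tensordot(dkeff, bank, axes=([1, 2], [1, 2]))
            dgl = g * (dg - np.sum(dg * g, axis=1, keepdims=True))
            grads[f"gateW{s}"] = dgl.T @ gap
            grads[f"gateb{s}"] = dgl.sum(axis=0)
        return grads


def dynamic_conv(supervision_input: np.ndarray, layer: DynamicConvLayer) -> np.ndarray:
    """Forward one 2*dim vector (or a batch) through a dynamic-conv layer."""
    X = np.atleast_2d(np.asarray(supervision_input, dtype=float))
    out = layer.forward(X)
    return out[0] if supervision_input.ndim == 1 else out


# ---------------------------------------------------------------------------
# The full model
# ---------------------------------------------------------------------------

@dataclass
class MecModel:
    config: MecConfig
    ae: EncoderParams
    da: EncoderParams
    dc_layers: list[DynamicConvLayer] | None
    clf_W: np.ndarray
    clf_b: np.ndarray
    loss_trajectory: list[float] = field(default_factory=list)

    def _branch_outputs(self, V: np.ndarray, training: bool,
                        rng: np.random.Generator | None):
        cfg = self.config
        B = V.shape[0]
        if training and rng is not None:
            n = rng.uniform(-cfg.perturb_scale, cfg.perturb_scale, size=(B, 1))
            eps = cfg.dae_sigma * rng.standard_normal(V.shape) if cfg.dae_sigma > 0 else 0.0
        else:
            n, eps = 0.0, 0.0   # noise is a train-time augmentation only
        e1 = V + n
        e2 = self.ae.forward(V)
        e3 = self.da.forward(V + eps)
        return e1, e2, e3

    def features(self, V: np.ndarray, training: bool = False,
                 rng: np.random.Generator | None = None, want_caches: bool = False):
        cfg = self.config
        e1, e2, e3 = self._branch_outputs(V, training, rng)
        inputs = [np.concatenate([e2, e3], axis=1),
                  np.concatenate([e1, e3], axis=1),
                  np.concatenate([e1, e2], axis=1)]
        caches = [None, None, None]
        if cfg.dc_mode == "dynamic":
            outs = []
            for i, layer in enumerate(self.dc_layers):
                o, c = layer.forward(inputs[i], want_cache=True)
                outs.append(o)
                caches[i] = c
        elif cfg.dc_mode == "bypass":
            outs = [e1, e2, e3]
        else:  # zero
            outs = [np.zeros_like(e1)] * 3
        feat = np.concatenate(outs + [V], axis=1)
        if want_caches:
            return feat, outs, (e1, e2, e3), caches
        return feat

    def probabilities(self, V: np.ndarray) -> np.ndarray:
        feat = self.features(V, training=False)
        return softmax(feat @ self.clf_W.T + self.clf_b)


def _as_int_labels(labels) -> np.ndarray:
    labels = list(labels)
    if labels and isinstance(labels[0], str):
        return np.array([CLASSES.index(l) for l in labels])
    return np.asarray(labels, dtype=int)


def train_mec(emb: EmbeddingMatrix, labels, cfg: MecConfig = MecConfig(),
              ae: EncoderParams | None = None, da: EncoderParams | None = None,
              duplicate_pairs: list[tuple[np.ndarray, np.ndarray]] | None = None,
              learning_rate: float | None = None) -> MecModel:
    """Train the MEC classifier on labelled embeddings.

    The AE and DA branches may be passed in pretrained; if absent they
    are pretrained here (the AE on ``duplicate_pairs`` when given,
    otherwise on identity pairs of the training embeddings; the DA on
    the training embeddings with ``cfg.dae_sigma``) and then frozen.
    The trainable parameters are the three dynamic-convolution layers
    and the linear classifier; the objective is cross-entropy plus
    ``supervision_weight`` times the sum of MSE(o_i, stop_grad(e_i)).
    """
    V = emb.values
    y = _as_int_labels(labels)
    if len(y) != V.shape[0]:
        raise ValueError("labels not aligned with embeddings")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train")
    dim = V.shape[1]
    C = len(CLASSES)
    lr = cfg.learning_rate if learning_rate is None else learning_rate

    if ae is None:
        pairs = duplicate_pairs if duplicate_pairs is not None \
            else [(v, v) for v in V]
        ae = train_autoencoder(pairs, replace(cfg, dim=dim), learning_rate=1e-3,
                               seed=cfg.seed + 11)
    if da is None:
        da = train_denoising_autoencoder(V, cfg.dae_sigma, replace(cfg, dim=dim),
                                         learning_rate=1e-3, seed=cfg.seed + 13)

    rng = np.random.default_rng(cfg.seed)
    dc_layers = None
    params: dict[str, np.ndarray] = {}
    if cfg.dc_mode == "dynamic":
        dc_layers = [DynamicConvLayer(dim, cfg, seed=cfg.seed + 100 + i) for i in range(3)]
        for i, layer in enumerate(dc_layers):
            for k, v in layer.params.items():
                params[f"dc{i}/{k}"] = v
    clf_W = glorot(rng, C, 4 * dim)
    clf_b = np.zeros(C)
    params["clf_W"] = clf_W
    params["clf_b"] = clf_b

    model = MecModel(config=cfg, ae=ae, da=da, dc_layers=dc_layers,
                     clf_W=clf_W, clf_b=clf_b)
    opt = Adam(params, lr=lr)
    Y = one_hot(y, C)
    n = V.shape[0]
    gamma = cfg.supervision_weight

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            vb, yb = V[idx], Y[idx]
            B = len(idx)
            feat, outs, encs, caches = model.features(vb, training=True, rng=rng,
                                                      want_caches=True)
            if cfg.dropout > 0:
                mask = (rng.random(feat.shape) >= cfg.dropout) / (1 - cfg.dropout)
                featd = feat * mask
            else:
                mask = None
                featd = feat
            logits = featd @ model.clf_W.T + model.clf_b
            p = softmax(logits)
            ce = -np.mean(np.sum(yb * np.log(np.clip(p, 1e-12, None)), axis=1))
            sup = 0.0
            if cfg.dc_mode == "dynamic" and gamma > 0:
                sup = gamma * sum(float(np.mean((o - e) ** 2))
                                  for o, e in zip(outs, encs))
            loss = ce + sup
            epoch_loss += loss * B

            dlogits = (p - yb) / B
            grads = {"clf_W": dlogits.T @ featd, "clf_b": dlogits.sum(axis=0)}
            if cfg.dc_mode == "dynamic":
                dfeat = dlogits @ model.clf_W
                if mask is not None:
                    dfeat = dfeat * mask
                for i, layer in enumerate(dc_layers):
                    do = dfeat[:, i * dim:(i + 1) * dim].copy()
                    if gamma > 0 and cfg.supervision_direction == "dc_to_encoder":
                        do += gamma * 2.0 * (outs[i] - encs[i]) / outs[i].size
                    for k, gv in layer.backward(do, caches[i]).items():
                        grads[f"dc{i}/{k}"] = gv
            opt.step(grads)
        model.loss_trajectory.append(epoch_loss / n)
    return model


def predict(model: MecModel, emb: EmbeddingMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic prediction: class argmax (ties to the lowest id) and
    the full probability matrix (rows sum to 1)."""
    probs = model.probabilities(emb.values)
    return np.argmax(probs, axis=1), probs
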