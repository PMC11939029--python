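"""Multi-encoder-cascade components: branches, dynamic convolution, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhetsec import (EmbeddingMatrix, MecConfig, corrupt, dynamic_conv,
                     linear_perturb, predict, train_autoencoder,
                     train_denoising_autoencoder, train_mec)
from rhetsec.mec import DynamicConvLayer, EncoderParams
from rhetsec._nn import softmax

from conftest import HEAD_LR, sim_matrix


# ---------------------------------------------------------------------------
# linear perturbation and corruption
# ---------------------------------------------------------------------------

def test_perturb_identity_and_closed_form():
    v = np.array([1.0, -2.0, 3.0])
    assert np.array_equal(linear_perturb(v, 0.0), v)
    assert np.allclose(linear_perturb(np.zeros(4), 0.1), np.full(4, 0.1))
    with pytest.raises(ValueError):
        linear_perturb(v, float("nan"))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(-5, 5))
def test_perturb_shifts_every_coordinate_equally(seed, n):
    v = np.random.default_rng(seed).normal(size=16)
    diff = linear_perturb(v, n) - v
    assert np.allclose(diff, n, atol=1e-12)


def test_corrupt_zero_sigma_and_determinism():
    v = np.arange(8.0)
    r0 = corrupt(v, 0.0, seed=1)
    assert np.array_equal(r0.vn, v) and np.all(r0.eps == 0)
    r1 = corrupt(v, 0.1, seed=2)
    r2 = corrupt(v, 0.1, seed=2)
    assert np.array_equal(r1.eps, r2.eps)
    assert np.allclose(r1.vn - v, r1.eps)
    with pytest.raises(ValueError):
        corrupt(v, -0.1)


def test_corrupt_noise_variance():
    # 10^5 coordinate draws at sigma=0.1: sample variance within 3 SE of 0.01.
    # Var of the sample variance of N(0, s^2) is ~2 s^4 / n.
    r = corrupt(np.zeros(100_000), 0.1, seed=3)
    se3 = 3 * np.sqrt(2 * 0.1 ** 4 / 100_000)
    assert abs(np.var(r.eps) - 0.01) < se3


# ---------------------------------------------------------------------------
# autoencoder branches
# ---------------------------------------------------------------------------

def _small_cfg(**kw):
    defaults = dict(dim=16, ae_hidden=32, epochs=200, batch_size=10, seed=0)
    defaults.update(kw)
    return MecConfig(**defaults)


def test_autoencoder_learns_identity_pairs():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(10, 16))
    pairs = [(p, p) for p in pts]
    # epoch count fixed from a pilot run at this seed
    enc = train_autoencoder(pairs, _small_cfg(), learning_rate=1e-2, seed=1)
    assert enc.final_loss < 1e-3
    assert enc.final_loss <= enc.initial_loss


def test_autoencoder_zero_epochs_is_initialization():
    pairs = [(np.ones(8), np.ones(8))]
    enc = train_autoencoder(pairs, _small_cfg(dim=8), epochs=0, seed=5)
    ref = EncoderParams.initialize(8, 32, 5)
    assert np.array_equal(enc.W1, ref.W1) and np.array_equal(enc.W2, ref.W2)


def test_autoencoder_loss_mostly_decreasing():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(20, 12))
        enc = train_autoencoder([(p, p) for p in pts],
                                _small_cfg(dim=12, epochs=50),
                                learning_rate=1e-2, seed=seed)
        steps = np.diff(enc.loss_trajectory)
        assert np.mean(steps <= 0) >= 0.9


def test_autoencoder_validation():
    with pytest.raises(ValueError):
        train_autoencoder([], _small_cfg())
    with pytest.raises(ValueError):
        train_autoencoder([(np.ones(4), np.ones(5))], _small_cfg(dim=4))


def test_denoising_autoencoder_zero_sigma_reconstructs():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(10, 16))
    enc = train_denoising_autoencoder(pts, 0.0, _small_cfg(), learning_rate=1e-2, seed=2)
    assert enc.final_loss < 1e-3
    assert enc.forward(pts).shape == pts.shape


def test_denoising_autoencoder_beats_untrained():
    rng = np.random.default_rng(3)
    train_pts = rng.normal(size=(80, 16))
    held_out = rng.normal(size=(20, 16))
    trained = train_denoising_autoencoder(train_pts, 0.1, _small_cfg(epochs=300),
                                          learning_rate=1e-2, seed=3)
    untrained = EncoderParams.initialize(16, 32, 3)
    noisy = corrupt(held_out, 0.1, seed=9).vn
    err_t = np.mean((trained.forward(noisy) - held_out) ** 2)
    err_u = np.mean((untrained.forward(noisy) - held_out) ** 2)
    assert err_t < err_u


# ---------------------------------------------------------------------------
# dynamic convolution
# ---------------------------------------------------------------------------

def _toy_layer(K=2, dim=8, filters=4, sizes=(2, 3), seed=0):
    cfg = MecConfig(dim=dim, dc_total_filters=filters, dc_kernel_sizes=sizes,
                    dc_candidate_kernels=K)
    return DynamicConvLayer(dim, cfg, seed=seed), cfg


def scalar_dynamic_conv(layer, x):
    """Independent loop-based forward pass for one 2*dim input vector."""
    dim = layer.dim
    xs = [list(x[:dim]), list(x[dim:])]
    gap = [sum(ch) / dim for ch in xs]
    feats = []
    for s in layer.sizes:
        f = layer.filters[s]
        bank = layer.params[f"bank{s}"]
        gW, gb = layer.params[f"gateW{s}"], layer.params[f"gateb{s}"]
        logits = [sum(gW[kk][c] * gap[c] for c in range(2)) + gb[kk]
                  for kk in range(layer.K)]
        m = max(logits)
        exps = [np.exp(v - m) for v in logits]
        g = [e / sum(exps) for e in exps]
        for fi in range(f):
            best = None
            for p in range(dim - s + 1):
                acc = layer.params[f"cbias{s}"][fi]
                for c in range(2):
                    for t in range(s):
                        keff = sum(g[kk] * bank[kk][fi][c][t] for kk in range(layer.K))
                        acc += keff * xs[c][p + t]
                acc = max(acc, 0.0)
                best = acc if best is None else max(best, acc)
            feats.append(best)
    Wo, bo = layer.params["Wo"], layer.params["bo"]
    return np.array([sum(Wo[d][j] * feats[j] for j in range(len(feats))) + bo[d]
                     for d in range(dim)])


def test_dynamic_conv_matches_scalar_oracle():
    layer, _ = _toy_layer()
    rng = np.random.default_rng(4)
    for _ in range(3):
        x = rng.normal(size=16)
        assert np.allclose(dynamic_conv(x, layer), scalar_dynamic_conv(layer, x),
                           atol=1e-10)


def test_single_candidate_equals_standard_convolution():
    layer, _ = _toy_layer(K=1)
    rng = np.random.default_rng(5)
    x = rng.normal(size=16)
    out = dynamic_conv(x, layer)
    # with K=1 the gate is identically 1: replacing the gate weights must
    # not change anything
    layer.params["gateW2"][:] = rng.normal(size=layer.params["gateW2"].shape)
    layer.params["gateW3"][:] = rng.normal(size=layer.params["gateW3"].shape)
    assert np.allclose(dynamic_conv(x, layer), out)


def test_gate_softmax_normalized():
    layer, _ = _toy_layer(K=4)
    rng = np.random.default_rng(6)
    X = rng.normal(size=(5, 16))
    gap = X.reshape(5, 2, 8).mean(axis=2)
    for s in layer.sizes:
        g = softmax(gap @ layer.params[f"gateW{s}"].T + layer.params[f"gateb{s}"])
        assert np.allclose(g.sum(axis=1), 1.0)
        assert np.all(g >= 0)


def test_dynamic_conv_gradients_match_finite_differences():
    layer, _ = _toy_layer(K=2, dim=6, filters=4, sizes=(2, 3), seed=7)
    rng = np.random.default_rng(8)
    X = rng.normal(size=(3, 12))
    T = rng.normal(size=(3, 6))

    def loss():
        o = layer.forward(X)
        return 0.5 * np.sum((o - T) ** 2)

    out, cache = layer.forward(X, want_cache=True)
    grads = layer.backward(out - T, cache)
    eps = 1e-6
    for name, P in layer.params.items():
        flat = P.reshape(-1)
        for idx in [0, flat.size // 2, flat.size - 1]:
            old = flat[idx]
            flat[idx] = old + eps
            lp = loss()
            flat[idx] = old - eps
            lm = loss()
            flat[idx] = old
            num = (lp - lm) / (2 * eps)
            assert grads[name].reshape(-1)[idx] == pytest.approx(num, abs=1e-5, rel=1e-4)


def test_dynamic_conv_input_length_validation():
    layer, _ = _toy_layer(dim=8)
    with pytest.raises(ValueError):
        layer.forward(np.zeros((2, 15)))


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_training_setup():
    emb, labels = sim_matrix(2.0, 0.05, seed=2, n_per_class=60, dim=16)
    return emb, labels


def test_predict_rows_are_distributions_and_equivariant(tiny_training_setup):
    emb, labels = tiny_training_setup
    cfg = MecConfig(dim=16, ae_hidden=16, dc_total_filters=12, epochs=2, seed=0)
    model = train_mec(emb, labels, cfg, learning_rate=HEAD_LR)
    pred, probs = predict(model, emb)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)
    rng = np.random.default_rng(1)
    perm = rng.permutation(emb.n)
    permuted = EmbeddingMatrix(values=emb.values[perm],
                               ids=[emb.ids[i] for i in perm])
    pred_p, probs_p = predict(model, permuted)
    assert np.array_equal(pred_p, pred[perm])
    assert np.allclose(probs_p, probs[perm])


def test_predict_matches_rowwise_forward(tiny_training_setup):
    emb, labels = tiny_training_setup
    cfg = MecConfig(dim=16, ae_hidden=16, dc_total_filters=12, epochs=1, seed=1)
    model = train_mec(emb, labels, cfg, learning_rate=HEAD_LR)
    _, probs = predict(model, emb)
    for i in [0, 100, 239]:
        row = EmbeddingMatrix(values=emb.values[i:i + 1], ids=["x"])
        _, p_row = predict(model, row)
        assert np.allclose(p_row[0], probs[i], atol=1e-10)


def test_training_is_reproducible(tiny_training_setup):
    emb, labels = tiny_training_setup
    cfg = MecConfig(dim=16, ae_hidden=16, dc_total_filters=12, epochs=2, seed=3)
    m1 = train_mec(emb, labels, cfg, learning_rate=HEAD_LR)
    m2 = train_mec(emb, labels, cfg, learning_rate=HEAD_LR)
    assert np.array_equal(m1.clf_W, m2.clf_W)
    for l1, l2 in zip(m1.dc_layers, m2.dc_layers):
        for k in l1.params:
            assert np.array_equal(l1.params[k], l2.params[k])
    assert m1.loss_trajectory == m2.loss_trajectory


def test_zero_masked_model_is_linear_on_embedding():
    # separable benchmark: the gamma=0, DC-masked model reduces to a linear
    # classifier on V and must solve it
    emb, labels = sim_matrix(2.0, 0.05, seed=2, n_per_class=250, dim=64)
    ntr = 800
    tr = EmbeddingMatrix(values=emb.values[:ntr], ids=emb.ids[:ntr])
    te = EmbeddingMatrix(values=emb.values[ntr:], ids=emb.ids[ntr:])
    cfg = MecConfig(dim=64, seed=2, supervision_weight=0.0, dc_mode="zero")
    model = train_mec(tr, labels[:ntr], cfg, learning_rate=HEAD_LR)
    pred, _ = predict(model, te)
    assert np.mean(pred == labels[ntr:]) >= 0.85


def test_train_mec_validation(tiny_training_setup):
    emb, labels = tiny_training_setup
    with pytest.raises(ValueError):
        train_mec(emb, np.zeros(emb.n, dtype=int), MecConfig(dim=16))
    with pytest.raises(ValueError):
        train_mec(emb, labels[:5], MecConfig(dim=16))
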