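"""The predictor: shapes, determinism, ablations, and an independent forward oracle."""

import numpy as np
import pytest

from piwislice import autodiff as ad
from piwislice.autodiff import Tensor
from piwislice.encoding import GuideSequence, PairingSpec, encode_interaction
from piwislice.network import InteractionRegressor, ModelConfig, build_model
from piwislice.simulate import generate_benchmark

from conftest import zeroed


def all_match_encodings(L: int, n: int = 3):
    guide = GuideSequence("g", "ACGU" * (L // 4 + 1))
    guide = GuideSequence("g", guide.nucleotides[:L])
    return [encode_interaction(guide, PairingSpec.all_match(L))] * n


class TestConfig:
    def test_head_width_bookkeeping(self):
        assert ModelConfig().head_input_width == 26 * 16 + 8
        assert ModelConfig(ablation="no_insert").head_input_width == 26 * 16
        assert ModelConfig(ablation="simple_pairing").input_width == 6

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(conv_filters=15)
        with pytest.raises(ValueError, match="odd"):
            ModelConfig(kernel=4)
        with pytest.raises(ValueError, match="ablation"):
            ModelConfig(ablation="nope")


class TestBuildDeterminism:
    def test_same_seed_bit_identical(self, tiny_config):
        a = build_model(tiny_config, seed=7)
        b = build_model(tiny_config, seed=7)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_different_seed_differs(self, tiny_config):
        a = build_model(tiny_config, seed=1)
        b = build_model(tiny_config, seed=2)
        assert any(
            not np.array_equal(pa.data, pb.data)
            for pa, pb in zip(a.parameters(), b.parameters())
        )

    def test_parameter_counts(self):
        full = build_model(ModelConfig(), 0).count_parameters()
        no_pos = build_model(ModelConfig(ablation="no_position"), 0).count_parameters()
        no_ins = build_model(ModelConfig(ablation="no_insert"), 0).count_parameters()
        assert full - no_pos == 26 * 16  # the positional table
        # insertion branch (27*8+8) plus the head-width reduction (8*64)
        assert full - no_ins == 27 * 8 + 8 + 8 * 64
        assert build_model(ModelConfig(), 3).count_parameters() == full

    def test_simple_pairing_projection_width(self):
        m = build_model(ModelConfig(ablation="simple_pairing"), 0)
        assert m.proj.W.shape == (6, 16)
        assert build_model(ModelConfig(), 0).proj.W.shape == (11, 16)

    def test_no_position_has_no_table(self):
        m = build_model(ModelConfig(ablation="no_position"), 0)
        assert m.pos is None
        assert "pos" not in dict(m.named_parameters())


class TestForward:
    def test_zero_model_predicts_bias(self, tiny_config):
        m = zeroed(build_model(tiny_config, 0))
        enc = all_match_encodings(tiny_config.L, n=4)
        np.testing.assert_array_equal(m.predict(enc), np.zeros(4))

    def test_replication_equivariance(self, tiny_benchmark, tiny_config):
        data, _ = tiny_benchmark
        m = build_model(tiny_config, 3)
        encs = data.encodings()[:5]
        # no cross-record leakage: a record's prediction is unchanged (to BLAS
        # round-off) by duplication or by the other records in the batch
        batch = m.predict(encs + [encs[2]])
        np.testing.assert_allclose(batch[-1], batch[2], rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(m.predict([encs[2]]), [batch[2]], rtol=1e-5, atol=1e-7)
        shuffled = m.predict(encs[::-1])
        np.testing.assert_allclose(shuffled[::-1], batch[:5], rtol=1e-5, atol=1e-7)

    @pytest.mark.parametrize("L", [3, 7, 15, 26, 40])
    @pytest.mark.parametrize("ablation", ["none", "no_position", "pure_cnn", "simple_pairing", "no_insert"])
    def test_shape_invariance(self, L, ablation):
        cfg = ModelConfig(L=L, d=8, d_ins=4, conv_filters=8, n_layers=1, n_heads=2, ablation=ablation)
        m = build_model(cfg, 0)
        out = m.predict(all_match_encodings(L, n=2))
        assert out.shape == (2,)
        assert np.isfinite(out).all()

    def test_length_mismatch_raises(self, tiny_config):
        m = build_model(tiny_config, 0)
        with pytest.raises(ValueError, match="length"):
            m.predict(all_match_encodings(tiny_config.L + 1, n=1))

    def test_gradients_exist_and_finite(self, tiny_benchmark, tiny_config):
        data, _ = tiny_benchmark
        m = build_model(tiny_config, 5)
        X, I = m.batch_inputs(data.encodings()[:6])
        Xt = Tensor(X, requires_grad=True)
        m.forward(Xt, Tensor(I)).sum().backward()
        assert Xt.grad is not None
        assert np.isfinite(Xt.grad).all()
        assert np.abs(Xt.grad).max() > 0


def independent_forward(m: InteractionRegressor, X: np.ndarray, I: np.ndarray) -> np.ndarray:
    """Plain-numpy re-implementation of the forward pass (the oracle)."""
    c = m.config
    p = {k: v.astype(np.float64) for k, v in m.state_dict().items()}
    h = X @ p["proj.W"] + p["proj.b"]
    if c.ablation != "no_position":
        h = h + p["pos"]
    # zero-padded correlation
    B, L, d = h.shape
    pad = (c.kernel - 1) // 2
    hp = np.pad(h, ((0, 0), (pad, pad), (0, 0)))
    conv = np.zeros((B, L, c.conv_filters))
    for i in range(L):
        conv[:, i, :] = np.einsum("bkc,ock->bo", hp[:, i : i + c.kernel, :], p["conv.W"])
    h = np.maximum(conv + p["conv.b"], 0.0)
    if c.ablation != "pure_cnn":
        for layer in range(c.n_layers):
            pre = f"block{layer}."
            def split(x):
                return x.reshape(B, L, c.n_heads, -1).transpose(0, 2, 1, 3)
            q = split(h @ p[pre + "q.W"] + p[pre + "q.b"])
            k = split(h @ p[pre + "k.W"] + p[pre + "k.b"])
            v = split(h @ p[pre + "v.W"] + p[pre + "v.b"])
            scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(q.shape[-1])
            a = np.exp(scores - scores.max(-1, keepdims=True))
            a /= a.sum(-1, keepdims=True)
            att = (a @ v).transpose(0, 2, 1, 3).reshape(B, L, -1)
            h = h + att @ p[pre + "o.W"] + p[pre + "o.b"]

            def ln(x, g, b):
                mu = x.mean(-1, keepdims=True)
                sd = np.sqrt(x.var(-1, keepdims=True) + 1e-5)
                return g * (x - mu) / sd + b
            h = ln(h, p[pre + "ln1.g"], p[pre + "ln1.b"])
            ff = np.maximum(h @ p[pre + "ff1.W"] + p[pre + "ff1.b"], 0.0) @ p[pre + "ff2.W"] + p[pre + "ff2.b"]
            h = ln(h + ff, p[pre + "ln2.g"], p[pre + "ln2.b"])
    flat = h.reshape(B, -1)
    if c.ablation != "no_insert":
        flat = np.concatenate([flat, I @ p["ins.W"] + p["ins.b"]], axis=1)
    hid = np.maximum(flat @ p["head1.W"] + p["head1.b"], 0.0)
    return (hid @ p["head2.W"] + p["head2.b"]).reshape(B)


@pytest.mark.parametrize("ablation", ["none", "pure_cnn", "no_position", "no_insert"])
def test_forward_matches_independent_numpy_oracle(ablation):
    """The full matrix chain agrees with a from-scratch numpy forward pass."""
    cfg = ModelConfig(L=5, d=4, d_ins=2, conv_filters=4, kernel=3, n_layers=2, n_heads=2,
                      ablation=ablation)
    with ad.use_dtype(np.float64):
        m = build_model(cfg, seed=9)
        data, _ = generate_benchmark(n_guides=2, seed=4, L=5)
        X, I = m.batch_inputs(data.encodings()[:7])
        ours = m.forward(Tensor(X), Tensor(I)).data
    theirs = independent_forward(m, X, I)
    np.testing.assert_allclose(ours, theirs, rtol=1e-10, atol=1e-12)


def test_hand_computed_tiny_chain():
    """Hand-set weights on the smallest config reproduce an explicit matrix chain."""
    cfg = ModelConfig(L=3, d=2, d_ins=2, conv_filters=2, kernel=1, n_layers=1, n_heads=1,
                      ablation="pure_cnn")
    with ad.use_dtype(np.float64):
        m = zeroed(build_model(cfg, 0))
        # h_i = [G_i,A, 0]; conv doubles channel 0; head sums positions
        m.proj.W.data[0, 0] = 1.0
        m.conv_w.data[0, 0, 0] = 2.0
        m.conv_b.data[:] = 1.0
        m.head1.W.data[0::2, 0] = 1.0  # channel 0 of every position
        m.head2.W.data[0, 0] = 0.5
        m.head2.b.data[:] = -0.25
        guide = GuideSequence("g", "AGA")
        enc = encode_interaction(guide, PairingSpec.all_match(3))
        pred = m.predict([enc])
    # per position: conv = 2*G_A + 1 -> [3, 1, 3]; also channel 1 = relu(0+1)=1
    # head1 sums channel 0 over positions = 7; pred = 0.5*7 - 0.25
    np.testing.assert_allclose(pred, [3.25])


def test_pure_cnn_perturbation_locality():
    """Without the attention stack, a perturbation at one position can only
    reach head-input entries within the convolution's receptive field."""
    from piwislice.autodiff import conv1d

    cfg = ModelConfig(L=10, d=4, d_ins=2, conv_filters=4, kernel=3, n_layers=1,
                      n_heads=2, ablation="pure_cnn")
    m = build_model(cfg, 0)
    data, _ = generate_benchmark(n_guides=2, seed=3, L=10)
    X, I = m.batch_inputs(data.encodings()[:3])

    def local_activations(Xarr):
        h = m.proj(Tensor(Xarr))
        h = h + m.pos
        return conv1d(h, m.conv_w, m.conv_b).relu().data

    base = local_activations(X)
    Xp = X.copy()
    Xp[:, 5, :] += 0.7
    pert = local_activations(Xp)
    changed = np.where(np.abs(pert - base).sum(axis=(0, 2)) > 0)[0]
    assert set(changed) <= {4, 5, 6}
    assert 5 in changed


class TestCheckpoint:
    def test_round_trip_bit_exact(self, tiny_config, tmp_path):
        m = build_model(tiny_config, 13)
        path = tmp_path / "model.npz"
        m.save(path, normalization=(1.5, 0.25))
        loaded, norm = InteractionRegressor.load(path)
        assert norm == (1.5, 0.25)
        assert loaded.config == m.config
        for (_, pa), (_, pb) in zip(m.named_parameters(), loaded.named_parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
        enc = all_match_encodings(tiny_config.L, n=2)
        np.testing.assert_array_equal(m.predict(enc), loaded.predict(enc))
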