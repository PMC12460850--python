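"""Contracts of the fused channel-attention block and the residual gate,
checked against straight-line transcriptions and against the trainable
layer implementations."""

import numpy as np
import pytest

from specfusenet.attention import (ECAConfig, SRGConfig, eca_branch,
                                   fuse_attention, fused_eca_forward,
                                   gap_descriptor, gmp_descriptor, srg_forward)
from specfusenet.autograd import Tensor
from specfusenet.nn import FusedECA, SpectralResidualGate


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))


class TestDescriptors:
    def test_gap_known(self):
        np.testing.assert_allclose(gap_descriptor([[1, 2, 3], [4, 5, 6]]), [2, 5])

    def test_gmp_known(self):
        np.testing.assert_allclose(gmp_descriptor([[1, 2, 3], [4, 5, 6]]), [3, 6])

    def test_constant_map(self):
        x = np.full((3, 7), 1.3)
        np.testing.assert_allclose(gap_descriptor(x), 1.3)
        np.testing.assert_allclose(gmp_descriptor(x), 1.3)

    def test_all_negative_max_stays_negative(self):
        assert gmp_descriptor([[-5.0, -2.0, -3.0]])[0] == -2.0

    def test_gmp_dominates_gap(self, rng):
        x = rng.normal(size=(6, 11))
        assert np.all(gmp_descriptor(x) >= gap_descriptor(x))

    def test_single_position(self):
        x = np.array([[2.0], [3.0]])
        np.testing.assert_allclose(gap_descriptor(x), [2.0, 3.0])


class TestEcaBranch:
    def test_center_one_kernel_zero_input(self):
        s = eca_branch(np.zeros(2), [0, 1, 0], 0.0)
        np.testing.assert_allclose(s, 0.5)

    def test_bias_only(self):
        s = eca_branch(np.zeros(4), np.zeros(5), 1.7)
        np.testing.assert_allclose(s, _sigmoid(1.7))

    def test_boxcar_sliding_sum(self):
        s = eca_branch(np.array([1.0, 2.0, 3.0]), np.ones(3), 0.0)
        np.testing.assert_allclose(s, _sigmoid([3.0, 6.0, 5.0]))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            eca_branch(np.zeros(3), np.ones(4))

    def test_output_strictly_in_unit_interval(self, rng):
        s = eca_branch(rng.normal(size=20) * 10, rng.normal(size=5), 0.3)
        assert np.all((s > 0) & (s < 1))


class TestFuseAttention:
    def test_elementwise_max(self):
        np.testing.assert_allclose(fuse_attention([0.2, 0.7], [0.5, 0.6]),
                                   [0.5, 0.7])

    def test_idempotent_and_dominant(self, rng):
        a, b = _sigmoid(rng.normal(size=(2, 9)))
        np.testing.assert_allclose(fuse_attention(a, a), a)
        fused = fuse_attention(a, b)
        assert np.all(fused >= a) and np.all(fused >= b)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fuse_attention([0.5], [0.5, 0.5])


def _literal_fused_eca(x, kg, bg, km, bm):
    """Independent transcription: pool, channel conv, sigmoid, max, rescale."""
    c, m = x.shape
    z_gap = x.mean(axis=1)
    z_gmp = x.max(axis=1)
    k = len(kg)
    pad = (k - 1) // 2

    def channel_conv(z, w, b):
        zp = np.concatenate([np.zeros(pad), z, np.zeros(pad)])
        return np.array([sum(w[j] * zp[i + j] for j in range(k))
                         for i in range(c)]) + b

    s = np.maximum(_sigmoid(channel_conv(z_gap, kg, bg)),
                   _sigmoid(channel_conv(z_gmp, km, bm)))
    return x * s[:, None]


class TestFusedEcaForward:
    def test_matches_literal_transcription(self, rng):
        cfg = ECAConfig(kernel_size=3)
        for _ in range(20):
            x = rng.normal(size=(3, 7))
            kg, km = rng.normal(size=(2, 3))
            bg, bm = rng.normal(size=2)
            got = fused_eca_forward(x, cfg, kg, bg, km, bm)
            want = _literal_fused_eca(x, kg, bg, km, bm)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_saturated_positive_bias_identity(self, rng):
        x = rng.normal(size=(4, 9))
        cfg = ECAConfig(kernel_size=5)
        y = fused_eca_forward(x, cfg, np.zeros(5), 50.0, np.zeros(5), 50.0)
        np.testing.assert_allclose(y, x, atol=1e-8)

    def test_saturated_negative_bias_annihilates(self, rng):
        x = rng.normal(size=(4, 9))
        cfg = ECAConfig(kernel_size=5)
        y = fused_eca_forward(x, cfg, np.zeros(5), -50.0, np.zeros(5), -50.0)
        np.testing.assert_allclose(y, 0.0, atol=1e-8)

    def test_plain_eca_skips_gmp_branch(self, rng):
        x = rng.normal(size=(5, 6))
        kg = rng.normal(size=3)
        got = fused_eca_forward(x, ECAConfig(3, fused=False), kg, 0.2)
        s = eca_branch(gap_descriptor(x), kg, 0.2)
        np.testing.assert_allclose(got, s[:, None] * x, atol=1e-12)

    def test_layer_agrees_with_reference(self, rng):
        """Autograd FusedECA layer == reference function, both variants."""
        for fused in (True, False):
            layer = FusedECA(5, np.random.default_rng(7), fused=fused)
            x = rng.normal(size=(2, 6, 12))
            out = layer(Tensor(x)).data
            for n in range(2):
                ref = fused_eca_forward(
                    x[n], ECAConfig(5, fused=fused),
                    layer.gap_weight.data.ravel(), float(layer.gap_bias.data[0]),
                    layer.gmp_weight.data.ravel(), float(layer.gmp_bias.data[0]))
                np.testing.assert_allclose(out[n], ref, atol=1e-6)

    def test_channel_permutation_equivariance_symmetric_kernel(self, rng):
        """With a symmetric channel kernel, permuting channels permutes the
        output when the permutation also reorders the descriptor sequence
        consistently (checked with the reversal permutation)."""
        x = rng.normal(size=(6, 8))
        w = np.array([0.3, 1.1, 0.3])
        cfg = ECAConfig(3)
        y = fused_eca_forward(x, cfg, w, 0.1, w, -0.2)
        y_rev = fused_eca_forward(x[::-1], cfg, w, 0.1, w, -0.2)
        np.testing.assert_allclose(y_rev, y[::-1], atol=1e-10)


def _literal_srg(x, r, w1, b1, w2, b2, w3, alpha):
    """Independent per-position transcription of the gated residual."""
    c, m = x.shape
    out = np.zeros_like(x)
    for i in range(m):
        v = np.concatenate([x[:, i], r[:, i]])
        h = v @ w1 + b1
        h = np.where(h >= 0, h, np.exp(np.minimum(h, 0)) - 1)  # ELU
        g = _sigmoid(((h @ w2 + b2) @ w3).item())
        out[:, i] = x[:, i] + alpha * float(g) * r[:, i]
    return out


def _srg_params(c, h, rng):
    return (rng.normal(size=(2 * c, h)) * 0.3, rng.normal(size=h) * 0.3,
            rng.normal(size=(h, c)) * 0.3, rng.normal(size=c) * 0.3,
            rng.normal(size=(c, 1)) * 0.3)


class TestSrgForward:
    def test_matches_literal_transcription(self, rng):
        cfg = SRGConfig(hidden_dim=6)
        for _ in range(20):
            x, r = rng.normal(size=(2, 4, 5))
            w1, b1, w2, b2, w3 = _srg_params(4, 6, rng)
            alpha = rng.normal()
            got = srg_forward(x, r, cfg, w1, b1, w2, b2, w3, alpha)
            want = _literal_srg(x, r, w1, b1, w2, b2, w3, alpha)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_alpha_zero_is_identity(self, rng):
        x, r = rng.normal(size=(2, 3, 7))
        w1, b1, w2, b2, w3 = _srg_params(3, 5, rng)
        out = srg_forward(x, r, SRGConfig(5), w1, b1, w2, b2, w3, 0.0)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_saturated_gate_is_plain_residual(self, rng):
        """Gate forced to 1 with alpha 1 reduces to x + r."""
        x, r = rng.normal(size=(2, 3, 7))
        w1 = np.zeros((6, 5))
        b1 = np.zeros(5)
        w2 = np.zeros((5, 3))
        b2 = np.ones(3) * 100.0
        w3 = np.ones((3, 1))
        out = srg_forward(x, r, SRGConfig(5), w1, b1, w2, b2, w3, 1.0)
        np.testing.assert_allclose(out, x + r, atol=1e-8)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            srg_forward(np.zeros((2, 3)), np.zeros((2, 4)), SRGConfig(4),
                        *_srg_params(2, 4, rng), 1.0)

    def test_lipschitz_bound_in_alpha(self, rng):
        """|x_hat - x| <= |alpha| * |r| elementwise since the gate is in (0,1)."""
        x, r = rng.normal(size=(2, 4, 6))
        w1, b1, w2, b2, w3 = _srg_params(4, 8, rng)
        for alpha in (-0.5, 0.25, 2.0):
            out = srg_forward(x, r, SRGConfig(8), w1, b1, w2, b2, w3, alpha)
            assert np.all(np.abs(out - x) <= abs(alpha) * np.abs(r) + 1e-12)

    def test_layer_agrees_with_reference(self, rng):
        layer = SpectralResidualGate(4, 6, np.random.default_rng(11))
        x, r = rng.normal(size=(2, 2, 4, 5))
        out = layer(Tensor(x), Tensor(r)).data
        for n in range(2):
            ref = srg_forward(x[n], r[n], SRGConfig(6),
                              layer.w1.data, layer.b1.data, layer.w2.data,
                              layer.b2.data, layer.w3.data,
                              float(layer.alpha.data))
            np.testing.assert_allclose(out[n], ref, atol=1e-6)

    def test_global_gate_variant_uses_mean_gate(self, rng):
        layer = SpectralResidualGate(3, 4, np.random.default_rng(5),
                                     global_gate=True)
        x, r = rng.normal(size=(2, 1, 3, 6))
        g = layer.gate(Tensor(x), Tensor(r)).data
        assert np.allclose(g, g[0, 0, 0])  # one scalar per sample


class TestLayerGradients:
    """Finite-difference checks of both blocks' parameter gradients."""

    def test_fused_eca_gradients(self, rng):
        from tests.test_autograd import numeric_grad
        layer = FusedECA(3, np.random.default_rng(3))
        x = rng.normal(size=(2, 4, 6))

        def loss_value():
            out = layer(Tensor(x))
            return float((out * out).sum().data)

        out = layer(Tensor(x))
        loss = (out * out).sum()
        loss.backward()
        for name, p in layer.named_parameters():
            num = numeric_grad(loss_value, p.data)
            scale = max(np.abs(num).max(), 1e-3)
            assert np.allclose(p.grad, num, atol=1e-4 * scale), name

    def test_srg_gradients(self, rng):
        from tests.test_autograd import numeric_grad
        layer = SpectralResidualGate(3, 4, np.random.default_rng(4))
        x, r = rng.normal(size=(2, 2, 3, 5))

        def loss_value():
            out = layer(Tensor(x), Tensor(r))
            return float((out * out).sum().data)

        out = layer(Tensor(x), Tensor(r))
        loss = (out * out).sum()
        loss.backward()
        for name, p in layer.named_parameters():
            num = numeric_grad(loss_value, p.data)
            scale = max(np.abs(num).max(), 1e-3)
            assert np.allclose(p.grad, num, atol=1e-4 * scale), name
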