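"""Generalized self-attention block: loop oracles, invariants, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurostage import attention
from neurostage.attention import (
    GSAConfig,
    channel_attention,
    fuse_head,
    fusion_scalar_gradients,
    gsa_forward,
    init_gsa,
    init_head,
    project_qkv,
    spatial_attention,
)
from neurostage.exceptions import ConfigError, ShapeError


@pytest.fixture
def instance(rng):
    Z = rng.normal(size=(2, 2, 8))
    heads, config = init_gsa(8, seed=42, heads=4)
    return Z, heads, config


def loop_projection(Z, weight, bias):
    h, w, c = Z.shape
    out = np.zeros((h * w, weight.shape[1]))
    for y in range(h):
        for x in range(w):
            for j in range(weight.shape[1]):
                out[y * w + x, j] = Z[y, x, :] @ weight[:, j] + bias[j]
    return out


class TestProjection:
    def test_zero_input_gives_bias_rows(self, instance):
        _, heads, _ = instance
        Q, K, V = project_qkv(np.zeros((2, 2, 8)), heads[0])
        assert np.allclose(Q, heads[0].query_bias)
        assert np.allclose(K, np.tile(heads[0].key_bias, (4, 1)))
        assert np.allclose(V, np.tile(heads[0].value_bias, (4, 1)))

    def test_single_pixel_pooling_identity(self, rng):
        Z = rng.normal(size=(1, 1, 8))
        params = init_head(8, rng)
        Q, _, _ = project_qkv(Z, params)
        single = Z[0, 0, :] @ params.query_proj + params.query_bias
        assert np.allclose(Q.ravel(), single)  # pooling over one element

    def test_matches_loop_oracle(self, instance):
        Z, heads, _ = instance
        params = heads[0]
        Q, K, V = project_qkv(Z, params)
        k_oracle = loop_projection(Z, params.key_proj, params.key_bias)
        v_oracle = loop_projection(Z, params.value_proj, params.value_bias)
        q_oracle = loop_projection(Z, params.query_proj, params.query_bias).mean(
            axis=0, keepdims=True
        )
        assert np.allclose(K, k_oracle, atol=1e-12)
        assert np.allclose(V, v_oracle, atol=1e-12)
        assert np.allclose(Q, q_oracle, atol=1e-12)


class TestSpatialAttention:
    def test_constant_logits_give_uniform_weights(self, rng):
        Z = rng.normal(size=(2, 3, 4))
        Q = np.zeros((1, 2))
        K = np.ones((6, 2))
        Z_sp, weights = spatial_attention(Q, K, Z)
        assert np.allclose(weights, 1.0 / 6.0)
        assert np.allclose(Z_sp, Z / 6.0)

    def test_dominant_logit_saturates(self, rng):
        Z = rng.normal(size=(2, 2, 3))
        Q = np.array([[1.0]])
        K = np.array([[1e4], [0.0], [0.0], [0.0]])
        Z_sp, weights = spatial_attention(Q, K, Z)
        assert weights[0] > 1 - 1e-10
        masked = np.zeros_like(Z)
        masked[0, 0, :] = Z[0, 0, :]
        assert np.allclose(Z_sp, masked, atol=1e-8)

    def test_matches_exp_normalize_oracle(self, instance):
        Z, heads, _ = instance
        Q, K, _ = project_qkv(Z, heads[0])
        Z_sp, weights = spatial_attention(Q, K, Z)
        logits = np.array([float(Q.ravel() @ K[r]) for r in range(4)])
        expected_w = np.exp(logits) / np.exp(logits).sum()
        expected_map = np.empty_like(Z)
        for y in range(2):
            for x in range(2):
                expected_map[y, x, :] = expected_w[y * 2 + x] * Z[y, x, :]
        assert np.allclose(weights, expected_w, atol=1e-10)
        assert np.allclose(Z_sp, expected_map, atol=1e-10)


class TestChannelAttention:
    def test_zero_preactivation_halves_map(self, rng):
        Z = rng.normal(size=(2, 2, 6))
        z_prime = np.full(4, 0.25)
        V = np.zeros((4, 2))
        expand = np.zeros((2, 6))
        Z_ch, gates = channel_attention(z_prime, V, expand, np.zeros(6), Z)
        assert np.allclose(gates, 0.5)
        assert np.allclose(Z_ch, Z / 2.0)

    def test_zero_map_annihilates(self, instance):
        Z, heads, _ = instance
        _, _, V = project_qkv(Z, heads[0])
        _, z_prime = spatial_attention(*project_qkv(Z, heads[0])[:2], Z)
        Z_ch, _ = channel_attention(
            z_prime, V, heads[0].channel_expand, heads[0].expand_bias, np.zeros_like(Z)
        )
        assert np.allclose(Z_ch, 0.0)

    def test_matches_matrix_sigmoid_oracle(self, instance):
        Z, heads, _ = instance
        params = heads[0]
        Q, K, V = project_qkv(Z, params)
        _, z_prime = spatial_attention(Q, K, Z)
        Z_ch, gates = channel_attention(
            z_prime, V, params.channel_expand, params.expand_bias, Z
        )
        summary = sum(z_prime[r] * V[r] for r in range(4))
        pre = summary @ params.channel_expand + params.expand_bias
        expected_gates = 1.0 / (1.0 + np.exp(-pre))
        assert np.allclose(gates, expected_gates, atol=1e-12)
        assert np.allclose(Z_ch, Z * expected_gates.reshape(1, 1, -1), atol=1e-12)


class TestFusion:
    def test_projection_and_annihilation(self, rng):
        a, b = rng.normal(size=(2, 3, 3, 4))
        assert np.allclose(fuse_head(a, b, 1.0, 0.0), a)
        assert np.allclose(fuse_head(a, b, 0.0, 0.0), 0.0)

    def test_convexity_on_equal_inputs(self, rng):
        a = rng.normal(size=(3, 3, 4))
        assert np.allclose(fuse_head(a, a.copy(), 0.5, 0.5), a)


def reference_gsa(Z, heads, config):
    """Fully looped reference of the whole block."""
    h, w, c = Z.shape
    fused = []
    for params in heads:
        flat = Z.reshape(h * w, c)
        q = (flat @ params.query_proj + params.query_bias).mean(axis=0)
        K = flat @ params.key_proj + params.key_bias
        V = flat @ params.value_proj + params.value_bias
        logits = K @ q
        weights = np.exp(logits - logits.max())
        weights /= weights.sum()
        Z_sp = Z * weights.reshape(h, w, 1)
        gates = 1.0 / (1.0 + np.exp(-(weights @ V @ params.channel_expand + params.expand_bias)))
        Z_ch = Z * gates.reshape(1, 1, c)
        fused.append(params.w1 * Z_sp + params.w2 * Z_ch)
    concat = np.concatenate(fused, axis=2).reshape(h * w, len(heads) * c)
    return (concat @ config.output_proj + config.output_bias).reshape(h, w, c)


class TestBlockForward:
    def test_single_head_identity_projection(self, rng):
        Z = rng.normal(size=(2, 2, 8))
        heads, config = init_gsa(8, seed=3, heads=1)
        config.output_proj = np.eye(8)
        config.output_bias = np.zeros(8)
        out, _ = gsa_forward(Z, heads, config)
        expected, *_ = attention.head_forward(Z, heads[0])
        assert np.allclose(out, expected)

    def test_matches_looped_reference(self, instance):
        Z, heads, config = instance
        out, _ = gsa_forward(Z, heads, config)
        assert np.allclose(out, reference_gsa(Z, heads, config), atol=1e-10)

    def test_head_count_mismatch_rejected(self, instance):
        Z, heads, config = instance
        with pytest.raises(ConfigError):
            gsa_forward(Z, heads[:2], config)

    @pytest.mark.parametrize("shape,h", [((1, 1, 1), 1), ((3, 5, 4), 2), ((2, 2, 16), 4)])
    def test_shape_preserved(self, rng, shape, h):
        Z = rng.normal(size=shape)
        heads, config = init_gsa(shape[2], seed=0, heads=h)
        out, diags = gsa_forward(Z, heads, config)
        assert out.shape == shape
        for w in diags.spatial_weights:
            assert w.shape == (shape[0] * shape[1],)

    def test_zero_input_zero_bias_gives_zero_output(self):
        heads, config = init_gsa(8, seed=5, heads=2)
        out, _ = gsa_forward(np.zeros((3, 3, 8)), heads, config)
        assert np.allclose(out, 0.0)


class TestInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        h=st.integers(1, 4),
        w=st.integers(1, 4),
        c=st.integers(1, 12),
    )
    def test_simplex_and_gate_ranges(self, seed, h, w, c):
        rng = np.random.default_rng(seed)
        Z = rng.normal(size=(h, w, c))
        heads, config = init_gsa(c, seed=seed, heads=2)
        _, diags = gsa_forward(Z, heads, config)
        for weights in diags.spatial_weights:
            assert np.all(weights >= 0)
            assert abs(weights.sum() - 1.0) < 1e-6
        for gates in diags.channel_gates:
            assert np.all(gates > 0) and np.all(gates < 1)

    def test_reduced_channels_floor(self):
        assert attention.reduced_channels(16) == 2
        assert attention.reduced_channels(8) == 1
        assert attention.reduced_channels(5) == 1  # degenerate C < divisor


class TestFusionGradients:
    def test_finite_difference_matches_analytic(self, instance):
        Z, heads, config = instance
        rng = np.random.default_rng(9)
        G = rng.normal(size=Z.shape)  # loss L = <G, output>

        def loss():
            out, _ = gsa_forward(Z, heads, config)
            return float(np.sum(G * out))

        dw1, dw2 = fusion_scalar_gradients(Z, heads, config, G)
        eps = 1e-6
        for i, params in enumerate(heads):
            for attr, analytic in (("w1", dw1[i]), ("w2", dw2[i])):
                orig = getattr(params, attr)
                setattr(params, attr, orig + eps)
                up = loss()
                setattr(params, attr, orig - eps)
                down = loss()
                setattr(params, attr, orig)
                fd = (up - down) / (2 * eps)
                assert abs(fd - analytic) <= 1e-4 * max(1.0, abs(fd))

    def test_grad_output_shape_checked(self, instance):
        Z, heads, config = instance
        with pytest.raises(ShapeError):
            fusion_scalar_gradients(Z, heads, config, np.zeros((3, 3, 8)))
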