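"""Fusion network contracts: affine alignment, the attention path against
an explicit step-by-step loop oracle, highway-gate semantics, and the
ordering of the concatenated fusion input."""

import numpy as np
import pytest

from synfuse.autograd import Tensor
from synfuse.fusion import (
    AlignedFeatureSet,
    AttentionPath,
    DualFusionNetwork,
    FusionConfig,
    HighwayPath,
    build_fusion_input,
)
from synfuse.nn import Linear


def loop_attention_oracle(l: np.ndarray, wq, wk, wv, wr, n_heads: int) -> np.ndarray:
    """Explicit per-head, per-token evaluation of the attention path:
    projections, scaled dot-product softmax, head concat, projected
    residual, ReLU. Pure loops, no vectorized shortcuts."""
    n_tok, d = l.shape
    dk = d // n_heads
    q_all, k_all, v_all = l @ wq, l @ wk, l @ wv
    attended = np.zeros((n_tok, d))
    for h in range(n_heads):
        sl = slice(h * dk, (h + 1) * dk)
        q, k, v = q_all[:, sl], k_all[:, sl], v_all[:, sl]
        for i in range(n_tok):
            scores = np.array([q[i] @ k[j] / np.sqrt(dk) for j in range(n_tok)])
            e = np.exp(scores - scores.max())
            w = e / e.sum()
            attended[i, sl] = sum(w[j] * v[j] for j in range(n_tok))
    out = attended + l @ wr
    return np.maximum(out, 0.0).reshape(-1)


def make_aligned(rng, d=4, batch=2) -> AlignedFeatureSet:
    return AlignedFeatureSet(*(Tensor(rng.normal(size=(batch, d))) for _ in range(5)))


class TestAlign:
    def test_identity_weights_pass_through(self, rng):
        lin = Linear(3, 3, rng)
        lin.W.data = np.eye(3)
        lin.b.data = np.zeros(3)
        x = rng.normal(size=(2, 3))
        np.testing.assert_allclose(lin(Tensor(x)).data, x)

    def test_zero_input_returns_bias(self, rng):
        lin = Linear(3, 2, rng)
        np.testing.assert_allclose(lin(Tensor(np.zeros((1, 3)))).data[0], lin.b.data)

    def test_matches_explicit_loop_product(self, rng):
        lin = Linear(3, 2, rng)
        x = rng.normal(size=3)
        expected = np.array(
            [sum(x[i] * lin.W.data[i, j] for i in range(3)) + lin.b.data[j]
             for j in range(2)]
        )
        np.testing.assert_allclose(lin(Tensor(x)).data, expected, atol=1e-12)

    def test_affine_superposition(self, rng):
        """g(x) - g(0) is linear: g(ax+by) - g(0) = a(g(x)-g(0)) + b(g(y)-g(0))."""
        lin = Linear(5, 4, rng)
        g = lambda v: lin(Tensor(v[None, :])).data[0]
        g0 = g(np.zeros(5))
        for _ in range(20):
            x, y = rng.normal(size=5), rng.normal(size=5)
            a, b = rng.normal(), rng.normal()
            lhs = g(a * x + b * y) - g0
            rhs = a * (g(x) - g0) + b * (g(y) - g0)
            np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestFusionInput:
    def test_concatenation_order(self):
        d = 2
        vecs = [Tensor(np.full((1, d), float(i + 1))) for i in range(5)]
        l = build_fusion_input(AlignedFeatureSet(*vecs))
        np.testing.assert_array_equal(
            l.flat.data[0], [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
        )

    def test_matrix_row_two_is_expression(self, rng):
        aligned = make_aligned(rng)
        l = build_fusion_input(aligned)
        np.testing.assert_array_equal(l.mat.data[:, 2, :], aligned.z.data)

    def test_flat_reshape_equals_matrix(self, rng):
        aligned = make_aligned(rng, d=3)
        l = build_fusion_input(aligned)
        np.testing.assert_array_equal(
            l.flat.data.reshape(-1, 5, 3), l.mat.data
        )

    def test_mixed_dimensions_rejected(self, rng):
        vecs = [Tensor(rng.normal(size=(1, 4))) for _ in range(4)]
        vecs.append(Tensor(rng.normal(size=(1, 3))))
        with pytest.raises(ValueError):
            build_fusion_input(AlignedFeatureSet(*vecs))


class TestAttentionPath:
    def test_zero_query_gives_uniform_attention(self, rng):
        path = AttentionPath(d=4, n_heads=1, rng=rng)
        path.wq.W.data[:] = 0.0
        mat = Tensor(rng.normal(size=(1, 5, 4)))
        _, weights, attended = path(mat, return_parts=True)
        np.testing.assert_allclose(weights.data, 0.2, atol=1e-12)
        v = mat.data[0] @ path.wv.W.data
        np.testing.assert_allclose(attended.data[0], np.tile(v.mean(axis=0), (5, 1)),
                                   atol=1e-12)

    def test_attention_rows_sum_to_one(self, rng):
        path = AttentionPath(d=8, n_heads=2, rng=rng)
        mat = Tensor(rng.normal(size=(3, 5, 8)))
        _, weights, _ = path(mat, return_parts=True)
        np.testing.assert_allclose(weights.data.sum(axis=-1), 1.0, atol=1e-6)
        assert (weights.data >= 0).all()

    def test_output_nonnegative_after_relu(self, rng):
        path = AttentionPath(d=8, n_heads=2, rng=rng)
        m_vec = path(Tensor(rng.normal(size=(4, 5, 8))))
        assert (m_vec.data >= 0).all()

    @pytest.mark.parametrize("d", [4, 8])
    def test_single_head_matches_loop_oracle(self, d, rng):
        path = AttentionPath(d=d, n_heads=1, rng=rng)
        for _ in range(100):
            l = rng.normal(size=(5, d))
            expected = loop_attention_oracle(
                l, path.wq.W.data, path.wk.W.data, path.wv.W.data,
                path.wr.W.data, n_heads=1,
            )
            got = path(Tensor(l[None])).data[0]
            np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_multi_head_matches_loop_oracle(self, rng):
        path = AttentionPath(d=8, n_heads=2, rng=rng)
        l = rng.normal(size=(5, 8))
        expected = loop_attention_oracle(
            l, path.wq.W.data, path.wk.W.data, path.wv.W.data,
            path.wr.W.data, n_heads=2,
        )
        np.testing.assert_allclose(path(Tensor(l[None])).data[0], expected, atol=1e-8)

    def test_heads_must_divide_dim(self, rng):
        with pytest.raises(ValueError):
            AttentionPath(d=6, n_heads=4, rng=rng)


class TestHighwayPath:
    def test_open_gate_passes_transform(self, rng):
        layer = HighwayPath(6, 1, rng).layers[0]
        layer.gate.b.data[:] = 1e4  # g -> 1
        x = Tensor(rng.normal(size=(2, 6)))
        out, _, t, _ = layer(x, return_parts=True)
        np.testing.assert_allclose(out.data, t.data, atol=1e-12)

    def test_closed_gate_passes_carry(self, rng):
        layer = HighwayPath(6, 1, rng).layers[0]
        layer.gate.b.data[:] = -1e4  # g -> 0
        x = Tensor(rng.normal(size=(2, 6)))
        out, _, _, q = layer(x, return_parts=True)
        np.testing.assert_allclose(out.data, q.data, atol=1e-12)

    def test_output_between_transform_and_carry(self, rng):
        """Each coordinate is a convex combination of t(l) and q(l)."""
        layer = HighwayPath(9, 1, rng).layers[0]
        for _ in range(50):
            x = Tensor(rng.normal(size=(3, 9)))
            out, g, t, q = layer(x, return_parts=True)
            lo = np.minimum(t.data, q.data) - 1e-12
            hi = np.maximum(t.data, q.data) + 1e-12
            assert (out.data >= lo).all() and (out.data <= hi).all()
            manual = g.data * t.data + (1 - g.data) * q.data
            np.testing.assert_allclose(out.data, manual, atol=1e-12)

    def test_depth_validation(self, rng):
        with pytest.raises(ValueError):
            HighwayPath(4, 0, rng)


class TestDualFusionNetwork:
    def make_net(self, **flags):
        cfg = FusionConfig(d=8, n_heads=2, dropout_p=0.1, **flags)
        return DualFusionNetwork(cfg, n_bits=32, n_genes=10, d_smiles=12)

    def inputs(self, rng, b=3):
        return (rng.integers(0, 2, (b, 32)).astype(float),
                rng.integers(0, 2, (b, 32)).astype(float),
                rng.normal(size=(b, 10)), rng.normal(size=(b, 12)),
                rng.normal(size=(b, 12)))

    def test_output_shapes_and_probability_range(self, rng):
        net = self.make_net()
        out = net(*self.inputs(rng))
        assert out.m_vec.shape == out.m_bit.shape == out.m_x.shape == (3, 40)
        assert ((out.prob.data > 0) & (out.prob.data < 1)).all()
        np.testing.assert_allclose(out.m_x.data, out.m_vec.data + out.m_bit.data)

    def test_eval_mode_deterministic(self, rng):
        net = self.make_net()
        args = self.inputs(rng)
        np.testing.assert_array_equal(net(*args).prob.data, net(*args).prob.data)

    @pytest.mark.parametrize("flag,part", [
        ("no_attention", "m_vec"), ("no_highway", "m_bit"),
    ])
    def test_path_ablation_zeroes_branch(self, flag, part, rng):
        net = self.make_net(**{flag: True})
        out = net(*self.inputs(rng))
        assert np.all(getattr(out, part).data == 0.0)

    def test_input_ablations_ignore_that_input(self, rng):
        args = list(self.inputs(rng))
        net = self.make_net(no_fingerprint=True)
        base = net(*args).prob.data
        args2 = list(args)
        args2[0] = np.zeros_like(args[0])
        args2[1] = np.ones_like(args[1])
        np.testing.assert_array_equal(net(*args2).prob.data, base)

    def test_layernorm_normalizes_before_affine(self, rng):
        net = self.make_net()
        m_x = Tensor(rng.normal(size=(4, 40)))
        normed = net.head.norm.normalized(m_x).data
        np.testing.assert_allclose(normed.mean(axis=-1), 0.0, atol=1e-5)
        np.testing.assert_allclose(normed.var(axis=-1), 1.0, atol=1e-3)

    def test_double_ablation_rejected(self):
        with pytest.raises(ValueError):
            self.make_net(no_attention=True, no_highway=True)
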