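"""Forward-pass stages and the assembled network."""

import numpy as np
import pytest

from citegraph.model import (
    ModelConfig,
    build_nodes,
    encode_rna,
    forward,
    forward_t,
    init_params,
    predict_abundance,
    prelu,
    propagate,
)
from citegraph.training import _mse_loss_t
from _oracle import oracle_forward


class TestPrelu:
    def test_values(self):
        assert prelu(3.0) == 3.0
        assert prelu(-4.0) == -1.0
        assert prelu(0.0) == 0.0

    def test_elementwise(self):
        x = np.array([-2.0, 0.5])
        np.testing.assert_allclose(prelu(x), [-0.5, 0.5])


class TestEncodeRNA:
    def test_hand_computed_toy(self):
        # 2 -> 3 -> 2 with unit weights; PReLU only bites on negatives
        w1 = np.ones((2, 3))
        b1 = np.array([-5.0, 0.0, 1.0])
        w2 = np.ones((3, 2))
        b2 = np.zeros(2)
        x = np.array([[1.0, 2.0]])
        # pre-activations [-2, 3, 4] -> prelu -> [-0.5, 3, 4], sum = 6.5
        np.testing.assert_allclose(encode_rna(x, w1, b1, w2, b2), [[6.5, 6.5]])

    def test_zero_input_zero_weights(self):
        out = encode_rna(np.zeros((2, 4)), np.zeros((4, 3)), np.zeros(3),
                         np.zeros((3, 2)), np.zeros(2))
        np.testing.assert_array_equal(out, 0)

    def test_default_width_is_128(self):
        cfg = ModelConfig(n_genes=30, n_proteins=3, use_prior=False)
        params = init_params(cfg, np.random.default_rng(0))
        out = encode_rna(
            np.zeros((2, 30)),
            params["enc1_W"].data, params["enc1_b"].data,
            params["enc2_W"].data, params["enc2_b"].data,
        )
        assert out.shape == (2, 128)

    def test_gene_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            encode_rna(np.zeros((1, 5)), np.zeros((4, 3)), np.zeros(3),
                       np.zeros((3, 2)), np.zeros(2))


class TestBuildNodes:
    @pytest.mark.parametrize("n,d_k,d", [(10, 320, 384), (13, 416, 480)])
    def test_published_node_widths(self, n, d_k, d):
        d_r, h2, b = 64, 8, 2
        rng = np.random.default_rng(0)
        nodes = build_nodes(
            rng.normal(size=(b, h2)),
            rng.normal(size=(h2, n * d_r)),
            rng.normal(size=(n * d_r,)),
            rng.normal(size=(n, d_k)),
        )
        assert nodes.shape == (b, n, d)

    def test_zero_rep_zero_bias_leaves_knowledge_rows(self):
        n, d_r, d_k, h2 = 3, 2, 4, 5
        vk = np.arange(n * d_k, dtype=float).reshape(n, d_k)
        nodes = build_nodes(
            np.zeros((2, h2)), np.zeros((h2, n * d_r)), np.zeros(n * d_r), vk
        )
        np.testing.assert_array_equal(nodes[..., :d_r], 0)
        for c in range(2):
            np.testing.assert_array_equal(nodes[c, :, d_r:], vk)

    def test_knowledge_block_constant_across_cells(self):
        rng = np.random.default_rng(1)
        n, d_r, d_k, h2 = 4, 3, 8, 6
        nodes = build_nodes(
            rng.normal(size=(5, h2)),
            rng.normal(size=(h2, n * d_r)),
            rng.normal(size=(n * d_r,)),
            rng.normal(size=(n, d_k)),
        )
        for c in range(1, 5):
            np.testing.assert_array_equal(nodes[c, :, d_r:], nodes[0, :, d_r:])


class TestPropagate:
    def test_zero_adjacency_or_relation_gives_half(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(3, 4))
        np.testing.assert_allclose(propagate(v, np.zeros((3, 3)), np.eye(4)), 0.5)
        np.testing.assert_allclose(propagate(v, np.eye(3), np.zeros((4, 4))), 0.5)

    def test_hand_case(self):
        v = np.array([[0.0, 0.0], [1.0, -1.0]])
        out = propagate(v, np.eye(2), np.eye(2))
        sig = lambda x: 1 / (1 + np.exp(-x))
        np.testing.assert_allclose(out, [[0.5, 0.5], [sig(1), sig(-1)]])

    def test_output_in_open_unit_interval_and_same_shape(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(5, 6))
        out = propagate(v, rng.normal(size=(5, 5)), rng.normal(size=(6, 6)))
        assert out.shape == v.shape
        assert ((out > 0) & (out < 1)).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="non-conforming"):
            propagate(np.zeros((3, 4)), np.zeros((2, 2)), np.eye(4))


class TestPredictor:
    def test_negative_bias_reaches_negative_output(self):
        out = predict_abundance(np.zeros((3, 4)), np.zeros((4, 1)), np.array([-2.0]))
        np.testing.assert_allclose(out, np.full(3, -0.5))

    def test_positive_branch_is_identity(self):
        out = predict_abundance(np.zeros((3, 4)), np.zeros((4, 1)), np.array([2.0]))
        np.testing.assert_allclose(out, np.full(3, 2.0))


class TestForward:
    def test_matches_straight_line_oracle(self, tiny_instance):
        config, params, priors, x = tiny_instance
        ours = forward(x, params, config, priors)
        expected = oracle_forward(
            x, priors, {k: t.data for k, t in params.items()},
            d_r=config.d_r, d_c=config.d_c, slope=config.prelu_slope,
        )
        np.testing.assert_allclose(ours, expected, atol=1e-10)

    def test_batch_invariance(self, tiny_instance):
        config, params, priors, x = tiny_instance
        full = forward(x, params, config, priors)
        single = forward(x[2:3], params, config, priors)
        np.testing.assert_allclose(single[0], full[2], atol=1e-12)

    def test_all_zero_parameters_predict_zero(self, tiny_instance):
        config, params, priors, x = tiny_instance
        zeroed = {k: type(t)(np.zeros_like(t.data)) for k, t in params.items()}
        np.testing.assert_array_equal(forward(x, zeroed, config, priors), 0)

    def test_every_parameter_receives_gradient(self, tiny_instance):
        config, params, priors, x = tiny_instance
        y = np.random.default_rng(0).normal(size=(x.shape[0], config.n_proteins))
        loss = _mse_loss_t(y, forward_t(x, params, config, priors))
        loss.backward()
        for name, p in params.items():
            assert p.grad is not None and np.any(p.grad != 0), name

    def test_missing_priors_rejected(self, tiny_instance):
        config, params, _, x = tiny_instance
        with pytest.raises(ValueError, match="priors"):
            forward(x, params, config, None)

    def test_no_prior_variant_runs(self):
        cfg = ModelConfig(n_genes=6, n_proteins=3, hidden=(4, 3), d_r=2,
                          use_prior=False)
        params = init_params(cfg, np.random.default_rng(0))
        out = forward(np.zeros((2, 6)), params, cfg)
        assert out.shape == (2, 3)

    def test_per_protein_predictor_variant(self):
        cfg = ModelConfig(n_genes=6, n_proteins=3, hidden=(4, 3), d_r=2,
                          use_prior=False, per_protein_predictor=True)
        params = init_params(cfg, np.random.default_rng(0))
        assert forward(np.zeros((2, 6)), params, cfg).shape == (2, 3)

    def test_adjacency_mask_restricts_support(self):
        mask = np.eye(3)
        cfg = ModelConfig(n_genes=6, n_proteins=3, hidden=(4, 3), d_r=2,
                          use_prior=False, adjacency_mask=mask)
        params = init_params(cfg, np.random.default_rng(0))
        # with a diagonal mask, zeroing off-diagonal A must not change output
        base = forward(np.ones((1, 6)), params, cfg)
        params["A"].data[0, 1] = 99.0
        np.testing.assert_allclose(forward(np.ones((1, 6)), params, cfg), base)
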