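"""Unit and oracle tests for the trainable stages and their gradients."""

import math

import numpy as np
import pytest

from mdapred import nn


class TestConvFuse:
    def test_output_shape(self, rng):
        channels = rng.random((6, 10, 10))
        w = rng.standard_normal((60, 4))
        out = nn.conv_fuse(channels, w, np.zeros(4))
        assert out.shape == (10, 4)

    def test_zero_tensor_zero_bias_gives_zero(self, rng):
        w = rng.standard_normal((12, 3))
        assert not nn.conv_fuse(np.zeros((2, 6, 6)), w, np.zeros(3)).any()

    def test_one_hot_kernel_selects_column(self, rng):
        channels = rng.random((1, 5, 5))
        w = np.zeros((5, 1))
        w[3, 0] = 1.0  # pick feature column 3 of the single channel
        bias = np.array([0.25])
        out = nn.conv_fuse(channels, w, bias)
        assert np.allclose(out[:, 0], channels[0][:, 3] + 0.25)

    def test_linear_in_input(self, rng):
        channels = rng.random((2, 4, 4))
        w = rng.standard_normal((8, 3))
        b = np.zeros(3)
        assert np.allclose(nn.conv_fuse(3 * channels, w, b), 3 * nn.conv_fuse(channels, w, b))

    def test_channel_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            nn.conv_fuse(rng.random((2, 4, 4)), rng.standard_normal((9, 3)), np.zeros(3))


class TestConcatStructure:
    def test_width_is_sum_of_blocks(self, rng):
        out = nn.concat_structure([rng.random((5, 5)), rng.random((5, 5))], rng.random((5, 3)))
        assert out.shape == (5, 13)

    def test_no_high_order_block(self, rng):
        out = nn.concat_structure([rng.random((5, 5)), rng.random((5, 5))], None)
        assert out.shape == (5, 10)

    def test_zero_high_order_leaves_first_order_unchanged(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4))
        out = nn.concat_structure([a, b], np.zeros((4, 2)))
        assert np.allclose(out[:, :8], np.hstack([a, b]))

    def test_node_count_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            nn.concat_structure([rng.random((4, 4))], rng.random((5, 2)))


def test_transform_nodes_matches_blockwise_products(rng):
    x_m, y_d = rng.random((3, 6)), rng.random((2, 4))
    w_m, w_d = rng.standard_normal((6, 5)), rng.standard_normal((4, 5))
    h = nn.transform_nodes(x_m, y_d, w_m, w_d)
    assert np.allclose(h[:3], x_m @ w_m)
    assert np.allclose(h[3:], y_d @ w_d)


class TestAttentionAggregate:
    def test_single_neighbor_passes_through_activation(self, rng):
        h = rng.standard_normal((2, 3))
        adj = np.array([[0, 1], [1, 0]])
        out = nn.attention_aggregate(h, adj, activation="elu")
        expected = np.where(h > 0, h, np.expm1(np.minimum(h, 0)))
        assert np.allclose(out[0], expected[1])
        assert np.allclose(out[1], expected[0])

    def test_equal_scores_give_half_half(self):
        h = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        adj = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]])
        _, cache = nn.attention_aggregate(h, adj, return_cache=True)
        assert np.allclose(cache["coef"][0], [0.0, 0.5, 0.5])

    def test_matches_bruteforce_enumeration(self, rng):
        h = rng.standard_normal((3, 4))
        adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        slope = 0.2
        out, cache = nn.attention_aggregate(h, adj, slope, "elu", return_cache=True)
        for i in range(3):
            nbrs = [j for j in range(3) if adj[i, j]]
            raw = {j: h[i] @ h[j] for j in nbrs}
            e = {j: r if r > 0 else slope * r for j, r in raw.items()}
            denom = sum(math.exp(v) for v in e.values())
            agg = sum(math.exp(e[j]) / denom * h[j] for j in nbrs)
            expected = np.where(agg > 0, agg, np.expm1(np.minimum(agg, 0)))
            assert np.allclose(out[i], expected, atol=1e-12)
            assert np.allclose(
                [cache["coef"][i, j] for j in nbrs],
                [math.exp(e[j]) / denom for j in nbrs],
            )

    def test_coefficients_sum_to_one_over_neighbors(self, rng):
        h = rng.standard_normal((6, 3))
        adj = (rng.random((6, 6)) < 0.5).astype(int)
        adj = ((adj + adj.T) > 0).astype(int)
        np.fill_diagonal(adj, 0)
        _, cache = nn.attention_aggregate(h, adj, return_cache=True)
        sums = cache["coef"].sum(axis=1)
        has_nbr = adj.sum(axis=1) > 0
        assert np.allclose(sums[has_nbr], 1.0, atol=1e-6)

    def test_isolated_node_gets_zero(self, rng):
        h = rng.standard_normal((3, 2))
        adj = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        out = nn.attention_aggregate(h, adj)
        assert not out[2].any()


class TestNeuralAggregate:
    def test_zero_weights_give_zero(self, rng):
        h, h_n = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        z = nn.neural_aggregate(h, h_n, np.zeros((6, 3)), np.zeros(3), np.zeros((3, 3)), np.zeros(3))
        assert not z.any()

    def test_additive_branch_identity(self, rng):
        h = rng.standard_normal((4, 3))
        z = nn.neural_aggregate(
            h, np.zeros_like(h), np.zeros((6, 3)), np.zeros(3), np.eye(3), np.zeros(3)
        )
        assert np.allclose(z[:, 3:], h)

    def test_matches_hand_assembled_affine_maps(self, rng):
        h, h_n = rng.standard_normal((5, 2)), rng.standard_normal((5, 2))
        w1, b1 = rng.standard_normal((4, 2)), rng.standard_normal(2)
        w2, b2 = rng.standard_normal((2, 2)), rng.standard_normal(2)
        z = nn.neural_aggregate(h, h_n, w1, b1, w2, b2)
        assert np.allclose(z, np.hstack([np.hstack([h, h_n]) @ w1 + b1, (h + h_n) @ w2 + b2]))


class TestMultiHeadConcat:
    def test_single_head_is_identity(self, rng):
        z = rng.standard_normal((5, 4))
        z_m, z_d = nn.multi_head_concat([z], 3)
        assert np.allclose(np.vstack([z_m, z_d]), z)

    def test_final_width(self, rng):
        heads = [rng.standard_normal((6, 512)) for _ in range(2)]
        z_m, z_d = nn.multi_head_concat(heads, 4)
        assert z_m.shape == (4, 1024) and z_d.shape == (2, 1024)

    def test_permuting_heads_permutes_column_blocks(self, rng):
        a, b = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        z1 = np.hstack([a, b])
        z_m, z_d = nn.multi_head_concat([b, a], 2)
        assert np.allclose(np.vstack([z_m, z_d]), np.hstack([b, a]))
        assert np.allclose(np.hstack([z1[:, 3:], z1[:, :3]]), np.vstack([z_m, z_d]))


class TestDecoder:
    def test_zero_embeddings_score_half(self):
        assert np.allclose(nn.decode(np.zeros((3, 4)), np.zeros((2, 4))), 0.5)

    def test_orthogonal_rows_score_half(self):
        z_m = np.array([[1.0, 0.0]])
        z_d = np.array([[0.0, 1.0]])
        assert np.allclose(nn.decode(z_m, z_d), 0.5)

    def test_hand_computed_two_by_two(self):
        z_m = np.array([[1.0, 2.0], [0.5, -1.0]])
        z_d = np.array([[1.0, 0.0], [-1.0, 1.0]])
        logits = z_m @ z_d.T
        assert np.allclose(nn.decode(z_m, z_d), 1 / (1 + np.exp(-logits)))

    def test_scores_strictly_inside_unit_interval(self, rng):
        scores = nn.decode(rng.standard_normal((5, 3)), rng.standard_normal((4, 3)))
        assert np.all((scores > 0) & (scores < 1))


class TestBceLoss:
    @pytest.mark.parametrize("p,y,expected", [
        (0.5, 1, math.log(2)),
        (0.5, 0, math.log(2)),
        (0.9, 1, -math.log(0.9)),
    ])
    def test_closed_form_values(self, p, y, expected):
        assert nn.bce_loss(np.array([p]), np.array([y])) == pytest.approx(expected)

    def test_clamping_keeps_loss_finite(self):
        assert np.isfinite(nn.bce_loss(np.array([0.0, 1.0]), np.array([1, 0])))


def micro_problem(rng, variant="full", n_heads=2, f_tran=3, c_out=2):
    """A 4-miRNA / 2-disease instance with random fixed inputs."""
    nm, nd = 4, 2
    k = 2
    adj = np.zeros((nm + nd, nm + nd), dtype=bool)
    a = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
    adj[:nm, nm:] = a
    adj[nm:, :nm] = a.T
    inputs = {
        "fo_m": rng.random((nm, 2 * nm)),
        "fo_d": rng.random((nd, 2 * nd)),
        "adjacency": adj,
        "xflat_m": rng.random((nm, k * nm)),
        "xflat_d": rng.random((nd, k * nd)),
        "c_in_m": k,
        "c_in_d": k,
    }
    params = nn.init_params(rng, nm, nd, k, k, 2 * nm, 2 * nd, c_out, f_tran, n_heads, variant)
    pairs = (np.array([0, 1, 2, 3, 2]), np.array([0, 1, 0, 0, 1]))
    labels = np.array([1.0, 1.0, 1.0, 0.0, 1.0])
    return params, inputs, pairs, labels


class TestForwardAndGradients:
    def test_forward_deterministic(self, rng):
        params, inputs, _, _ = micro_problem(rng)
        a = nn.forward(params, inputs, n_heads=2)
        b = nn.forward(params, inputs, n_heads=2)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("variant", ["full", "no_high_order", "plain_gat"])
    def test_numerical_vs_analytic_gradients(self, rng, variant):
        """Finite differences agree with backprop on a 6-node instance."""
        params, inputs, pairs, labels = micro_problem(rng, variant)
        _, grads = nn.loss_and_grads(params, inputs, pairs, labels, 2, variant)
        eps = 1e-6
        check_rng = np.random.default_rng(7)
        checked = 0
        keys = sorted(params)
        while checked < 10:
            key = keys[checked % len(keys)]
            p = params[key]
            idx = tuple(check_rng.integers(s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = nn.loss_and_grads(params, inputs, pairs, labels, 2, variant)
            p[idx] = orig - eps
            lm, _ = nn.loss_and_grads(params, inputs, pairs, labels, 2, variant)
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[key][idx]
            rel = abs(numeric - analytic) / max(abs(numeric) + abs(analytic), 1e-10)
            assert rel < 1e-4, f"{key}{idx}: numeric {numeric} vs analytic {analytic}"
            checked += 1

    def test_plain_gat_consistent_with_neutralised_full_model(self, rng):
        """With W_1 passing h_N through and branch 2 zeroed, the full
        aggregator reduces to the standard attention output."""
        f_tran = 3
        params, inputs, _, _ = micro_problem(rng, "full", n_heads=1, f_tran=f_tran)
        # branch 1 reproduces h_N, branch 2 silenced
        params["h0_w1"] = np.vstack([np.zeros((f_tran, f_tran)), np.eye(f_tran)])
        params["h0_b1"] = np.zeros(f_tran)
        params["h0_w2"] = np.zeros((f_tran, f_tran))
        params["h0_b2"] = np.zeros(f_tran)
        full_logits = nn.forward(params, inputs, 1, "full")

        gat_params = {k: v for k, v in params.items() if not k.startswith("h0_w1")
                      and not k.startswith("h0_b1") and not k.startswith("h0_w2")
                      and not k.startswith("h0_b2")}
        gat_params["h0_w1"] = np.hstack([np.eye(f_tran), np.zeros((f_tran, f_tran))])
        gat_params["h0_b1"] = np.zeros(2 * f_tran)
        gat_logits = nn.forward(gat_params, inputs, 1, "plain_gat")
        assert np.allclose(full_logits, gat_logits, atol=1e-12)
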