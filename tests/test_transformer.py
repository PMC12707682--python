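"""Dimension-aligned encoder, prediction heads, multi-task loss, full forward."""

import numpy as np
import pytest

from permawell import (
    AttentionProfile,
    EncoderDims,
    alignment_matrix,
    build_topology_set,
    default_prior,
    encoder_forward,
    forward_full,
    init_encoder_params,
    init_head_params,
    init_model_params,
    loss_total,
    predict_heads,
)
from permawell.relational_gnn import GnnDims

DIMS = EncoderDims(layers=2, width=16, heads=3, head_width=4, ffn_width=32, dropout=0.1)


def np_layer_norm(x, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


def np_gelu(v):
    return 0.5 * v * (1 + np.tanh(np.sqrt(2 / np.pi) * (v + 0.044715 * v**3)))


class TestEncoder:
    def test_identical_tokens_give_uniform_attention(self, rng):
        params = init_encoder_params(DIMS, seed=0)
        token = rng.normal(size=16)
        tokens = np.tile(token, (4, 5, 1))
        _, profile = encoder_forward(tokens, params)
        np.testing.assert_allclose(profile.maps, 0.2, atol=1e-12)

    def test_attention_rows_sum_to_one(self, rng):
        params = init_encoder_params(DIMS, seed=1)
        tokens = rng.normal(size=(3, 5, 16))
        _, profile = encoder_forward(tokens, params)
        np.testing.assert_allclose(profile.maps.sum(axis=-1), 1.0, atol=1e-6)

    def test_wrong_token_count_rejected(self, rng):
        params = init_encoder_params(DIMS, seed=1)
        with pytest.raises(ValueError, match="5 PERMA tokens"):
            encoder_forward(rng.normal(size=(2, 4, 16)), params)

    def test_single_layer_matches_manual_computation(self, rng):
        dims = EncoderDims(layers=1, width=16, heads=3, head_width=4, ffn_width=32)
        params = init_encoder_params(dims, seed=2)
        tokens = rng.normal(size=(1, 5, 16))
        out, profile = encoder_forward(tokens, params)

        layer = params.layers[0]
        x = tokens[0]
        normed = np_layer_norm(x) * layer.ln1_gain.data + layer.ln1_bias.data
        heads = []
        for h in range(3):
            q = normed @ layer.w_q[h].data
            k = normed @ layer.w_k[h].data
            v = normed @ layer.w_v[h].data
            logits = q @ k.T / np.sqrt(4)
            attn = np.exp(logits - logits.max(axis=-1, keepdims=True))
            attn /= attn.sum(axis=-1, keepdims=True)
            np.testing.assert_allclose(profile.maps[0, h], attn, atol=1e-8)
            heads.append(attn @ v)
        x = x + np.concatenate(heads, axis=-1) @ layer.w_o.data
        normed = np_layer_norm(x) * layer.ln2_gain.data + layer.ln2_bias.data
        hidden = np_gelu(normed @ layer.ffn_in.data + layer.ffn_in_bias.data)
        x = x + hidden @ layer.ffn_out.data + layer.ffn_out_bias.data
        np.testing.assert_allclose(np.asarray(out)[0], x, atol=1e-8)

    def test_eval_mode_is_deterministic_train_mode_is_not(self, rng):
        params = init_encoder_params(DIMS, seed=3)
        tokens = rng.normal(size=(2, 5, 16))
        a, _ = encoder_forward(tokens, params)
        b, _ = encoder_forward(tokens, params)
        np.testing.assert_array_equal(np.asarray(a), np.asarray(b))
        t1, _ = encoder_forward(tokens, params, train_mode=True, rng=np.random.default_rng(0))
        t2, _ = encoder_forward(tokens, params, train_mode=True, rng=np.random.default_rng(1))
        assert not np.array_equal(np.asarray(t1), np.asarray(t2))


class TestPredictHeads:
    def test_zero_pool_zero_bias_gives_half(self):
        heads = init_head_params(width=16, seed=0)
        bundle, _, _ = predict_heads(np.zeros((3, 5, 16)), heads)
        np.testing.assert_allclose(bundle.wellbeing_pred, 0.5, atol=1e-15)
        np.testing.assert_allclose(bundle.perma_pred, 0.5, atol=1e-15)

    def test_large_positive_bias_saturates_toward_one(self):
        heads = init_head_params(width=16, seed=0)
        heads.w_wellbeing.data = np.zeros_like(heads.w_wellbeing.data)
        heads.b_wellbeing.data = np.array([30.0])
        bundle, _, _ = predict_heads(np.zeros((2, 5, 16)), heads)
        assert np.all(bundle.wellbeing_pred > 1 - 1e-9) and np.all(bundle.wellbeing_pred < 1)

    def test_matches_pool_affine_sigmoid_oracle(self, rng):
        heads = init_head_params(width=16, seed=1)
        encoded = rng.normal(size=(4, 5, 16))
        bundle, _, _ = predict_heads(encoded, heads)
        pooled = encoded.mean(axis=1)
        sig = lambda v: 1 / (1 + np.exp(-v))
        np.testing.assert_allclose(
            bundle.wellbeing_pred,
            sig(pooled @ heads.w_wellbeing.data[:, 0] + heads.b_wellbeing.data[0]),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            bundle.perma_pred, sig(pooled @ heads.w_perma.data + heads.b_perma.data), atol=1e-12
        )

    def test_predictions_strictly_inside_unit_interval(self, rng):
        heads = init_head_params(width=16, seed=2)
        bundle, _, _ = predict_heads(rng.normal(size=(10, 5, 16)) * 5, heads)
        assert np.all(bundle.wellbeing_pred > 0) and np.all(bundle.wellbeing_pred < 1)
        assert np.all(bundle.perma_pred > 0) and np.all(bundle.perma_pred < 1)


class TestLoss:
    def test_perfect_consistent_predictions_zero_loss(self):
        perma = np.full((4, 5), 0.5)  # dyadic value: the row mean is exact
        y = perma.mean(axis=1)
        loss = loss_total(y, perma, y, perma)
        assert loss.as_floats() == {"wellbeing": 0.0, "perma": 0.0, "consistency": 0.0, "total": 0.0}

    def test_maximal_consistency_gap_is_one(self):
        y_hat = np.ones(3)
        perma_hat = np.zeros((3, 5))
        loss = loss_total(y_hat, perma_hat, np.ones(3), np.zeros((3, 5)))
        assert float(loss.l_consistency) == pytest.approx(1.0)

    def test_reference_lambdas_combine_unit_components(self):
        # constructed inputs with every component loss equal to 1
        y_hat, y = np.zeros(2), np.ones(2)           # wellbeing MSE = 1
        perma_hat, perma = np.zeros((2, 5)), np.ones((2, 5))  # perma MSE = 1
        # consistency: |0 - mean(0)| = 0 -> force it via y_hat = 1, perma_hat = 0
        loss = loss_total(np.ones(2), np.zeros((2, 5)), np.zeros(2), np.ones((2, 5)))
        assert float(loss.l_wellbeing) == 1.0
        assert float(loss.l_perma) == 1.0
        assert float(loss.l_consistency) == 1.0
        assert float(loss.l_total) == pytest.approx(1.0 + 0.8 + 0.5)

    def test_linear_combination_identity(self, rng):
        y_hat = rng.uniform(0, 1, 6)
        perma_hat = rng.uniform(0, 1, (6, 5))
        y = rng.uniform(0, 1, 6)
        perma = rng.uniform(0, 1, (6, 5))
        lambdas = (0.7, 0.2, 1.3)
        loss = loss_total(y_hat, perma_hat, y, perma, lambdas=lambdas)
        expected = (
            lambdas[0] * float(loss.l_wellbeing)
            + lambdas[1] * float(loss.l_perma)
            + lambdas[2] * float(loss.l_consistency)
        )
        assert float(loss.l_total) == pytest.approx(expected, abs=1e-9)

    def test_missing_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="label"):
            loss_total(rng.uniform(0, 1, 3), rng.uniform(0, 1, (3, 5)), None, None)


class TestAlignment:
    def test_identical_tokens_give_uniform_alignment(self, rng):
        params = init_encoder_params(DIMS, seed=0)
        tokens = np.tile(rng.normal(size=16), (3, 5, 1))
        _, profile = encoder_forward(tokens, params)
        np.testing.assert_allclose(alignment_matrix(profile), 0.2, atol=1e-12)

    def test_concentrated_profile_gives_identity(self):
        maps = np.zeros((2, 5, 5, 5))
        for h in range(5):
            maps[:, h, :, h] = 1.0
        profile = AttentionProfile(maps)
        np.testing.assert_array_equal(alignment_matrix(profile), np.eye(5))

    def test_matches_direct_averaging_oracle(self, rng):
        raw = rng.uniform(size=(3, 4, 5, 5))
        raw /= raw.sum(axis=-1, keepdims=True)
        profile = AttentionProfile(raw)
        expected = raw.mean(axis=(0, 2))
        np.testing.assert_allclose(alignment_matrix(profile), expected, atol=1e-12)
        np.testing.assert_allclose(alignment_matrix(profile).sum(axis=1), 1.0, atol=1e-9)


class TestForwardFull:
    @pytest.fixture(scope="class")
    @staticmethod
    def setup(small_cohort):
        sub = small_cohort.permuted(np.arange(12))
        prior = default_prior(sub.schema)
        topologies = build_topology_set(sub, prior)
        params = init_model_params(
            d=sub.schema.d,
            style_names=sorted(np.unique(sub.learning_styles)),
            prior=prior,
            seed=0,
            token_width=8,
            encoder_dims=EncoderDims(layers=2, width=16, heads=5, head_width=4, ffn_width=32),
            gnn_dims=GnnDims(gcn_layers=2, gcn_width=8, gat_heads=4, gat_head_width=4),
        )
        return sub, topologies, params

    def test_eval_forward_is_bit_identical(self, setup):
        cohort, topologies, params = setup
        a = forward_full(cohort, topologies, params)
        b = forward_full(cohort, topologies, params)
        np.testing.assert_array_equal(a.bundle.wellbeing_pred, b.bundle.wellbeing_pred)
        np.testing.assert_array_equal(a.bundle.perma_pred, b.bundle.perma_pred)

    def test_duplicate_students_identical_predictions(self, small_cohort):
        from permawell.cohort import CohortTable

        feats = np.vstack([small_cohort.features[:5], small_cohort.features[0]])
        dup = CohortTable(
            schema=small_cohort.schema, features=feats,
            cultures=np.append(small_cohort.cultures[:5], small_cohort.cultures[0]),
            learning_styles=np.append(small_cohort.learning_styles[:5],
                                      small_cohort.learning_styles[0]),
            stress_levels=np.append(small_cohort.stress_levels[:5],
                                    small_cohort.stress_levels[0]),
        )
        prior = default_prior(dup.schema)
        topologies = build_topology_set(dup, prior)
        params = init_model_params(
            d=dup.schema.d, style_names=sorted(np.unique(dup.learning_styles)),
            prior=prior, seed=1, token_width=8,
            encoder_dims=EncoderDims(layers=1, width=16, heads=5, head_width=4, ffn_width=32),
            gnn_dims=GnnDims(gcn_layers=1, gcn_width=8, gat_heads=4, gat_head_width=4),
        )
        result = forward_full(dup, topologies, params)
        assert result.bundle.wellbeing_pred[0] == pytest.approx(
            result.bundle.wellbeing_pred[5], abs=1e-9
        )
        np.testing.assert_allclose(
            result.bundle.perma_pred[0], result.bundle.perma_pred[5], atol=1e-9
        )

    def test_composition_equals_suboperations(self, setup):
        from permawell.perma_features import cross_modal_enhance, tokenize
        from permawell.relational_gnn import encode_relations

        cohort, topologies, params = setup
        result = forward_full(cohort, topologies, params)

        tokens = tokenize(cohort.features, params.embed)
        h_graph, beta, _ = encode_relations(cohort, topologies, params.gnn)
        tokens = cross_modal_enhance(tokens, h_graph, params.cross)
        encoded, _ = encoder_forward(tokens, params.encoder)
        bundle, _, _ = predict_heads(encoded, params.heads)
        np.testing.assert_allclose(result.bundle.wellbeing_pred, bundle.wellbeing_pred, atol=1e-12)
        np.testing.assert_allclose(result.bundle.perma_pred, bundle.perma_pred, atol=1e-12)
        np.testing.assert_allclose(
            np.asarray(result.fusion_weights), np.asarray(beta), atol=1e-12
        )

    def test_fusion_weights_start_uniform(self, setup):
        cohort, topologies, params = setup
        result = forward_full(cohort, topologies, params)
        np.testing.assert_array_equal(np.asarray(result.fusion_weights), np.full((12, 4), 0.25))
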