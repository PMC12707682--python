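"""GCN/GAT layers, topology fusion and the full relational encoder."""

import numpy as np
import pytest

from permawell import (
    GnnDims,
    build_topology_set,
    default_prior,
    encode_relations,
    fuse_topologies,
    gat_layer,
    gcn_layer,
    init_gnn_params,
    normalize_adjacency,
)
from permawell.autodiff import Tensor
from permawell.graphs import Topology

SMALL_DIMS = GnnDims(gcn_layers=2, gcn_width=8, gat_heads=2, gat_head_width=4)


def leaky(v, slope=0.2):
    return np.where(v > 0, v, slope * v)


def elu(v):
    return np.where(v > 0, v, np.expm1(v))


class TestGcnLayer:
    def test_single_node_identity(self):
        H = np.array([[0.3, 0.7]])
        out = np.asarray(gcn_layer(H, np.eye(1), np.eye(2)))
        np.testing.assert_allclose(out, H, atol=1e-15)

    def test_two_connected_equal_rows_unchanged(self):
        topo = Topology("cosine", np.array([[0.0, 1.0], [1.0, 0.0]]))
        a_norm = normalize_adjacency(topo)
        H = np.array([[0.2, 0.5], [0.2, 0.5]])
        out = np.asarray(gcn_layer(H, a_norm, np.eye(2)))
        np.testing.assert_allclose(out, H, atol=1e-12)

    def test_matches_dense_triple_product(self, rng):
        n, w_in, w_out = 8, 5, 3
        raw = rng.uniform(0.3, 1, size=(n, n))
        a = np.triu(raw, 1)
        a = a + a.T
        topo = Topology("cosine", a)
        a_norm = normalize_adjacency(topo)
        H = rng.normal(size=(n, w_in))
        W = rng.normal(size=(w_in, w_out))
        expected = np.maximum(a_norm @ H @ W, 0.0)
        np.testing.assert_allclose(np.asarray(gcn_layer(H, a_norm, W)), expected, atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            gcn_layer(rng.normal(size=(3, 4)), np.eye(3), rng.normal(size=(5, 2)))


class TestGatLayer:
    def _params(self, w_in, head_width, heads, rng):
        weights = [Tensor(rng.normal(size=(w_in, head_width))) for _ in range(heads)]
        attn = [Tensor(rng.normal(size=(2 * head_width, 1))) for _ in range(heads)]
        return weights, attn

    def test_isolated_node_attends_only_to_itself(self, rng):
        adjacency = np.zeros((3, 3))
        adjacency[1, 2] = adjacency[2, 1] = 0.5
        weights, attn = self._params(4, 3, 2, rng)
        H = rng.normal(size=(3, 4))
        _, maps = gat_layer(H, adjacency, weights, attn)
        for h in range(2):
            assert maps[h, 0, 0] == pytest.approx(1.0)
            assert maps[h, 0, 1] == maps[h, 0, 2] == 0.0

    def test_identical_neighbors_get_equal_weight(self, rng):
        # node 0 linked to nodes 1 and 2, which carry identical features
        adjacency = np.zeros((3, 3))
        adjacency[0, 1] = adjacency[1, 0] = 0.8
        adjacency[0, 2] = adjacency[2, 0] = 0.8
        H = rng.normal(size=(3, 4))
        H[2] = H[1]
        weights, attn = self._params(4, 3, 2, rng)
        _, maps = gat_layer(H, adjacency, weights, attn)
        for h in range(2):
            assert maps[h, 0, 1] == pytest.approx(maps[h, 0, 2], abs=1e-12)

    def test_attention_rows_sum_to_one_over_neighborhood(self, rng):
        adjacency = (rng.uniform(size=(6, 6)) > 0.5).astype(float) * 0.7
        adjacency = np.triu(adjacency, 1)
        adjacency = adjacency + adjacency.T
        weights, attn = self._params(5, 4, 2, rng)
        _, maps = gat_layer(rng.normal(size=(6, 5)), adjacency, weights, attn)
        np.testing.assert_allclose(maps.sum(axis=-1), np.ones((2, 6)), atol=1e-6)

    def test_matches_per_edge_manual_computation(self, rng):
        n, w_in, hw, heads = 6, 5, 4, 2
        adjacency = (rng.uniform(size=(n, n)) > 0.4).astype(float) * 0.6
        adjacency = np.triu(adjacency, 1)
        adjacency = adjacency + adjacency.T
        H = rng.normal(size=(n, w_in))
        weights, attn = self._params(w_in, hw, heads, rng)
        out, maps = gat_layer(H, adjacency, weights, attn)
        out = np.asarray(out)

        for h in range(heads):
            W, a = weights[h].data, attn[h].data[:, 0]
            Wh = H @ W
            for i in range(n):
                neigh = sorted(set(np.flatnonzero(adjacency[i] > 0)) | {i})
                logits = np.array(
                    [leaky(a[:hw] @ Wh[i] + a[hw:] @ Wh[j]) for j in neigh]
                )
                alpha = np.exp(logits - logits.max())
                alpha /= alpha.sum()
                expected_row = np.zeros(n)
                expected_row[neigh] = alpha
                np.testing.assert_allclose(maps[h, i], expected_row, atol=1e-10)
                expected_out = elu(sum(al * Wh[j] for al, j in zip(alpha, neigh)))
                np.testing.assert_allclose(out[i, h * hw:(h + 1) * hw], expected_out, atol=1e-10)


class TestFusion:
    def _params(self, styles=("s0", "s1"), seed=0):
        return init_gnn_params(d=6, style_names=styles, dims=SMALL_DIMS, seed=seed)

    def test_zero_scorers_give_exact_uniform_quarters(self, rng):
        params = self._params()
        H_set = [rng.normal(size=(4, 8)) for _ in range(4)]
        styles = np.array(["s0", "s1", "s0", "s1"])
        stress = np.array(["low", "medium", "high", "low"])
        h_final, beta = fuse_topologies(H_set, styles, stress, params)
        np.testing.assert_array_equal(np.asarray(beta), np.full((4, 4), 0.25))
        np.testing.assert_allclose(
            np.asarray(h_final), 0.25 * sum(H_set), atol=1e-12
        )

    def test_saturated_scores_select_single_branch(self, rng):
        params = self._params()
        # craft v_k so branch 0 wins by a huge margin for every student
        params.w_g.data = np.zeros_like(params.w_g.data)
        params.b_g.data = np.ones_like(params.b_g.data)  # hidden = tanh(1) > 0
        params.fusion_v.data = np.zeros_like(params.fusion_v.data)
        params.fusion_v.data[0] = 100.0
        H_set = [rng.normal(size=(3, 8)) for _ in range(4)]
        styles = np.array(["s0", "s0", "s1"])
        stress = np.array(["low", "low", "high"])
        h_final, beta = fuse_topologies(H_set, styles, stress, params)
        np.testing.assert_allclose(np.asarray(beta)[:, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(np.asarray(h_final), H_set[0], atol=1e-9)

    def test_matches_manual_softmax_convex_combination(self, rng):
        params = self._params(seed=3)
        params.fusion_v.data = rng.normal(size=params.fusion_v.data.shape)
        n = 5
        H_set = [rng.normal(size=(n, 8)) for _ in range(4)]
        styles = np.array(["s0", "s1", "s0", "s1", "s0"])
        stress = np.array(["low", "medium", "high", "low", "medium"])
        h_final, beta = fuse_topologies(H_set, styles, stress, params)

        stress_order = ["low", "medium", "high"]
        for i in range(n):
            e_style = params.style_table.data[["s0", "s1"].index(styles[i])]
            e_stress = params.stress_table.data[stress_order.index(stress[i])]
            hidden = np.tanh(
                np.concatenate([e_style, e_stress]) @ params.w_g.data + params.b_g.data
            )
            scores = params.fusion_v.data @ hidden
            expected_beta = np.exp(scores - scores.max())
            expected_beta /= expected_beta.sum()
            np.testing.assert_allclose(np.asarray(beta)[i], expected_beta, atol=1e-10)
            expected_h = sum(b * H_set[k][i] for k, b in enumerate(expected_beta))
            np.testing.assert_allclose(np.asarray(h_final)[i], expected_h, atol=1e-10)

    def test_beta_rows_sum_to_one(self, rng):
        params = self._params(seed=5)
        params.fusion_v.data = rng.normal(size=params.fusion_v.data.shape)
        H_set = [rng.normal(size=(7, 8)) for _ in range(4)]
        styles = np.array(["s0"] * 7)
        stress = np.array(["medium"] * 7)
        _, beta = fuse_topologies(H_set, styles, stress, params)
        np.testing.assert_allclose(np.asarray(beta).sum(axis=1), np.ones(7), atol=1e-9)

    def test_unknown_style_rejected(self, rng):
        params = self._params()
        H_set = [rng.normal(size=(1, 8)) for _ in range(4)]
        with pytest.raises(ValueError, match="unknown learning styles"):
            fuse_topologies(H_set, np.array(["zzz"]), np.array(["low"]), params)


class TestEncodeRelations:
    def _setup(self, cohort):
        prior = default_prior(cohort.schema)
        topologies = build_topology_set(cohort, prior)
        params = init_gnn_params(
            d=cohort.schema.d,
            style_names=sorted(np.unique(cohort.learning_styles)),
            dims=SMALL_DIMS,
            seed=0,
        )
        return topologies, params

    def test_duplicate_students_get_identical_rows(self, small_cohort):
        from permawell.cohort import CohortTable

        feats = np.vstack([small_cohort.features[:6], small_cohort.features[0]])
        dup = CohortTable(
            schema=small_cohort.schema,
            features=feats,
            cultures=np.append(small_cohort.cultures[:6], small_cohort.cultures[0]),
            learning_styles=np.append(
                small_cohort.learning_styles[:6], small_cohort.learning_styles[0]
            ),
            stress_levels=np.append(
                small_cohort.stress_levels[:6], small_cohort.stress_levels[0]
            ),
        )
        topologies, params = self._setup(dup)
        h, beta, _ = encode_relations(dup, topologies, params)
        np.testing.assert_allclose(np.asarray(h)[0], np.asarray(h)[6], atol=1e-9)
        np.testing.assert_allclose(np.asarray(beta)[0], np.asarray(beta)[6], atol=1e-12)

    def test_permutation_equivariance(self, small_cohort, rng):
        sub = small_cohort.permuted(np.arange(12))
        topologies, params = self._setup(sub)
        h, beta, _ = encode_relations(sub, topologies, params)
        perm = rng.permutation(12)
        permuted = sub.permuted(perm)
        topo_perm = build_topology_set(permuted, default_prior(sub.schema))
        h_p, beta_p, _ = encode_relations(permuted, topo_perm, params)
        np.testing.assert_allclose(np.asarray(h_p), np.asarray(h)[perm], atol=1e-8)
        np.testing.assert_allclose(np.asarray(beta_p), np.asarray(beta)[perm], atol=1e-10)

    def test_composition_equals_audited_suboperations(self, small_cohort):
        sub = small_cohort.permuted(np.arange(12))
        topologies, params = self._setup(sub)
        h, beta, maps = encode_relations(sub, topologies, params)

        branch_outputs = []
        for k, topo in enumerate(topologies):
            a_norm = normalize_adjacency(topo)
            hk = sub.features
            for W in params.gcn_weights[k]:
                hk = np.asarray(gcn_layer(hk, a_norm, W))
            out, m = gat_layer(hk, topo.adjacency, params.gat_weights[k], params.gat_attn[k])
            np.testing.assert_allclose(maps[topo.kind], m, atol=1e-12)
            branch_outputs.append(np.asarray(out))
        h_expected, beta_expected = fuse_topologies(
            branch_outputs, sub.learning_styles, sub.stress_levels, params
        )
        np.testing.assert_allclose(np.asarray(h), np.asarray(h_expected), atol=1e-10)
        np.testing.assert_allclose(np.asarray(beta), np.asarray(beta_expected), atol=1e-12)

    def test_empty_graphs_still_equivariant(self, small_cohort, rng):
        from permawell.graphs import Topology, TopologySet

        sub = small_cohort.permuted(np.arange(8))
        _, params = self._setup(sub)
        empty = TopologySet(tuple(
            Topology(kind, np.zeros((8, 8))) for kind in ("cosine", "euclidean", "learning", "perma")
        ))
        h, _, _ = encode_relations(sub, empty, params)
        perm = rng.permutation(8)
        h_p, _, _ = encode_relations(sub.permuted(perm), empty, params)
        np.testing.assert_allclose(np.asarray(h_p), np.asarray(h)[perm], atol=1e-9)
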