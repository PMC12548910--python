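import numpy as np
import pytest

from causyn.autograd import Tensor, concat
from causyn.featurize import FEATURE_DIM, normalize_adjacency, smiles_to_graph
from causyn.model import (
    FusedGraph,
    LossBundle,
    ModelConfig,
    SynergyNet,
    bias_loss,
    causal_loss,
    combine_pair,
    compute_masks,
    cross_attention_fuse,
    decouple,
    encode_drug,
    gcn_forward,
    intervention_loss,
    predict,
)
from tests.conftest import random_graph_adjacency


def tiny_net(n_feat=FEATURE_DIM, **kw):
    return SynergyNet(n_feat, ModelConfig(hidden_dim=8, attn_dim=4,
                                          mask_hidden=6, **kw))


def make_fused(net, gn=5, seed=0):
    rng = np.random.default_rng(seed)
    A = random_graph_adjacency(rng, gn, p=0.5)
    a_hat = normalize_adjacency(A)
    feats = Tensor(rng.normal(size=(gn, net.config.fused_dim)))
    return FusedGraph(feats, A, a_hat)


class TestGCNForward:
    def test_single_node_hand_product(self):
        out = gcn_forward([[1.0]], [[2.0]], [Tensor([[3.0]])])
        assert np.allclose(out.data, [[6.0]])

    def test_zero_weights_annihilate(self):
        rng = np.random.default_rng(0)
        A = normalize_adjacency(random_graph_adjacency(rng, 4))
        out = gcn_forward(A, rng.normal(size=(4, 3)), [Tensor(np.zeros((3, 2)))])
        assert np.all(out.data == 0)

    def test_shape_mismatch_names_layer(self):
        with pytest.raises(ValueError, match="layer 0"):
            gcn_forward([[1.0]], [[1.0, 2.0]], [Tensor([[1.0]])])

    @pytest.mark.parametrize("trial", range(5))
    def test_permutation_equivariance_vs_dense_reference(self, trial):
        rng = np.random.default_rng(trial)
        n = 6
        A = random_graph_adjacency(rng, n)
        X = rng.normal(size=(n, 4))
        W = [Tensor(rng.normal(size=(4, 3))), Tensor(rng.normal(size=(3, 3)))]
        a_hat = normalize_adjacency(A)
        out = gcn_forward(a_hat, X, W).data
        # dense reference: explicit matrix products
        ref = X
        for w in W:
            ref = np.maximum(a_hat @ ref @ w.data, 0)
        assert np.allclose(out, ref, atol=1e-10)
        P = np.eye(n)[rng.permutation(n)]
        out_p = gcn_forward(normalize_adjacency(P @ A @ P.T), P @ X, W).data
        assert np.allclose(out_p, P @ out, atol=1e-8)


class TestDrugEncoding:
    def test_max_pool_columnwise(self):
        # pooled vector is the columnwise max of the node features
        h = Tensor(np.array([[1.0, 5.0], [3.0, 2.0]]))
        from causyn.model import _pool

        assert np.allclose(_pool(h, "max").data, [[3.0, 5.0]])

    def test_isomorphic_smiles_same_embedding(self):
        rng = np.random.default_rng(0)
        weights = [Tensor(rng.normal(size=(FEATURE_DIM, 6)))]
        a = encode_drug(smiles_to_graph("OCC"), weights)
        b = encode_drug(smiles_to_graph("CCO"), weights)
        assert np.allclose(a.data, b.data, atol=1e-12)

    def test_single_atom_identity_pooling(self):
        rng = np.random.default_rng(1)
        weights = [Tensor(rng.normal(size=(FEATURE_DIM, 6)))]
        g = smiles_to_graph("C")
        out = encode_drug(g, weights)
        assert out.shape == (1, 6)
        assert np.allclose(out.data, np.maximum(g.X @ weights[0].data, 0))


class TestCombinePair:
    def test_sum_and_commutativity(self):
        x = Tensor(np.array([[1.0, 2.0]]))
        y = Tensor(np.array([[3.0, 4.0]]))
        assert np.allclose(combine_pair(x, y).data, [[4.0, 6.0]])
        assert np.allclose(combine_pair(x, y).data, combine_pair(y, x).data)
        zero = Tensor(np.zeros((1, 2)))
        assert np.allclose(combine_pair(x, zero).data, x.data)

    def test_dim_mismatch(self):
        with pytest.raises(ValueError):
            combine_pair(Tensor(np.zeros((1, 2))), Tensor(np.zeros((1, 3))))


class TestCrossAttention:
    def _params(self, rng, h, b):
        return [{
            "Wq": Tensor(rng.normal(size=(h, b))),
            "Wk": Tensor(rng.normal(size=(1, b))),
            "Wv": Tensor(rng.normal(size=(h, b))),
            "Wr": Tensor(rng.normal(size=(h, b))),
        }]

    def test_equal_logits_give_uniform_attention(self):
        h, b, gn = 6, 3, 4
        params = [{
            "Wq": Tensor(np.zeros((h, b))),  # all logits equal (zero)
            "Wk": Tensor(np.ones((1, b))),
            "Wv": Tensor(np.eye(h)[:, :b]),
            "Wr": Tensor(np.ones((h, b))),
        }]
        ce = Tensor(np.random.default_rng(0).normal(size=(gn, h)))
        d = Tensor(np.ones((1, h)))
        fused, attn = cross_attention_fuse(ce, d, params, b)
        # gene-axis softmax of a constant matrix is uniform; with the mean-1
        # rescaling every gate entry equals exactly 1
        assert np.allclose(attn.data, np.ones((gn, b)) * h)

    def test_output_width_is_b_plus_h(self):
        rng = np.random.default_rng(1)
        h, b, gn = 5, 3, 7
        ce = Tensor(rng.normal(size=(gn, h)))
        d = Tensor(rng.normal(size=(1, h)))
        fused, _ = cross_attention_fuse(ce, d, self._params(rng, h, b), b)
        assert fused.shape == (gn, b + h)

    def test_empty_graph_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            cross_attention_fuse(
                Tensor(np.empty((0, 4))), Tensor(np.ones((1, 4))),
                self._params(rng, 4, 2), 2,
            )


class TestMasksAndDecoupling:
    def test_scores_sum_to_one(self):
        net = tiny_net()
        fused = make_fused(net)
        masks = net.masks(fused)
        assert np.allclose(masks.alpha_c.data + masks.alpha_s.data, 1, atol=1e-6)
        assert np.allclose(masks.beta_c.data + masks.beta_s.data, 1, atol=1e-6)

    def test_zero_weight_mlps_give_half(self):
        net = tiny_net()  # mask output layers are zero-initialized
        masks = net.masks(make_fused(net))
        assert np.allclose(masks.node_mask, 0.5)
        assert np.allclose(masks.beta_c.data, 0.5)

    def test_edge_mask_matrix_symmetric(self):
        net = tiny_net()
        fused = make_fused(net, seed=3)
        m = net.masks(fused).edge_mask_matrix(fused.n_nodes)
        assert np.allclose(m, m.T)
        assert np.all((m >= 0) & (m <= 1))

    def test_feature_complementarity(self):
        net = tiny_net()
        fused = make_fused(net, seed=4)
        # non-trivial masks: perturb the mask output layer
        net.params["node_mlp.W2"].data += np.random.default_rng(0).normal(
            size=net.params["node_mlp.W2"].shape
        )
        masks = net.masks(fused)
        pair = net.decouple(fused, masks)
        assert np.allclose(
            pair.features_c.data + pair.features_s.data,
            fused.node_features.data, atol=1e-9,
        )

    def test_mask_extremes(self):
        net = tiny_net(freeze_masks=True)
        fused = make_fused(net, seed=5)
        masks = net.masks(fused)  # frozen: alpha_c = 1 everywhere
        pair = net.decouple(fused, masks)
        assert np.allclose(pair.features_c.data, fused.node_features.data)
        assert np.allclose(pair.features_s.data, 0)

    def test_masked_propagation_zero_off_support(self):
        net = tiny_net()
        fused = make_fused(net, seed=6)
        pair = net.decouple(fused, net.masks(fused))
        off = (fused.adjacency == 0) & ~np.eye(fused.n_nodes, dtype=bool)
        assert np.all(pair.propagation_c.data[off] == 0)


class TestPredictAndLosses:
    def test_zero_head_gives_half(self):
        head = {"W1": Tensor(np.zeros((4, 3))), "b1": Tensor(np.zeros((1, 3))),
                "W2": Tensor(np.zeros((3, 2))), "b2": Tensor(np.zeros((1, 2)))}
        z = predict(Tensor(np.ones((2, 4))), head)
        assert np.allclose(z.data, 0.5)

    def test_probabilities_sum_to_one_and_monotone(self):
        rng = np.random.default_rng(0)
        head = {"W1": Tensor(rng.normal(size=(4, 3))),
                "b1": Tensor(rng.normal(size=(1, 3))),
                "W2": Tensor(rng.normal(size=(3, 2))),
                "b2": Tensor(rng.normal(size=(1, 2)))}
        z = predict(Tensor(rng.normal(size=(6, 4))), head)
        assert np.allclose(z.data.sum(axis=1), 1, atol=1e-12)
        # raising the positive logit raises the positive probability
        logits = Tensor(np.array([[0.2, 0.4]]))
        low = logits.softmax_rows().data[0, 1]
        high = Tensor(np.array([[0.2, 1.4]])).softmax_rows().data[0, 1]
        assert high > low

    def test_causal_loss_closed_forms(self):
        perfect = Tensor(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert causal_loss(perfect, [1, 0]).data < 1e-9
        uniform = Tensor(np.full((4, 2), 0.5))
        assert np.isclose(causal_loss(uniform, [0, 1, 1, 0]).data, np.log(2))
        # batch loss equals the mean of the singleton losses
        z = Tensor(np.array([[0.3, 0.7], [0.8, 0.2]]))
        per = [causal_loss(Tensor(z.data[i:i + 1]), [y]).data
               for i, y in enumerate([1, 0])]
        assert np.isclose(causal_loss(z, [1, 0]).data, np.mean(per))

    def test_bias_loss_kl_properties(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.isclose(bias_loss(Tensor(y), y).data, 0.0, atol=1e-9)
        z = Tensor(np.array([[0.5, 0.5]]))
        assert np.isclose(bias_loss(z, np.array([[1.0, 0.0]])).data, np.log(2))
        rng = np.random.default_rng(1)
        raw = rng.random((5, 2))
        z = Tensor(raw / raw.sum(axis=1, keepdims=True))
        y = rng.random((5, 2))
        y /= y.sum(axis=1, keepdims=True)
        assert bias_loss(z, y).data >= -1e-12  # Gibbs inequality

    def test_intervention_loss_symmetry_and_pool_error(self):
        z1 = Tensor(np.array([[0.3, 0.7]]))
        z2 = Tensor(np.array([[0.6, 0.4]]))
        a = intervention_loss([z1, z2], [1]).data
        b = intervention_loss([z2, z1], [1]).data
        assert np.isclose(a, b)
        with pytest.raises(ValueError):
            intervention_loss([], [1])

    def test_total_loss_linearity(self):
        lc, lb, li = Tensor(0.4), Tensor(0.3), Tensor(0.2)
        base = LossBundle(lc, lb, li, 1.0, 1.0).total.data
        doubled = LossBundle(lc, lb, li, 2.0, 1.0).total.data
        assert np.isclose(doubled - base, 0.3)
        assert np.isclose(LossBundle(lc, lb, li, 0.0, 0.0).total.data, 0.4)
        zeros = LossBundle(Tensor(0.0), Tensor(0.0), Tensor(0.0), 0.5, 0.5)
        assert zeros.total.data == 0.0


class TestCheckpoint:
    def test_round_trip_restores_parameters_and_manifests(self, tmp_path):
        from causyn.model import load_checkpoint, save_checkpoint

        net = tiny_net()
        path = tmp_path / "model.npz"
        manifests = {"CL00": ["G0001", "G0002", "G0005"]}
        save_checkpoint(net, path, manifests)
        restored, loaded_manifests = load_checkpoint(path)
        assert loaded_manifests == manifests
        assert restored.config == net.config
        for k, v in net.state_dict().items():
            assert np.array_equal(restored.state_dict()[k], v)


class TestFullForward:
    def test_drug_order_invariance(self, small_dataset):
        ds = small_dataset
        net = SynergyNet(ds.feature_dim, ModelConfig(seed=0))
        rec = ds.records[0]
        def z_for(d1, d2):
            e1 = net.encode_drug(ds.drug_graphs[d1])
            e2 = net.encode_drug(ds.drug_graphs[d2])
            d_ij = combine_pair(e1, e2)
            ce = net.encode_cell(ds.cell_norm_adj[rec.cell_line],
                                 ds.cell_graphs[rec.cell_line].features)
            fused = net.fuse(ce, d_ij, ds.cell_graphs[rec.cell_line].adjacency,
                             ds.cell_norm_adj[rec.cell_line])
            pair = net.decouple(fused, net.masks(fused))
            return net.predict_causal(d_ij, pair.h_c).data

        assert np.allclose(z_for(rec.drug1, rec.drug2),
                           z_for(rec.drug2, rec.drug1), atol=1e-12)

    def test_frozen_mask_model_matches_plain_classifier(self, small_dataset):
        """With masks frozen at the causal extreme and zero loss weights the
        model is a plain GCN + cross-attention classifier."""
        ds = small_dataset
        cfg = ModelConfig(seed=3, freeze_masks=True, lambda_bias=0.0,
                          lambda_interv=0.0)
        net = SynergyNet(ds.feature_dim, cfg)
        rec = ds.records[1]
        e1 = net.encode_drug(ds.drug_graphs[rec.drug1])
        e2 = net.encode_drug(ds.drug_graphs[rec.drug2])
        d_ij = combine_pair(e1, e2)
        ce = net.encode_cell(ds.cell_norm_adj[rec.cell_line],
                             ds.cell_graphs[rec.cell_line].features)
        fused = net.fuse(ce, d_ij, ds.cell_graphs[rec.cell_line].adjacency,
                         ds.cell_norm_adj[rec.cell_line])
        pair = net.decouple(fused, net.masks(fused))
        z_model = net.predict_causal(d_ij, pair.h_c).data
        # plain path: no masking anywhere, same parameters
        from causyn.model import _pool, gcn_forward as gf

        h_plain = _pool(
            gf(fused.normalized_adjacency, fused.node_features,
               [net.params["dec_gcn.0"]]),
            cfg.pooling,
        )
        z_plain = net.predict_causal(d_ij, h_plain).data
        assert np.allclose(z_model, z_plain, atol=1e-12)
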