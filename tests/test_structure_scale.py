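import numpy as np
import pytest

from muse import _autodiff as ad
from muse._autodiff import Tensor
from muse.graph_io import MolecularGraph
from muse.structure_scale import (
    GCNEncoder,
    GeometricEncoder,
    GINEncoder,
    GraphBatch,
    PairClassifier,
    StructureEncoderParams,
    StructureModel,
    encode_structure_gcn,
    estep_loss,
    predict_pair_q,
    readout,
    train_estep,
)

from conftest import fast_config, small_spec


def random_graph(rng, n=None, d=4, kind="generic", with_coords=False):
    n = n or int(rng.integers(3, 10))
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n)
        if rng.random() < 0.4
    ]
    return MolecularGraph(
        entity_id="g",
        entity_kind=kind,
        node_features=rng.normal(size=(n, d)),
        edges=np.array(edges).reshape(-1, 2),
        coords=rng.normal(size=(n, 3)) * 5 if with_coords else None,
    )


def permuted_graph(g, perm):
    inv = np.argsort(perm)
    edges = inv[g.edges]
    return MolecularGraph(
        entity_id=g.entity_id,
        entity_kind=g.entity_kind,
        node_features=g.node_features[perm],
        edges=edges,
        coords=None if g.coords is None else g.coords[perm],
    )


class TestGCNEncoder:
    def test_single_node_identity_weights(self, rng):
        g = MolecularGraph(
            entity_id="g", entity_kind="generic",
            node_features=np.array([[-1.0, 2.0, 0.5]]), edges=[],
        )
        params = StructureEncoderParams(
            encoder_kind="gcn", layers=1, hidden=3, dropout=0.0,
            use_norm=False,
        )
        enc = GCNEncoder(3, params, rng)
        enc.linears[0].weight.data = np.eye(3)
        enc.eval()
        out = encode_structure_gcn(g, enc)
        # A_hat = [[1]] with self-loop, so output is ReLU(x)
        np.testing.assert_allclose(out, [[0.0, 2.0, 0.5]])

    def test_two_node_path_normalization(self):
        g = MolecularGraph(
            entity_id="g", entity_kind="generic",
            node_features=np.zeros((2, 1)), edges=[(0, 1)],
        )
        a_hat = GraphBatch([g]).normalized_adjacency(self_loops=True)
        np.testing.assert_allclose(
            a_hat.toarray(), [[0.5, 0.5], [0.5, 0.5]]
        )

    def test_permutation_equivariance(self, rng):
        params = StructureEncoderParams(
            encoder_kind="gcn", layers=2, hidden=8, dropout=0.0
        )
        enc = GCNEncoder(4, params, np.random.default_rng(7))
        enc.eval()
        for _ in range(100):
            g = random_graph(rng)
            perm = rng.permutation(g.n_nodes)
            out = encode_structure_gcn(g, enc)
            out_p = encode_structure_gcn(permuted_graph(g, perm), enc)
            np.testing.assert_allclose(out[perm], out_p, atol=1e-10)

    def test_empty_graph_errors(self, rng):
        params = StructureEncoderParams(encoder_kind="gcn")
        enc = GCNEncoder(4, params, rng)
        g = MolecularGraph(
            entity_id="g", entity_kind="generic",
            node_features=np.zeros((1, 4)), edges=[],
        )
        g.node_features = np.zeros((0, 4))  # force empty
        with pytest.raises(ValueError):
            encode_structure_gcn(g, enc)


class TestGeometricEncoder:
    def make_encoder(self, seed=3, layers=2, hidden=8, k=3):
        params = StructureEncoderParams(
            encoder_kind="geometric", layers=layers, hidden=hidden,
            dropout=0.0, knn_k=k,
        )
        return GeometricEncoder(4, params, np.random.default_rng(seed))

    def test_isolated_node_reduces_to_layernorm(self, rng):
        # single-node graph: no k-NN edges possible -> update is the
        # norm stack applied to the projected input
        g = random_graph(rng, n=1, with_coords=True)
        enc = self.make_encoder()
        enc.eval()
        out = enc(GraphBatch([g]))
        batch = GraphBatch([g])
        h = enc.input_proj(Tensor(np.concatenate(
            [batch.node_features, np.zeros((1, 9))], axis=1
        )))
        for norm in enc.norms:
            h = norm(h)
        np.testing.assert_allclose(out.data, h.data, atol=1e-10)

    def test_translation_invariance(self, rng):
        enc = self.make_encoder()
        enc.eval()
        for _ in range(100):
            g = random_graph(rng, n=8, with_coords=True)
            shifted = MolecularGraph(
                entity_id=g.entity_id, entity_kind=g.entity_kind,
                node_features=g.node_features, edges=g.edges,
                coords=g.coords + rng.normal(size=3) * 100,
            )
            out = enc(GraphBatch([g])).data
            out_shift = enc(GraphBatch([shifted])).data
            np.testing.assert_allclose(out, out_shift, atol=1e-8)

    def test_message_sum_matches_explicit_loop(self, rng):
        g = random_graph(rng, n=10, with_coords=True)
        enc = self.make_encoder(layers=1)
        enc.eval()
        batch = GraphBatch([g])
        edges = batch.knn_edges(3)
        from muse.structure_scale import _chain_vectors

        chain = _chain_vectors(batch.coords, batch.node_graph)
        h = enc.input_proj(Tensor(np.concatenate(
            [batch.node_features, chain], axis=1
        )))
        e_feat = Tensor(enc._edge_features(batch, edges))
        messages = enc.message_mlps[0](
            ad.concat([h.gather_rows(edges[:, 0]), e_feat], axis=1)
        ).data
        agg = ad.segment_sum(
            Tensor(messages), edges[:, 1], batch.n_nodes
        ).data
        # naive per-edge accumulation oracle
        expected = np.zeros_like(agg)
        for row, (_, dst) in zip(messages, edges):
            expected[dst] += row
        np.testing.assert_allclose(agg, expected, atol=1e-12)

    def test_missing_coords_errors(self, rng):
        g = random_graph(rng, with_coords=False)
        enc = self.make_encoder()
        with pytest.raises(ValueError, match="coordinates"):
            enc(GraphBatch([g]))


class TestGINEncoder:
    def make_encoder(self, d=4, edge_dim=0, seed=5):
        params = StructureEncoderParams(
            encoder_kind="gin", layers=2, hidden=8, dropout=0.0
        )
        return GINEncoder(d, edge_dim, params, np.random.default_rng(seed))

    def test_isolated_node_depends_only_on_self(self, rng):
        enc = self.make_encoder()
        enc.eval()
        g1 = MolecularGraph(
            entity_id="a", entity_kind="generic",
            node_features=rng.normal(size=(1, 4)), edges=[],
        )
        out1 = enc(GraphBatch([g1])).data
        # same node inside a larger batch of other graphs
        g2 = random_graph(rng)
        out_joint = enc(GraphBatch([g1, g2])).data
        np.testing.assert_allclose(out1[0], out_joint[0], atol=1e-10)

    def test_isomorphism_invariance(self, rng):
        enc = self.make_encoder()
        enc.eval()
        for _ in range(100):
            g = random_graph(rng)
            perm = rng.permutation(g.n_nodes)
            out = enc(GraphBatch([g])).data
            out_p = enc(GraphBatch([permuted_graph(g, perm)])).data
            # identical multisets of node embeddings
            np.testing.assert_allclose(out[perm], out_p, atol=1e-10)

    def test_star_aggregation_matches_loop(self, rng):
        # K_{1,3}: center 0, leaves 1..3
        g = MolecularGraph(
            entity_id="star", entity_kind="generic",
            node_features=rng.normal(size=(4, 4)),
            edges=[(0, 1), (0, 2), (0, 3)],
        )
        enc = self.make_encoder()
        enc.eval()
        batch = GraphBatch([g])
        h = enc.input_proj(Tensor(batch.node_features)).data
        directed = batch.directed_edges()
        agg = np.zeros_like(h)
        for src, dst in directed:
            agg[dst] += h[src]
        # center's aggregation = sum over the 3 leaves
        np.testing.assert_allclose(agg[0], h[1] + h[2] + h[3], atol=1e-12)
        out = enc.update_mlps[0](Tensor(h + agg))
        full = enc.update_mlps[0](
            Tensor(h) + ad.segment_sum(
                Tensor(h).gather_rows(directed[:, 0]),
                directed[:, 1], 4,
            )
        )
        np.testing.assert_allclose(out.data, full.data, atol=1e-12)


class TestReadout:
    def test_single_node(self, rng):
        emb = Tensor(rng.normal(size=(1, 5)))
        np.testing.assert_array_equal(readout(emb).data, emb.data[0])

    def test_permutation_invariance(self, rng):
        for _ in range(100):
            emb = rng.normal(size=(7, 4))
            perm = rng.permutation(7)
            np.testing.assert_allclose(
                readout(Tensor(emb)).data,
                readout(Tensor(emb[perm])).data,
                atol=1e-12,
            )

    def test_sum_of_ones(self):
        out = readout(Tensor(np.ones((5, 3))))
        np.testing.assert_array_equal(out.data, [5.0, 5.0, 5.0])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            readout(Tensor(np.zeros((0, 3))))


class TestPairClassifier:
    def test_symmetry(self, rng):
        clf = PairClassifier(8, 3, rng)
        for _ in range(100):
            a, b = rng.normal(size=(2, 8))
            p1 = predict_pair_q(a, b, clf)
            p2 = predict_pair_q(b, a, clf)
            np.testing.assert_array_equal(
                p1.label_distribution, p2.label_distribution
            )

    def test_zero_embedding_absorbs(self, rng):
        clf = PairClassifier(8, 1, rng)
        zero = np.zeros(8)
        p1 = predict_pair_q(zero, rng.normal(size=8), clf)
        p2 = predict_pair_q(zero, rng.normal(size=8), clf)
        np.testing.assert_array_equal(p1.logits, p2.logits)

    def test_zero_weights_give_half(self, rng):
        clf = PairClassifier(8, 1, rng)
        for p in clf.parameters():
            p.data = np.zeros_like(p.data)
        pred = predict_pair_q(rng.normal(size=8), rng.normal(size=8), clf)
        np.testing.assert_allclose(pred.label_distribution, [0.5])

    def test_width_mismatch_errors(self, rng):
        clf = PairClassifier(8, 1, rng)
        with pytest.raises(ValueError, match="mismatch"):
            predict_pair_q(np.zeros(8), np.zeros(4), clf)

    def test_softmax_head_sums_to_one(self, rng):
        clf = PairClassifier(8, 4, rng, head="softmax")
        pred = predict_pair_q(rng.normal(size=8), rng.normal(size=8), clf)
        assert pred.label_distribution.sum() == pytest.approx(1.0)


class TestEstepLoss:
    def make_batch(self, rng, n_obs=6, n_unobs=4, c=2):
        lo = Tensor(rng.normal(size=(n_obs, c)))
        yo = (rng.random((n_obs, c)) < 0.5).astype(float)
        lu = Tensor(rng.normal(size=(n_unobs, c)))
        yu = rng.random((n_unobs, c))
        return lo, yo, lu, yu

    def test_alpha_zero_is_supervised(self, rng):
        lo, yo, lu, yu = self.make_batch(rng)
        from muse.structure_scale import _cross_entropy

        loss = estep_loss(lo, yo, lu, yu, 0.0)
        expected = _cross_entropy(lo, yo, "sigmoid")
        assert loss.item() == pytest.approx(expected.item(), abs=1e-12)

    def test_alpha_one_is_distillation(self, rng):
        lo, yo, lu, yu = self.make_batch(rng)
        from muse.structure_scale import _cross_entropy

        loss = estep_loss(lo, yo, lu, yu, 1.0)
        expected = _cross_entropy(lu, yu, "sigmoid")
        assert loss.item() == pytest.approx(expected.item(), abs=1e-12)

    def test_linear_decomposition(self, rng):
        lo, yo, lu, yu = self.make_batch(rng)
        l0 = estep_loss(lo, yo, lu, yu, 0.0).item()
        l1 = estep_loss(lo, yo, lu, yu, 1.0).item()
        for alpha in (0.1, 0.25, 0.5, 0.75, 0.9):
            la = estep_loss(lo, yo, lu, yu, alpha).item()
            assert la == pytest.approx(alpha * l1 + (1 - alpha) * l0,
                                       abs=1e-6)

    def test_exact_match_hard_labels_zero_loss(self, rng):
        y = (rng.random((5, 2)) < 0.5).astype(float)
        logits = Tensor((2 * y - 1) * 1e3)  # saturated towards labels
        loss = estep_loss(logits, y, None, None, 0.0)
        assert loss.item() == pytest.approx(0.0, abs=1e-6)

    def test_alpha_out_of_range(self, rng):
        lo, yo, lu, yu = self.make_batch(rng)
        with pytest.raises(ValueError):
            estep_loss(lo, yo, lu, yu, 1.5)


class TestTrainEstep:
    def make_model_and_data(self, seed=0):
        from muse.em_core import MultiScaleDataset, build_structure_model

        ds = MultiScaleDataset.from_spec(small_spec(seed=seed))
        cfg = fast_config(seed=seed)
        model = build_structure_model(ds, cfg)
        pairs, labels = ds.observed_pairs_labels()
        return model, ds, pairs, labels

    def test_iteration_zero_equals_alpha_zero(self):
        model_a, ds, pairs, labels = self.make_model_and_data()
        unobs = ds.unobserved_pool()
        losses_none, _ = train_estep(
            model_a, pairs, labels, unobs, None, 0.7, epochs=3
        )
        model_b, ds, pairs, labels = self.make_model_and_data()
        losses_zero, _ = train_estep(
            model_b, pairs, labels, unobs,
            np.full((unobs.shape[0], 1), 0.5), 0.0, epochs=3,
        )
        np.testing.assert_allclose(losses_none, losses_zero, atol=1e-9)

    def test_loss_mostly_decreasing(self):
        model, ds, pairs, labels = self.make_model_and_data()
        losses, _ = train_estep(
            model, pairs, labels, ds.unobserved_pool(), None, 0.0,
            epochs=25, lr=1e-2,
        )
        diffs = np.diff(losses)
        assert np.mean(diffs <= 1e-9) >= 0.8

    def test_reproducible(self):
        results = []
        for _ in range(2):
            model, ds, pairs, labels = self.make_model_and_data()
            _, probs = train_estep(
                model, pairs, labels, ds.unobserved_pool(), None, 0.0,
                epochs=3,
            )
            results.append(probs)
        np.testing.assert_array_equal(results[0], results[1])

    def test_no_observed_links_errors(self):
        model, ds, pairs, labels = self.make_model_and_data()
        with pytest.raises(ValueError):
            train_estep(
                model, np.zeros((0, 2)), np.zeros((0, 1)),
                ds.unobserved_pool(), None, 0.0, epochs=1,
            )


def test_structure_model_pair_predictions_symmetric(small_dataset):
    from muse.em_core import build_structure_model

    model = build_structure_model(small_dataset, fast_config())
    pool = small_dataset.unobserved_pool()[:20]
    p_fwd = model.predict_pairs(pool)
    p_rev = model.predict_pairs(pool[:, ::-1])
    np.testing.assert_array_equal(p_fwd, p_rev)
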