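"""Variational graph auto-encoder: losses, featurization, training."""

import math

import numpy as np
import pytest

from heartkg import dvgae
from heartkg.graph import EdgeRecord, NodeRecord, build_graph


class TestClosedFormLosses:
    def test_reconstruction_single_edge_zero_dot(self):
        z = np.array([[1.0, 0.0], [0.0, 1.0]])
        loss = dvgae.reconstruction_loss(z, np.array([[0], [1]]), epsilon=1e-300)
        assert loss == pytest.approx(-math.log(0.5), abs=1e-9)

    def test_reconstruction_two_edges_averages(self):
        z = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 2.0], [3.0, 0.0]])
        loss = dvgae.reconstruction_loss(z, np.array([[0, 2], [1, 3]]), epsilon=1e-300)
        assert loss == pytest.approx(-math.log(0.5), abs=1e-9)

    def test_reconstruction_vanishes_for_certain_edges(self):
        z = np.full((2, 4), 30.0)
        loss = dvgae.reconstruction_loss(z, np.array([[0], [1]]))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_reconstruction_empty_edge_set_rejected(self):
        with pytest.raises(ValueError):
            dvgae.reconstruction_loss(np.zeros((2, 2)), np.empty((2, 0)))

    def test_kl_standard_normal_is_zero(self):
        assert dvgae.kl_loss(np.zeros(3), np.ones(3)) == pytest.approx(0.0, abs=1e-12)

    def test_kl_single_node_unit_mean(self):
        assert dvgae.kl_loss(np.array([1.0]), np.array([1.0])) == pytest.approx(0.5, abs=1e-12)

    def test_kl_nonnegative(self, rng):
        for _ in range(20):
            mu = rng.normal(size=(4, 3))
            sigma = np.exp(rng.normal(size=(4, 3)))
            assert dvgae.kl_loss(mu, sigma) >= -1e-12

    def test_kl_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            dvgae.kl_loss(np.zeros(2), np.array([1.0, 0.0]))

    def test_total_loss_additivity(self):
        assert dvgae.total_loss(0.5, 0.0, 10) == pytest.approx(0.5, abs=1e-12)
        assert dvgae.total_loss(0.5, 1.0, 2) == pytest.approx(1.0, abs=1e-12)
        for n in (1, 5, 1000):
            assert dvgae.total_loss(0.7, 0.0, n) == pytest.approx(0.7, abs=1e-12)

    def test_total_loss_rejects_bad_node_count(self):
        with pytest.raises(ValueError):
            dvgae.total_loss(0.5, 1.0, 0)


class TestDecoder:
    def test_orthogonal_vectors_give_half(self):
        assert dvgae.decode_edge_probability(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.5

    def test_monotone_in_dot_product(self):
        v = np.ones(4)
        probs = [dvgae.decode_edge_probability(c * v, v) for c in (0.1, 1.0, 10.0)]
        assert probs == sorted(probs)
        assert probs[-1] > 0.999999

    def test_symmetric(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        assert dvgae.decode_edge_probability(a, b) == dvgae.decode_edge_probability(b, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dvgae.decode_edge_probability(np.ones(3), np.ones(4))


class TestReparameterize:
    def test_zero_sigma_returns_mu(self):
        mu = np.arange(6.0).reshape(2, 3)
        assert np.array_equal(dvgae.reparameterize(mu, np.zeros_like(mu), 0), mu)

    def test_seeded_reproducibility(self):
        mu, sigma = np.zeros((3, 2)), np.ones((3, 2))
        assert np.array_equal(
            dvgae.reparameterize(mu, sigma, 5), dvgae.reparameterize(mu, sigma, 5)
        )

    def test_monte_carlo_mean_near_mu(self):
        mu = np.array([[1.5, -2.0]])
        sigma = np.array([[0.5, 1.0]])
        rng = np.random.default_rng(3)
        draws = np.stack([dvgae.reparameterize(mu, sigma, rng) for _ in range(100_000)])
        err = np.abs(draws.mean(axis=0) - mu)
        assert np.all(err < 3 * sigma / math.sqrt(100_000))


class TestEdgeWiseAccuracy:
    def test_superset_reconstruction_is_perfect(self):
        orig = {("a", "b"), ("b", "c")}
        assert dvgae.edge_wise_accuracy(orig, orig | {("c", "a")}) == 1.0

    def test_partial_recovery(self):
        orig = {(i, i + 1) for i in range(4)}
        rec = {(0, 1), (1, 2), (2, 3)}
        assert dvgae.edge_wise_accuracy(orig, rec) == 0.75

    def test_disjoint_sets_zero(self):
        assert dvgae.edge_wise_accuracy({("a", "b")}, {("b", "a")}) == 0.0

    def test_empty_original_rejected(self):
        with pytest.raises(ValueError):
            dvgae.edge_wise_accuracy(set(), {("a", "b")})


class TestNegativeSampling:
    def test_forced_single_missing_pair(self):
        # complete directed 3-node graph minus one ordered pair
        nodes = [NodeRecord(x, "gene") for x in "abc"]
        pairs = [(s, t) for s in "abc" for t in "abc" if s != t and (s, t) != ("c", "a")]
        kg = build_graph(nodes, [EdgeRecord(s, t, "r") for s, t in pairs])
        assert dvgae.sample_negative_edges(kg, 1, seed=0) == {("c", "a")}

    def test_disjoint_from_edges_and_seeded(self, tiny_sim):
        _, kg, _ = tiny_sim
        neg1 = dvgae.sample_negative_edges(kg, 200, seed=4)
        neg2 = dvgae.sample_negative_edges(kg, 200, seed=4)
        assert neg1 == neg2
        assert len(neg1) == 200
        assert not neg1 & kg.directed_pairs()
        assert all(u != v for u, v in neg1)

    def test_infeasible_count_rejected(self):
        nodes = [NodeRecord(x, "gene") for x in "ab"]
        kg = build_graph(nodes, [EdgeRecord("a", "b", "r")])
        with pytest.raises(ValueError):
            dvgae.sample_negative_edges(kg, 2, seed=0)


class TestFeaturize:
    def test_one_hot_width_without_numeric_properties(self):
        nodes = [NodeRecord("a", "gene"), NodeRecord("b", "disease")]
        kg = build_graph(nodes, [EdgeRecord("a", "b", "r")])
        feats = dvgae.featurize(kg)
        assert feats.X.shape == (2, 12)
        assert feats.X.sum() == 2  # one type bit per node

    def test_numeric_property_standardized_with_presence_flag(self):
        nodes = [
            NodeRecord("a", "individual", {"age": 60}),
            NodeRecord("b", "individual", {"age": 40}),
            NodeRecord("c", "disease"),
        ]
        kg = build_graph(nodes, [EdgeRecord("a", "c", "r")])
        feats = dvgae.featurize(kg)
        age = feats.feature_names.index("prop:age")
        flag = feats.feature_names.index("has:age")
        col = feats.X[:, age]
        assert col[0] == pytest.approx(1.0) and col[1] == pytest.approx(-1.0)
        assert col[2] == 0.0
        assert list(feats.X[:, flag]) == [1.0, 1.0, 0.0]

    def test_constant_property_column_is_zero(self):
        nodes = [NodeRecord(f"i{k}", "individual", {"age": 50}) for k in range(3)]
        kg = build_graph(nodes, [EdgeRecord("i0", "i1", "r")])
        feats = dvgae.featurize(kg)
        age = feats.feature_names.index("prop:age")
        assert np.all(feats.X[:, age] == 0.0)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            dvgae.featurize(build_graph([NodeRecord("a", "gene")], []))


class TestEncoder:
    @pytest.fixture(scope="class")
    def feats(self, tiny_sim):
        _, kg, _ = tiny_sim
        return dvgae.featurize(kg)

    def test_shapes_and_positive_sigma(self, feats):
        cfg = dvgae.EncoderConfig(latent_dim=8, seed=1)
        model = dvgae.DVGAE(cfg, feats.X.shape[1], feats.edge_feat.shape[1], feats.n_nodes)
        emb = model.encode(feats)
        assert emb.mu.shape == emb.sigma.shape == emb.z.shape == (feats.n_nodes, 8)
        assert np.all(emb.sigma > 0)

    def test_same_seed_is_deterministic(self, feats):
        cfg = dvgae.EncoderConfig(latent_dim=8, seed=1)
        m1 = dvgae.DVGAE(cfg, feats.X.shape[1], feats.edge_feat.shape[1], feats.n_nodes)
        m2 = dvgae.DVGAE(cfg, feats.X.shape[1], feats.edge_feat.shape[1], feats.n_nodes)
        e1, e2 = m1.encode(feats), m2.encode(feats)
        assert np.array_equal(e1.mu, e2.mu) and np.array_equal(e1.sigma, e2.sigma)

    def test_different_seeds_differ(self, feats):
        out = []
        for seed in (1, 2):
            cfg = dvgae.EncoderConfig(latent_dim=8, seed=seed)
            m = dvgae.DVGAE(cfg, feats.X.shape[1], feats.edge_feat.shape[1], feats.n_nodes)
            out.append(m.encode(feats).mu)
        assert not np.allclose(out[0], out[1])

    def test_backward_matches_finite_differences(self, feats):
        """Hand-written gradients agree with numeric differentiation of a
        smooth scalar functional of (mu, sigma)."""
        cfg = dvgae.EncoderConfig(latent_dim=3, seed=0, hidden_dim=5)
        model = dvgae.DVGAE(cfg, feats.X.shape[1], feats.edge_feat.shape[1], feats.n_nodes)
        rng = np.random.default_rng(2)
        Wm = rng.normal(size=(feats.n_nodes, 3))
        Ws = rng.normal(size=(feats.n_nodes, 3))

        def loss():
            mu, sigma, cache = model.forward(feats.X, feats.edge_index, feats.edge_feat)
            return float(np.sum(Wm * mu) + np.sum(Ws * sigma)), mu, sigma, cache

        _, mu, sigma, cache = loss()
        grads = model.backward(cache, Wm.copy(), Ws * 0.5 * sigma)
        glist = model._grad_list(grads)
        params = model.parameters()
        h = 1e-6
        checked = 0
        for pi, p in enumerate(params):
            flat = p.reshape(-1)
            if not flat.size:
                continue
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + h
                lp = loss()[0]
                flat[i] = orig - h
                lm = loss()[0]
                flat[i] = orig
                fd = (lp - lm) / (2 * h)
                an = glist[pi].reshape(-1)[i]
                assert abs(fd - an) <= 1e-4 * max(1.0, abs(fd)), (pi, i, fd, an)
                checked += 1
        assert checked > 30


class TestTraining:
    @pytest.fixture(scope="class")
    def small_cfg(self):
        return dvgae.EncoderConfig(
            learning_rate=0.01, epochs=5, latent_dim=8, batch_size=256
        )

    def test_single_config_grid_is_selected(self, tiny_sim, small_cfg):
        _, kg, _ = tiny_sim
        res = dvgae.train(kg, grid=[small_cfg], seed=3)
        assert res.config.key() == small_cfg.key()
        assert len(res.reports) == 1
        rep = res.reports[0]
        assert len(rep.trace) == small_cfg.epochs
        assert rep.total == pytest.approx(rep.recon + rep.kl / rep.n_nodes, abs=1e-9)

    def test_duplicated_config_yields_identical_reports(self, tiny_sim, small_cfg):
        _, kg, _ = tiny_sim
        res = dvgae.train(kg, grid=[small_cfg, small_cfg], seed=3)
        r1, r2 = res.reports
        assert r1.total == r2.total and r1.trace == r2.trace
        assert res.config is not None  # tie broken by grid order

    def test_validation_loss_decreases_on_reconstructible_graph(self, small_trained):
        # at the selected learning rate, epoch-100 validation loss beats epoch 1
        trace = small_trained["result"].reports[0].trace
        assert len(trace) == 100
        assert trace[-1] < trace[0]

    def test_empty_grid_rejected(self, tiny_sim):
        _, kg, _ = tiny_sim
        with pytest.raises(ValueError):
            dvgae.train(kg, grid=[], seed=0)

    def test_split_proportions_and_disjointness(self, tiny_sim):
        _, kg, _ = tiny_sim
        feats = dvgae.featurize(kg)
        split = dvgae.split_edges(feats, seed=9)
        n_train = split.train_edges.shape[1]
        n_val = split.validation_edges.shape[1]
        assert n_train + n_val == feats.n_edges
        assert abs(n_train - round(0.7 * feats.n_edges)) <= 1
        tr = set(map(tuple, split.train_edges.T))
        va = set(map(tuple, split.validation_edges.T))
        ne = set(map(tuple, split.negative_validation_edges.T))
        assert not tr & va
        assert not ne & (tr | va)
        assert len(ne) == n_val

    def test_export_embeddings_row_per_node(self, tiny_sim, small_cfg):
        _, kg, _ = tiny_sim
        res = dvgae.train(kg, grid=[small_cfg], seed=3)
        table = dvgae.export_embeddings(res, mode="mu")
        assert table.shape == (kg.n_nodes, small_cfg.latent_dim)
        table2 = dvgae.export_embeddings(res, mode="mu")
        assert table.equals(table2)

    def test_reconstruction_and_heldout_auc_on_low_rank_graph(self, small_trained):
        """With ground-truth low-rank structure, the trained model recovers
        >95% of edges at threshold 0.5 and separates held-out positive from
        sampled negative edges with AUC > 0.95."""
        result = small_trained["result"]
        kg = small_trained["kg"]
        acc = dvgae.edge_wise_accuracy(
            kg.directed_pairs(), dvgae.reconstruct_pairs(result.embeddings, 0.5)
        )
        assert acc > 0.95

        from sklearn.metrics import roc_auc_score

        mu = result.selection_embeddings.mu
        split = result.split
        s_pos = np.einsum(
            "ij,ij->i", mu[split.validation_edges[0]], mu[split.validation_edges[1]]
        )
        s_neg = np.einsum(
            "ij,ij->i",
            mu[split.negative_validation_edges[0]],
            mu[split.negative_validation_edges[1]],
        )
        y = np.r_[np.ones(len(s_pos)), np.zeros(len(s_neg))]
        assert roc_auc_score(y, np.r_[s_pos, s_neg]) > 0.95

    def test_export_requires_trained_model(self, tiny_sim, small_cfg):
        _, kg, _ = tiny_sim
        feats = dvgae.featurize(kg)
        model = dvgae.DVGAE(small_cfg, feats.X.shape[1], feats.edge_feat.shape[1], feats.n_nodes)
        fake = dvgae.TrainResult(model, small_cfg, feats, model.encode(feats), [], None)
        with pytest.raises(ValueError, match="untrained"):
            dvgae.export_embeddings(fake)
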