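import numpy as np
import pytest

from atompool.ego import PoolingConfig
from atompool.graph_io import Graph, GraphDataset
from atompool.network import (
    CVResult,
    ModelConfig,
    TrainConfig,
    atom_adjacency,
    atom_edge_list,
    atom_report,
    build_graph_cache,
    cross_validate,
    evaluate,
    forward,
    gcn_propagate,
    init_params,
    normalized_adjacency,
    readout,
    stratified_fold_indices,
    train_model,
)
from atompool.synthetic import MOTIF_LIBRARY, SyntheticConfig, generate_two_class_dataset

from .conftest import random_graph

PCFG = PoolingConfig(ego_size=4)
SMALL = ModelConfig(hidden_dim=8, mlp_hidden=6, dropout=0.5)


def tiny_dataset(seed=0, graphs_per_class=12, noise=0.0, shared=False):
    m0 = MOTIF_LIBRARY["clique4"]
    m1 = m0 if shared else MOTIF_LIBRARY["star5"]
    cfg = SyntheticConfig(
        motifs_per_class={0: ((m0, 2.0),), 1: ((m1, 2.0),)},
        graphs_per_class=graphs_per_class,
        noise_edge_prob=noise,
        bridge_edges=1,
        seed=seed,
    )
    return generate_two_class_dataset(cfg)[0]


class TestModelConfig:
    def test_pool_after_validated(self):
        with pytest.raises(ValueError):
            ModelConfig(conv_layers=3, pool_after=(3,))

    def test_gat_is_a_seam(self):
        with pytest.raises(NotImplementedError):
            ModelConfig(backbone="gat")

    def test_train_config_patience(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=10, patience=10)


class TestGCNPropagate:
    def test_single_node_identity_weight(self):
        x = np.array([[2.0, -3.0]])
        out = gcn_propagate(x, np.zeros((1, 1)), np.eye(2))
        assert np.allclose(out, [[2.0, 0.0]])  # ReLU of input

    def test_zero_features_give_zero(self, rng):
        g = random_graph(5, 0.5, rng)
        out = gcn_propagate(np.zeros((5, 3)), g.adjacency, rng.random((3, 4)))
        assert np.allclose(out, 0.0)

    def test_path_matches_dense_oracle(self):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        x = np.array([[1.0], [2.0], [3.0]])
        w = np.array([[1.5]])
        a_tilde = a + np.eye(3)
        d_inv = np.diag(1.0 / np.sqrt(a_tilde.sum(axis=1)))
        oracle = np.maximum(d_inv @ a_tilde @ d_inv @ x @ w, 0.0)
        assert np.allclose(gcn_propagate(x, a, w), oracle)

    def test_weighted_adjacency_supported(self, rng):
        a = np.array([[0.0, 2.5], [2.5, 0.0]])
        out = gcn_propagate(rng.random((2, 2)), a, np.eye(2))
        assert np.isfinite(out).all()


class TestReadout:
    def test_single_node(self):
        f = np.array([[1.0, -2.0]])
        assert np.allclose(readout(f), [1, -2, 1, -2, 1, -2])

    def test_two_identical_nodes(self):
        f = np.array([[1.0, 2.0], [1.0, 2.0]])
        assert np.allclose(readout(f), [1, 2, 1, 2, 2, 4])

    def test_matches_elementwise_oracle(self, rng):
        x = rng.standard_normal((7, 4))
        r = readout(x)
        assert np.allclose(r[:4], x.max(axis=0))
        assert np.allclose(r[4:8], x.mean(axis=0))
        assert np.allclose(r[8:], x.sum(axis=0))

    def test_zero_nodes_rejected(self):
        with pytest.raises(ValueError):
            readout(np.zeros((0, 3)))


class TestForward:
    def test_logit_length_is_class_count(self, rng):
        g = random_graph(9, 0.4, rng, feature_dim=3)
        cache = build_graph_cache(g, SMALL, PCFG)
        params = init_params(3, 4, SMALL, rng)
        assert forward(cache, params, SMALL).shape == (4,)

    def test_eval_forward_deterministic(self, rng):
        g = random_graph(9, 0.4, rng, feature_dim=2)
        cache = build_graph_cache(g, SMALL, PCFG)
        params = init_params(2, 2, SMALL, rng)
        l1 = forward(cache, params, SMALL)
        l2 = forward(cache, params, SMALL)
        assert np.array_equal(l1, l2)

    def test_feature_dim_mismatch(self, rng):
        g = random_graph(5, 0.4, rng, feature_dim=3)
        cache = build_graph_cache(g, SMALL, PCFG)
        params = init_params(2, 2, SMALL, rng)
        with pytest.raises(ValueError):
            forward(cache, params, SMALL)

    def test_identity_pooling_equals_plain_gcn(self, rng):
        # an edgeless graph triggers the identity-S fallback at both pool
        # layers; the model must then reduce to a plain 3-layer GCN whose
        # per-layer readouts are concatenated
        n, d = 5, 3
        g = Graph(adjacency=np.zeros((n, n)), features=rng.random((n, d)), label=0)
        cache = build_graph_cache(g, SMALL, PCFG)
        assert all(
            s is None or np.array_equal(s, np.eye(n)) for s in cache.s_after
        )
        params = init_params(d, 2, SMALL, rng)
        got = forward(cache, params, SMALL)

        x = g.features
        reads = []
        for l in range(3):
            x = gcn_propagate(x, np.zeros((n, n)), params[f"W{l}"])
            reads.append(readout(x))
        h = np.concatenate(reads)
        a1 = np.maximum(h @ params["Wm1"] + params["bm1"], 0.0)
        oracle = a1 @ params["Wm2"] + params["bm2"]
        assert np.allclose(got, oracle)

    def test_node_counts_shrink_geometrically(self, rng):
        g = random_graph(16, 0.35, rng)
        cache = build_graph_cache(g, SMALL, PCFG)
        n0, n1, n2 = cache.node_counts
        assert n0 == 16
        assert n1 <= int(np.ceil(n0 / 2))
        assert n2 <= int(np.ceil(n1 / 2))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        from atompool.network import _backward, _softmax

        g = random_graph(6, 0.5, rng, feature_dim=2)
        mcfg = ModelConfig(hidden_dim=4, mlp_hidden=3, dropout=0.0)
        cache = build_graph_cache(g, mcfg, PCFG)
        cache.label = 1
        params = init_params(2, 2, mcfg, rng)

        def loss_of(p):
            logits = forward(cache, p, mcfg)
            probs = _softmax(logits)
            return -np.log(probs[cache.label])

        logits, tape = forward(cache, params, mcfg, keep=True)
        probs = _softmax(logits)
        dlogits = probs.copy()
        dlogits[cache.label] -= 1.0
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        _backward(cache, params, mcfg, tape, dlogits, grads)

        eps = 1e-6
        for key in params:
            flat = params[key].reshape(-1)
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_of(params)
                flat[idx] = orig - eps
                down = loss_of(params)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[key].reshape(-1)[idx] == pytest.approx(
                    numeric, rel=1e-4, abs=1e-6
                ), key


class TestTraining:
    def test_one_class_training_reaches_full_accuracy(self, rng):
        graphs = [random_graph(6, 0.4, rng, feature_dim=2) for _ in range(8)]
        for g in graphs:
            g.label = 0
        caches = [build_graph_cache(g, SMALL, PCFG) for g in graphs]
        tcfg = TrainConfig(max_epochs=20, patience=10, batch_size=4, seed=0)
        params, history = train_model(caches, caches, n_classes=2, mcfg=SMALL, tcfg=tcfg)
        acc, _ = evaluate(caches, params, SMALL)
        assert acc == 1.0

    def test_zero_lr_stops_after_patience(self, rng):
        graphs = [random_graph(5, 0.4, rng, feature_dim=2) for _ in range(4)]
        for i, g in enumerate(graphs):
            g.label = i % 2
        caches = [build_graph_cache(g, SMALL, PCFG) for g in graphs]
        tcfg = TrainConfig(
            learning_rate=0.0, max_epochs=50, patience=1, batch_size=4, seed=0
        )
        _, history = train_model(caches, caches, 2, SMALL, tcfg)
        # epoch 0 improves over nothing, epoch 1 cannot improve -> stop at 2
        assert len(history["val_acc"]) == 2

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            train_model([], [], 2, SMALL, TrainConfig(max_epochs=2, patience=1))

    def test_learns_separable_synthetic_data(self):
        ds = tiny_dataset(seed=1, graphs_per_class=15)
        caches = [build_graph_cache(g, SMALL, PCFG) for g in ds]
        split = len(ds) * 2 // 3
        tcfg = TrainConfig(max_epochs=60, patience=30, batch_size=8, seed=0)
        params, _ = train_model(caches[:split], caches[split:], 2, SMALL, tcfg)
        acc, _ = evaluate(caches[split:], params, SMALL)
        assert acc >= 0.9

    def test_loss_trends_down(self):
        ds = tiny_dataset(seed=2, graphs_per_class=10)
        caches = [build_graph_cache(g, SMALL, PCFG) for g in ds]
        tcfg = TrainConfig(max_epochs=30, patience=29, batch_size=10, seed=0)
        _, history = train_model(caches, caches, 2, SMALL, tcfg)
        losses = history["train_loss"]
        assert np.mean(losses[-5:]) < np.mean(losses[:5])


class TestCrossValidation:
    def test_folds_partition_dataset(self):
        labels = np.array([0, 1] * 20)
        folds = stratified_fold_indices(labels, 5, seed=3)
        combined = np.sort(np.concatenate(folds))
        assert np.array_equal(combined, np.arange(40))

    def test_same_seed_same_split(self):
        labels = np.array([0, 1] * 25)
        a = stratified_fold_indices(labels, 10, seed=9)
        b = stratified_fold_indices(labels, 10, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_small_class_rejected(self):
        labels = np.array([0] * 20 + [1] * 3)
        with pytest.raises(ValueError, match="folds"):
            stratified_fold_indices(labels, 10, seed=0)

    def test_cv_result_stats(self):
        res = CVResult(fold_accuracies=(0.5, 1.0))
        assert res.mean == pytest.approx(0.75)
        assert res.std == pytest.approx(0.25)

    def test_cross_validate_runs(self):
        ds = tiny_dataset(seed=3, graphs_per_class=10)
        tcfg = TrainConfig(max_epochs=5, patience=3, batch_size=10, folds=2, seed=0)
        result, histories = cross_validate(ds, SMALL, tcfg, PCFG)
        assert len(result.fold_accuracies) == 2
        assert len(histories) == 2
        assert all(0.0 <= a <= 1.0 for a in result.fold_accuracies)


class TestAtomReport:
    def test_atom_adjacency_symmetrized(self):
        col = np.zeros(16, dtype=np.uint8)
        col[1] = 1  # (0,1) only in the upper triangle
        a = atom_adjacency(col, 4)
        assert a[0, 1] == a[1, 0] == 1
        assert np.diagonal(a).sum() == 0
        assert atom_edge_list(col, 4) == [(0, 1)]

    def test_single_graph_full_activation(self):
        from atompool.pooling import pool_layer

        a = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        g = Graph(adjacency=a, features=np.ones((3, 1)), label=0)
        ds = GraphDataset(graphs=[g], class_count=1, feature_dim=1)
        table = atom_report(ds, PoolingConfig(ego_size=3))
        # the triangle atom is assigned to every node of the only graph
        assert table["class_0_activation"].max() == pytest.approx(1.0)

    def test_absent_atom_has_zero_proportion(self):
        ds = tiny_dataset(seed=4, graphs_per_class=6)
        table = atom_report(ds, PoolingConfig(ego_size=5))
        assert not table.empty
        assert (table[["class_0_activation", "class_1_activation"]] >= 0).all().all()
        assert (table[["class_0_activation", "class_1_activation"]] <= 1).all().all()

    def test_planted_motifs_show_class_disparity(self):
        ds = tiny_dataset(seed=5, graphs_per_class=10)
        pcfg = PoolingConfig(ego_size=5)
        table = atom_report(ds, pcfg)

        def padded_edges(motif):
            out = np.zeros((5, 5), dtype=int)
            s = motif.adjacency.shape[0]
            out[:s, :s] = motif.adjacency
            return ";".join(
                f"{u}-{v}" for u, v in zip(*np.nonzero(np.triu(out)))
            )

        clique_row = table[table["edges"] == padded_edges(MOTIF_LIBRARY["clique4"])]
        star_row = table[table["edges"] == padded_edges(MOTIF_LIBRARY["star5"])]
        assert not clique_row.empty and not star_row.empty
        assert (
            clique_row["class_0_activation"].iloc[0]
            > clique_row["class_1_activation"].iloc[0]
        )
        assert (
            star_row["class_1_activation"].iloc[0]
            > star_row["class_0_activation"].iloc[0]
        )
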