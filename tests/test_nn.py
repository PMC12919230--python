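"""Masked forward pass, fusion, loss, and training-loop contracts."""

import numpy as np
import pytest

from motgnn import (
    LabelVector,
    OmicsMatrix,
    SyntheticConfig,
    TrainingConfig,
    bce_loss,
    build_motgnn,
    encode_modality,
    fuse_and_classify,
    generate_multiomics,
    graph_embedded_forward,
    load_checkpoint,
    predict_positive_proba,
    save_checkpoint,
    train_motgnn,
)
from motgnn.nn import ModalityEncoder, _l2_penalty
from motgnn.tree_graph import FeatureGraph


def _encoder(adjacency, depth=0, width=4, dropout=0.0, seed=0):
    ss = np.random.SeedSequence(seed)
    r1, r2 = [np.random.default_rng(s) for s in ss.spawn(2)]
    return ModalityEncoder(adjacency, depth, width, dropout, r1, r2)


def _graph(n, adjacency=None):
    nodes = [f"f{j}" for j in range(n)]
    A = np.eye(n, dtype=int) if adjacency is None else np.asarray(adjacency)
    edges = {
        (nodes[i], nodes[j])
        for i in range(n) for j in range(i, n) if A[i, j]
    }
    return FeatureGraph(1, nodes, edges, A, list(range(n)))


class TestGraphEmbeddedForward:
    def test_identity_mask_scales_columns_by_diagonal(self):
        enc = _encoder(np.eye(3))
        enc.W_in = np.diag([2.0, 3.0, 0.5]) + np.ones((3, 3))  # off-diag ignored
        enc.input_layer.b.value = np.zeros(3)
        x = np.array([[0.1, 0.2, 0.4], [0.3, 0.0, 1.0]])
        out = graph_embedded_forward(x, np.eye(3), enc)
        expected = x * np.array([3.0, 4.0, 1.5])  # diagonal entries of W_in
        assert np.allclose(out, expected, atol=1e-12)

    def test_hand_computed_dense_mask_product(self):
        enc = _encoder(np.ones((2, 2)))
        enc.W_in = np.array([[1.0, -1.0], [0.5, 1.0]])
        enc.input_layer.b.value = np.zeros(2)
        out = graph_embedded_forward(np.array([[1.0, 2.0]]), np.ones((2, 2)), enc)
        assert np.allclose(out, [[2.0, 1.0]], atol=1e-9)

    def test_zero_input_zero_bias_gives_zero(self):
        enc = _encoder(np.ones((3, 3)))
        enc.input_layer.b.value = np.zeros(3)
        out = graph_embedded_forward(np.zeros((4, 3)), np.ones((3, 3)), enc)
        assert np.array_equal(out, np.zeros((4, 3)))

    def test_shape_mismatch_raises(self):
        enc = _encoder(np.eye(3))
        with pytest.raises(ValueError, match="shape"):
            graph_embedded_forward(np.zeros((2, 4)), np.eye(3), enc)


class TestEncodeModality:
    def test_inference_is_deterministic(self):
        g = _graph(5)
        enc = _encoder(g.adjacency, depth=2, width=8, dropout=0.5)
        x = np.random.default_rng(0).random((6, 5))
        a = encode_modality(x, g, enc, train_mode=False)
        b = encode_modality(x, g, enc, train_mode=False)
        assert np.array_equal(a, b)

    def test_zero_depth_encoder_equals_graph_embedded_layer(self):
        g = _graph(4)
        enc = _encoder(g.adjacency, depth=0)
        x = np.random.default_rng(1).random((5, 4))
        assert np.array_equal(
            encode_modality(x, g, enc, train_mode=False),
            graph_embedded_forward(x, g.adjacency, enc),
        )

    def test_masked_weight_positions_are_inert(self):
        A = np.eye(6, dtype=int)
        A[0, 1] = A[1, 0] = 1
        g = _graph(6, A)
        enc = _encoder(g.adjacency, depth=1, width=8)
        x = np.random.default_rng(2).random((7, 6))
        before = encode_modality(x, g, enc, train_mode=False)
        rng = np.random.default_rng(3)
        enc.W_in = enc.W_in + rng.normal(0, 10.0, size=(6, 6)) * (1 - A)
        after = encode_modality(x, g, enc, train_mode=False)
        assert np.array_equal(before, after)

    def test_column_count_mismatch_raises(self):
        g = _graph(4)
        enc = _encoder(g.adjacency)
        with pytest.raises(ValueError, match="col_map"):
            encode_modality(np.zeros((2, 5)), g, enc)


class TestFuseAndClassify:
    @pytest.fixture()
    def zero_classifier(self):
        cfg = TrainingConfig(depth=0, width=4, dropout=0.0, seed=0)
        model = build_motgnn([_graph(2), _graph(2), _graph(2)], cfg)
        clf = model.fusion
        clf.fuse.w.value[:] = 0.0
        clf.head.w.value[:] = 0.0
        clf.head.b.value[:] = 0.0
        return clf

    def test_zero_weights_give_half_half(self, zero_classifier):
        z = np.random.default_rng(0).random((5, 2))
        probs = fuse_and_classify(z, z, z, zero_classifier)
        assert np.allclose(probs, 0.5, atol=1e-12)

    def test_hand_softmax_quarter_three_quarters(self, zero_classifier):
        zero_classifier.head.b.value = np.array([0.0, np.log(3.0)])
        z = np.zeros((3, 2))
        probs = fuse_and_classify(z, z, z, zero_classifier)
        assert np.allclose(probs, [[0.25, 0.75]] * 3, atol=1e-9)

    def test_rows_sum_to_one(self):
        cfg = TrainingConfig(depth=1, width=8, dropout=0.0, seed=1)
        model = build_motgnn([_graph(3), _graph(3), _graph(3)], cfg)
        z = np.random.default_rng(4).random((10, 8))
        probs = fuse_and_classify(z, z, z, model.fusion)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_permuting_samples_permutes_outputs(self):
        cfg = TrainingConfig(depth=1, width=8, dropout=0.0, seed=2)
        model = build_motgnn([_graph(3), _graph(3), _graph(3)], cfg)
        rng = np.random.default_rng(5)
        zs = [rng.random((6, 8)) for _ in range(3)]
        perm = rng.permutation(6)
        direct = fuse_and_classify(*zs, model.fusion)[perm]
        permuted = fuse_and_classify(*(z[perm] for z in zs), model.fusion)
        assert np.allclose(direct, permuted, atol=1e-12)

    def test_sample_count_mismatch_raises(self, zero_classifier):
        with pytest.raises(ValueError, match="sample counts"):
            fuse_and_classify(np.zeros((2, 2)), np.zeros((3, 2)), np.zeros((2, 2)),
                              zero_classifier)


class TestBceLoss:
    def test_single_uncertain_positive_gives_ln2(self):
        assert bce_loss([1], [0.5]) == pytest.approx(np.log(2.0), abs=1e-9)

    def test_mixed_pair_gives_ln2(self):
        assert bce_loss([0, 1], [0.5, 0.5]) == pytest.approx(np.log(2.0), abs=1e-9)

    def test_perfect_predictions_give_near_zero_loss(self):
        assert bce_loss([1, 0], [1.0, 0.0]) <= 1.2e-7

    def test_loss_finite_on_extreme_probabilities(self):
        assert np.isfinite(bce_loss([1, 0, 1], [0.0, 1.0, 1.0]))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            bce_loss([1, 0], [0.5])


def test_l2_penalty_strictly_positive_on_nonzero_weights():
    cfg = TrainingConfig(depth=1, width=8, dropout=0.0, seed=0)
    model = build_motgnn([_graph(3), _graph(3), _graph(3)], cfg)
    assert _l2_penalty(model, 0.01) > 0.0
    assert _l2_penalty(model, 0.0) == 0.0


@pytest.fixture(scope="module")
def easy_data():
    cfg = SyntheticConfig(
        n_samples=120, dims=(20, 20, 10), informative_per_modality=(5, 5, 3),
        effect_size=2.0, noise_sd=0.2, seed=8,
    )
    X, y, _ = generate_multiomics(cfg)
    graphs = [_full_graph(m) for m in X]
    idx = np.arange(120)
    return X, y, graphs, idx[:80], idx[80:]


class TestTrainMotgnn:
    def test_separable_data_reaches_high_train_accuracy(self, easy_data):
        X, y, graphs, tr, va = easy_data
        cfg = TrainingConfig(seed=0, learning_rate=1e-3, epochs=150)
        model, _ = train_motgnn(X, y, graphs, cfg, tr, va)
        prob = predict_positive_proba(model, graphs, X, tr)
        acc = ((prob >= 0.5).astype(int) == y.labels[tr]).mean()
        assert acc >= 0.95

    def test_same_seed_gives_identical_loss_history(self, easy_data):
        X, y, graphs, tr, va = easy_data
        cfg = TrainingConfig(seed=3, learning_rate=1e-3, epochs=15, patience=15)
        _, h1 = train_motgnn(X, y, graphs, cfg, tr, va)
        _, h2 = train_motgnn(X, y, graphs, cfg, tr, va)
        assert h1 == h2

    def test_huge_min_delta_stops_at_first_non_improving_epoch(self, easy_data):
        X, y, graphs, tr, va = easy_data
        cfg = TrainingConfig(seed=0, epochs=100, patience=1, min_delta=1e9)
        _, history = train_motgnn(X, y, graphs, cfg, tr, va)
        assert len(history) == 2  # epoch 1 beats inf; epoch 2 cannot improve

    def test_single_class_validation_split_rejected(self, easy_data):
        X, y, graphs, tr, _ = easy_data
        val = np.flatnonzero(y.labels == 1)[:5]
        with pytest.raises(ValueError, match="validation stratum"):
            train_motgnn(X, y, graphs, TrainingConfig(), tr, val)

    def test_checkpoint_roundtrip_preserves_predictions(self, easy_data, tmp_path):
        X, y, graphs, tr, va = easy_data
        cfg = TrainingConfig(seed=1, learning_rate=1e-3, epochs=10, patience=10)
        model, _ = train_motgnn(X, y, graphs, cfg, tr, va)
        save_checkpoint(model, graphs, cfg, tmp_path / "ckpt")
        loaded, graphs2, cfg2 = load_checkpoint(tmp_path / "ckpt")
        p1 = predict_positive_proba(model, graphs, X, va)
        p2 = predict_positive_proba(loaded, graphs2, X, va)
        assert np.array_equal(p1, p2)
        assert cfg2 == cfg


def _full_graph(m):
    """Fully connected feature graph over all columns of a matrix."""
    p = m.n_features
    A = np.ones((p, p), dtype=int)
    edges = {
        (min(a, b), max(a, b))
        for i, a in enumerate(m.feature_names)
        for b in m.feature_names[i:]
    }
    return FeatureGraph(m.modality_id, list(m.feature_names), edges, A, list(range(p)))
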