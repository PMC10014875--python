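"""Classifier construction, gradients, training callbacks, persistence."""

import numpy as np
import pytest

from explore import _nn
from explore.errors import ConsistencyError, FormatError, SchemaError
from explore.labeling import ClassCounts, ClassScheme, compute_class_weights
from explore.network import (
    FrameClassifier, NetworkSpec, build_network, load_model,
)


def _colour_dataset(rng, n=90, size=14, K=3):
    """Trivially separable frames: class k lights up colour channel k."""
    X = np.zeros((n, size, size, 3), dtype=np.uint8)
    y = np.asarray([i % K for i in range(n)])
    for i, c in enumerate(y):
        X[i, :, :, c % 3] = 180 + int(rng.integers(0, 40))
    return X, y


class TestBuildNetwork:
    def test_parameter_count_matches_hand_arithmetic(self):
        """Layer-by-layer count for the full-size spec, derived
        independently: conv f_out*(9*f_in+1), dense n_out*(n_in+1),
        with valid 3x3 convs and 2x2 pools shrinking 150 to 7."""
        conv = 32 * (9 * 3 + 1) + 64 * (9 * 32 + 1) + 128 * (9 * 64 + 1) \
            + 256 * (9 * 128 + 1)
        # 150 ->conv 148 ->pool 74 ->conv 72 ->pool 36 ->conv 34 ->pool 17
        # ->conv 15 ->pool 7 ; flatten = 7*7*256 = 12544
        dense = 500 * (12544 + 1) + 500 * (500 + 1)
        out = 3 * (500 + 1)
        _, n_params = build_network(NetworkSpec(), K=3)
        assert n_params == conv + dense + out == 6_912_919

    def test_multiclass_head_is_softmax_over_K(self, tiny_spec):
        net, _ = build_network(tiny_spec, K=3)
        x = np.random.default_rng(0).random((2, 14, 14, 3), dtype=np.float32)
        logits = net.forward(x)
        assert logits.shape == (2, 3)
        probs = _nn.softmax(logits)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_binary_head_is_single_unit(self, tiny_spec):
        net, _ = build_network(tiny_spec, K=2)
        x = np.random.default_rng(0).random((2, 14, 14, 3), dtype=np.float32)
        assert net.forward(x).shape == (2, 1)

    def test_fewer_than_two_classes_rejected(self, tiny_spec):
        with pytest.raises(ConsistencyError):
            build_network(tiny_spec, K=1)


class TestGradients:
    def test_backward_matches_directional_derivative(self, tiny_spec, rng):
        """The analytic gradient must match d loss / d t along random
        parameter directions (central differences, all layers at once)."""
        net, _ = build_network(tiny_spec, K=3, seed=1)
        x = rng.random((4, 14, 14, 3)).astype(np.float32)
        y = np.array([0, 1, 2, 1])

        def loss():
            return _nn.softmax_xent(net.forward(x, train=True), y)

        _, d = loss()
        net.backward(d)
        grads = [g.copy() for g in net.grads]
        eps = 1e-4
        for _ in range(3):
            direction = [rng.normal(size=p.shape).astype(np.float32)
                         for p in net.params]
            analytic = sum(float((g * dd).sum()) for g, dd in zip(grads, direction))
            for p, dd in zip(net.params, direction):
                p += eps * dd
            lp, _ = loss()
            for p, dd in zip(net.params, direction):
                p -= 2 * eps * dd
            lm, _ = loss()
            for p, dd in zip(net.params, direction):
                p += eps * dd
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(analytic, rel=1e-2, abs=1e-4)


class TestLossWeighting:
    def test_unit_weights_equal_unweighted_loss(self, rng):
        logits = rng.normal(size=(20, 4)).astype(np.float32)
        y = rng.integers(0, 4, 20)
        unweighted, _ = _nn.softmax_xent(logits, y)
        weighted, _ = _nn.softmax_xent(logits, y, np.ones(20))
        assert unweighted == pytest.approx(weighted, abs=1e-12)

    def test_binary_unit_weights_equal_unweighted(self, rng):
        logits = rng.normal(size=(12, 1)).astype(np.float32)
        y = rng.integers(0, 2, 12)
        a, _ = _nn.binary_xent(logits, y)
        b, _ = _nn.binary_xent(logits, y, np.ones(12))
        assert a == pytest.approx(b, abs=1e-12)

    def test_class_weights_rescale_per_sample_loss(self, rng):
        logits = rng.normal(size=(10, 3)).astype(np.float32)
        y = np.zeros(10, dtype=np.int64)
        base, _ = _nn.softmax_xent(logits, y)
        double, _ = _nn.softmax_xent(logits, y, np.full(10, 2.0))
        assert double == pytest.approx(2 * base)


class TestTrainingLoop:
    def test_flat_validation_loss_early_stops_after_patience(self, tiny_spec, rng):
        """With a zero learning rate the validation loss never improves,
        so training must stop after 1 + patience + 1 epochs."""
        X, y = _colour_dataset(rng)
        spec = NetworkSpec(**{**tiny_spec.__dict__, "learning_rate": 0.0,
                              "min_learning_rate": 0.0})
        res = FrameClassifier(X, y, ClassScheme.for_objects(2), spec=spec).fit(seed=0)
        assert res.history.stop_reason == "early_stop"
        assert res.history.epochs_run <= 1 + spec.early_stop_patience + 1

    def test_lr_reduced_on_plateau(self, tiny_spec, rng):
        # an infinitesimal learning rate leaves float32 weights (and so
        # the validation loss) unchanged -> a clean plateau
        X, y = _colour_dataset(rng)
        spec = NetworkSpec(**{**tiny_spec.__dict__, "learning_rate": 1e-30,
                              "min_learning_rate": 0.0})
        res = FrameClassifier(X, y, ClassScheme.for_objects(2), spec=spec).fit(seed=0)
        lrs = res.history.learning_rate
        assert lrs[-1] < lrs[0]
        assert lrs[-1] == pytest.approx(lrs[0] * spec.lr_plateau_factor)

    def test_epoch_cap_respected(self, tiny_spec, rng):
        X, y = _colour_dataset(rng, n=45)
        res = FrameClassifier(X, y, ClassScheme.for_objects(2), spec=tiny_spec).fit(
            seed=0, epochs=2
        )
        assert res.history.epochs_run <= 2

    def test_learns_colour_separable_task(self, tiny_spec, rng):
        """500 labeled frames of a trivially colour-separable 3-class
        problem must be fit almost perfectly within the epoch budget."""
        X, y = _colour_dataset(rng, n=500)
        counts = ClassCounts.from_labels(y, 3)
        res = FrameClassifier(
            X, y, ClassScheme.for_objects(2),
            class_weights=compute_class_weights(counts), spec=tiny_spec,
        ).fit(seed=0)
        assert res.history.train_acc[-1] >= 0.95

    def test_seeded_refit_reproduces_history(self, tiny_spec, rng):
        X, y = _colour_dataset(rng, n=60)
        model = FrameClassifier(X, y, ClassScheme.for_objects(2), spec=tiny_spec)
        a = model.fit(seed=3, epochs=3)
        b = model.fit(seed=3, epochs=3)
        assert abs(a.history.val_loss[-1] - b.history.val_loss[-1]) < 1e-3

    def test_empty_training_set_rejected(self, tiny_spec, scheme3):
        with pytest.raises(ConsistencyError):
            FrameClassifier(np.zeros((0, 14, 14, 3)), np.zeros(0), scheme3,
                            spec=tiny_spec)


class TestPrediction:
    @pytest.fixture()
    def fitted(self, tiny_spec):
        rng = np.random.default_rng(5)
        X, y = _colour_dataset(rng, n=120)
        return FrameClassifier(X, y, ClassScheme.for_objects(2), spec=tiny_spec).fit(
            seed=1, epochs=4
        ), X

    def test_probability_rows_sum_to_one(self, fitted):
        res, X = fitted
        track = res.predict_frames(X[:30], fps=25.0, video_id="v")
        assert len(track) == 30
        np.testing.assert_allclose(track.probabilities.sum(axis=1), 1.0, atol=1e-6)
        assert track.K == 3

    def test_binary_tie_breaks_to_class_zero(self, tiny_spec, rng):
        X, y = _colour_dataset(rng, n=30, K=2)
        res = FrameClassifier(X, y, ClassScheme.for_objects(1), spec=tiny_spec).fit(
            seed=0, epochs=1
        )
        # zero the output layer: every logit becomes exactly 0 -> p = 0.5
        res.net.params[-2][...] = 0
        res.net.params[-1][...] = 0
        track = res.predict_frames(X[:5], fps=25.0)
        np.testing.assert_allclose(track.probabilities, 0.5)
        assert (track.hard_classes == 0).all()

    def test_wrong_input_shape_rejected(self, fitted):
        res, _ = fitted
        with pytest.raises(ConsistencyError):
            res.predict_frames(np.zeros((2, 10, 10, 3), dtype=np.uint8), fps=25.0)


class TestPersistence:
    def test_save_load_round_trip_identical_predictions(self, tiny_spec, rng, tmp_path):
        X, y = _colour_dataset(rng, n=60)
        res = FrameClassifier(X, y, ClassScheme.for_objects(2), spec=tiny_spec).fit(
            seed=2, epochs=2
        )
        path = tmp_path / "model.h5"
        res.save(path)
        back = load_model(path)
        a = res.predict_frames(X[:10], fps=25.0)
        b = back.predict_frames(X[:10], fps=25.0)
        np.testing.assert_array_equal(a.hard_classes, b.hard_classes)
        np.testing.assert_allclose(a.probabilities, b.probabilities, atol=1e-6)

    def test_truncated_file_raises_format_error(self, tmp_path):
        path = tmp_path / "model.h5"
        path.write_bytes(b"\x89HDF\r\n\x1a\n" + b"\x00" * 20)
        with pytest.raises(FormatError):
            load_model(path)

    def test_scheme_mismatch_raises_schema_error(self, tiny_spec, rng, tmp_path):
        X, y = _colour_dataset(rng, n=45)
        res = FrameClassifier(X, y, ClassScheme.for_objects(2), spec=tiny_spec).fit(
            seed=0, epochs=1
        )
        path = tmp_path / "model.h5"
        res.save(path)
        with pytest.raises(SchemaError):
            load_model(path, scheme=ClassScheme.for_objects(1))
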