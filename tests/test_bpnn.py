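import json

import numpy as np
import pytest

import seedvision as sv
from seedvision.bpnn import (
    forward, gradients, one_hot, predict_batch, train_classifier,
)


def blob_data(n=200, sigma=0.05, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0.2, sigma, (n // 2, 2)),
                   rng.normal(0.8, sigma, (n // 2, 2))])
    labels = ["good"] * (n // 2) + ["ng"] * (n // 2)
    return np.clip(X, 0, 1), labels


class TestSizing:
    @pytest.mark.parametrize("ni, no, expected", [(10, 2, 6), (9, 2, 6), (2, 2, 2)])
    def test_hidden_node_rule(self, ni, no, expected):
        assert sv.hidden_nodes(ni, no) == expected

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            sv.hidden_nodes(0, 2)


class TestNormalization:
    def test_linear_map(self):
        bounds = sv.normalize_fit(np.array([[0.0], [5.0], [10.0]]))
        np.testing.assert_array_equal(
            sv.normalize_apply(bounds, np.array([[0.0], [5.0], [10.0]])),
            np.array([[0.0], [0.5], [1.0]]))

    def test_out_of_range_clipped(self):
        bounds = np.array([[0.0], [10.0]])
        assert sv.normalize_apply(bounds, np.array([20.0])) == 1.0
        assert sv.normalize_apply(bounds, np.array([-3.0])) == 0.0

    def test_roundtrip_hits_unit_interval_extremes(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4)) * rng.uniform(1, 50, 4)
        scaled = sv.normalize_apply(sv.normalize_fit(X), X)
        np.testing.assert_allclose(scaled.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(scaled.max(axis=0), 1.0, atol=1e-12)

    def test_constant_feature_error_names_column(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValueError, match=r"\[1\]"):
            sv.normalize_fit(X)


class TestGradients:
    def test_analytic_matches_central_differences(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            ni, nh, no = rng.integers(1, 5, size=3)
            w1 = rng.normal(size=(nh, ni))
            b1 = rng.normal(size=nh)
            w2 = rng.normal(size=(no, nh))
            b2 = rng.normal(size=no)
            x = rng.random(ni)
            t = rng.random(no)

            def loss(w1, b1, w2, b2):
                _, o = forward(w1, b1, w2, b2, x)
                return np.mean((t - o) ** 2)

            analytic = gradients(w1, b1, w2, b2, x, t)
            eps = 1e-6
            for gi, arr in enumerate((w1, b1, w2, b2)):
                num = np.zeros_like(arr)
                it = np.nditer(arr, flags=["multi_index"])
                while not it.finished:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    hi = loss(w1, b1, w2, b2)
                    arr[idx] = orig - eps
                    lo = loss(w1, b1, w2, b2)
                    arr[idx] = orig
                    num[idx] = (hi - lo) / (2 * eps)
                    it.iternext()
                rel = (np.linalg.norm(analytic[gi] - num)
                       / max(np.linalg.norm(num), 1e-10))
                assert rel < 1e-6


class TestTraining:
    def test_separable_blobs_converge(self):
        X, labels = blob_data()
        model = sv.train(X, one_hot(labels), sv.TrainConfig(rng_seed=1))
        assert model.converged and model.final_mse < 0.01
        pred = predict_batch(model, X)
        assert np.mean([p == l for p, l in zip(pred, labels)]) >= 0.99

    def test_holdout_accuracy(self):
        X, labels = blob_data(seed=0)
        model = sv.train(X, one_hot(labels), sv.TrainConfig(rng_seed=1))
        Xv, labv = blob_data(seed=99)
        pred = predict_batch(model, Xv)
        assert np.mean([p == l for p, l in zip(pred, labv)]) >= 0.95

    def test_memorizes_one_sample_per_class(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        labels = ["good", "ng"]
        # two samples per epoch at lr 0.01 converge slowly; allow extra epochs
        model = sv.train(X, one_hot(labels), sv.TrainConfig(rng_seed=3, max_epochs=50_000))
        assert model.converged
        assert predict_batch(model, X) == labels

    def test_seeded_determinism_is_bitwise(self):
        X, labels = blob_data(n=60)
        cfg = sv.TrainConfig(rng_seed=5)
        m1 = sv.train(X, one_hot(labels), cfg)
        m2 = sv.train(X, one_hot(labels), cfg)
        assert np.array_equal(m1.w1, m2.w1) and np.array_equal(m1.w2, m2.w2)
        assert np.array_equal(m1.b1, m2.b1) and np.array_equal(m1.b2, m2.b2)

    def test_nan_input_rejected(self):
        X = np.array([[0.1, np.nan], [0.9, 0.9]])
        with pytest.raises(ValueError, match="NaN"):
            sv.train(X, one_hot(["good", "ng"]), sv.TrainConfig())

    def test_single_class_rejected(self):
        X = np.array([[0.1, 0.1], [0.9, 0.9]])
        with pytest.raises(ValueError, match="class"):
            sv.train(X, one_hot(["good", "good"]), sv.TrainConfig())

    def test_nonconvergence_flagged_but_model_returned(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 2))
        labels = ["good", "ng"] * 20  # labels independent of features
        with pytest.warns(UserWarning, match="did not reach"):
            model = sv.train(X, one_hot(labels), sv.TrainConfig(max_epochs=50))
        assert not model.converged


class TestPredictAndCombine:
    def test_argmax_and_tie_rule(self, monkeypatch):
        X, labels = blob_data(n=40)
        model = sv.train(X, one_hot(labels), sv.TrainConfig(rng_seed=1))
        label, outputs = sv.predict(model, X[0])
        assert label == ("good" if outputs[0] > outputs[1] else "ng")
        # force a tie by zeroing the output layer: sigmoid(b2) equal
        model.w2[:] = 0.0
        model.b2[:] = 0.3
        label, outputs = sv.predict(model, X[0])
        assert outputs[0] == outputs[1] and label == "ng"

    def test_length_mismatch(self):
        X, labels = blob_data(n=40)
        model = sv.train(X, one_hot(labels), sv.TrainConfig(rng_seed=1))
        with pytest.raises(ValueError, match="length"):
            sv.predict(model, np.zeros(5))

    @pytest.mark.parametrize("a, b, expected", [
        ("good", "good", "good"), ("good", "ng", "ng"),
        ("ng", "good", "ng"), ("ng", "ng", "ng"),
    ])
    def test_and_rule(self, a, b, expected):
        assert sv.combine(a, b) == expected

    def test_combine_rejects_unknown_label(self):
        with pytest.raises(ValueError):
            sv.combine("good", "maybe")


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        X = rng.random((30, 3)) * np.array([10.0, 5.0, 1.0])
        labels = ["good"] * 15 + ["ng"] * 15
        X[:15] += 5.0
        model = train_classifier(X, labels, sv.TrainConfig(rng_seed=2, max_epochs=500),
                                 feature_columns=["a", "b", "c"])
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = sv.BPNNModel.from_json(path)
        assert loaded.feature_columns == ["a", "b", "c"]
        np.testing.assert_array_equal(loaded.w1, model.w1)
        np.testing.assert_array_equal(loaded.bounds, model.bounds)
        assert json.loads(model.to_json())["n_hidden"] == model.n_hidden
        row = X[0]
        assert sv.predict(loaded, row)[0] == sv.predict(model, row)[0]
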