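import numpy as np
import pytest

from drivefatigue import bpnn
from drivefatigue.bpnn import (
    MLPConfig,
    MLPModel,
    forward,
    gradients,
    init_model,
    load_model,
    one_hot_targets,
    predict,
    save_model,
    train,
)
from drivefatigue.signal_io import FatigueLabel


class TestInit:
    def test_default_shapes(self):
        model = init_model(MLPConfig(seed=1))
        assert [w.shape for w in model.weights] == [(6, 2), (6, 6), (3, 6)]
        assert [b.shape for b in model.biases] == [(6,), (6,), (3,)]

    def test_seed_determinism(self):
        a = init_model(MLPConfig(seed=7))
        b = init_model(MLPConfig(seed=7))
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_zero_scale(self):
        model = init_model(MLPConfig(init_scale=0.0))
        assert all(np.all(w == 0) for w in model.weights)
        assert all(np.all(b == 0) for b in model.biases)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MLPConfig(layer_sizes=(2, 3))
        with pytest.raises(ValueError):
            MLPConfig(momentum=1.0)
        with pytest.raises(ValueError):
            MLPConfig(layer_sizes=(2, 0, 3))


class TestForward:
    def test_zero_parameters_zero_output(self):
        model = init_model(MLPConfig(init_scale=0.0))
        _, out = forward(model, [0.3, -1.2])
        np.testing.assert_array_equal(out, np.zeros((1, 3)))

    def test_single_unit_closed_form(self):
        cfg = MLPConfig(layer_sizes=(1, 1, 1), init_scale=0.0)
        model = init_model(cfg)
        model.weights = [np.array([[1.0]]), np.array([[1.0]])]
        model.biases = [np.zeros(1), np.zeros(1)]
        _, out = forward(model, [0.5])
        assert out[0, 0] == pytest.approx(np.tanh(np.tanh(0.5)))

    def test_outputs_strictly_inside_unit_interval(self, rng):
        # (-1, 1) holds exactly in floats for pre-activations below ~19
        model = init_model(MLPConfig(seed=3, init_scale=2.0))
        for _ in range(20):
            _, out = forward(model, rng.normal(size=2))
            assert np.all(np.abs(out) < 1.0)

    def test_dimension_mismatch(self):
        model = init_model(MLPConfig())
        with pytest.raises(ValueError):
            forward(model, [1.0, 2.0, 3.0])


class TestGradients:
    def test_matches_finite_differences(self):
        """Analytic backprop equals central finite differences on a 2-3-2 net."""
        cfg = MLPConfig(layer_sizes=(2, 3, 2), seed=20)
        model = init_model(cfg)
        rng = np.random.default_rng(21)
        X = rng.normal(size=(7, 2))
        Y = rng.uniform(-0.9, 0.9, size=(7, 2))
        dW, dB, _ = gradients(model, X, Y)
        eps = 1e-6

        def mse():
            _, out = forward(model, X)
            return np.mean((out - Y) ** 2)

        for l in range(len(model.weights)):
            for arr, grad in ((model.weights[l], dW[l]), (model.biases[l], dB[l])):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    hi = mse()
                    arr[idx] = orig - eps
                    lo = mse()
                    arr[idx] = orig
                    numeric = (hi - lo) / (2 * eps)
                    denom = max(abs(numeric), abs(grad[idx]), 1e-12)
                    assert abs(grad[idx] - numeric) / denom < 1e-6


class TestTrain:
    def test_xor_learnable(self):
        """XOR reaches MSE <= 1e-3 within 5000 epochs for >= 9/10 seeds with
        the default hyperparameters (lr 0.082, momentum 0.95, tanh)."""
        X = np.array([[-1, -1], [-1, 1], [1, -1], [1, 1]], dtype=float)
        Y = np.array([[-0.9], [0.9], [0.9], [-0.9]])
        successes = 0
        for seed in range(10):
            cfg = MLPConfig(layer_sizes=(2, 2, 1), mse_goal=1e-3,
                            max_epochs=5000, seed=seed)
            model, trace = train(init_model(cfg), X, Y, standardize=False)
            if model.final_mse <= 1e-3:
                successes += 1
        assert successes >= 9

    def test_separable_blobs_perfect_training_accuracy(self):
        rng = np.random.default_rng(5)
        n = 50
        X = np.vstack([rng.normal(loc=(-3, 0), size=(n, 2)),
                       rng.normal(loc=(3, 0), size=(n, 2))])
        labels = np.repeat([0, 1], n)
        Y = one_hot_targets(labels, 3)
        cfg = MLPConfig(max_epochs=2000, seed=0)
        model, _ = train(init_model(cfg), X, Y)
        preds = bpnn.predict_batch(model, X)
        assert np.mean(preds == labels) == 1.0

    def test_momentum_zero_equals_plain_gradient_descent(self):
        # one epoch with momentum 0 and no adaptation is w -= lr * grad
        cfg = MLPConfig(layer_sizes=(1, 1, 1), momentum=0.0, lr_init=0.01,
                        lr_increase=1.0, lr_decrease=1.0, max_epochs=1,
                        init_scale=0.0, mse_goal=1e-30)
        model = init_model(cfg)
        for w in model.weights:
            w[:] = 0.1
        X = np.array([[1.0]])
        Y = np.array([[0.5]])
        dW, dB, _ = gradients(model, X, Y)
        expected_w = [0.1 - 0.01 * g[0, 0] for g in dW]
        expected_b = [-0.01 * g[0] for g in dB]
        trained, _ = train(model, X, Y, standardize=False)
        for l in range(2):
            assert trained.weights[l][0, 0] == pytest.approx(expected_w[l], rel=1e-12)
            assert trained.biases[l][0] == pytest.approx(expected_b[l], rel=1e-12)

    def test_trace_non_increasing_with_strict_rejection(self, rng):
        cfg = MLPConfig(max_mse_growth=1.0, max_epochs=300, seed=2)
        X = rng.normal(size=(30, 2))
        Y = one_hot_targets(rng.integers(0, 3, size=30))
        _, trace = train(init_model(cfg), X, Y)
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-15)

    def test_adaptive_rate_bounds_accepted_growth(self, rng):
        cfg = MLPConfig(max_epochs=500, seed=4)
        X = rng.normal(size=(40, 2))
        Y = one_hot_targets(rng.integers(0, 3, size=40))
        _, trace = train(init_model(cfg), X, Y)
        ratios = np.array(trace[1:]) / np.array(trace[:-1])
        assert np.all(ratios <= cfg.max_mse_growth + 1e-12)

    def test_standardization_stored(self, rng):
        X = rng.normal(loc=10.0, scale=3.0, size=(20, 2))
        Y = one_hot_targets(rng.integers(0, 3, size=20))
        model, _ = train(init_model(MLPConfig(max_epochs=5)), X, Y)
        np.testing.assert_allclose(model.x_mean, X.mean(axis=0))
        np.testing.assert_allclose(model.x_std, X.std(axis=0))


class TestPredict:
    def test_argmax_decoding(self):
        model = init_model(MLPConfig(init_scale=0.0))
        model.biases[-1] = np.arctanh(np.array([0.8, -0.2, -0.7]))
        label, out = predict(model, [0.0, 0.0])
        assert label is FatigueLabel.AWAKE
        np.testing.assert_allclose(out, [0.8, -0.2, -0.7], atol=1e-12)

    def test_tie_breaks_toward_lower_level(self):
        model = init_model(MLPConfig(init_scale=0.0))
        label, out = predict(model, [1.0, -1.0])
        np.testing.assert_array_equal(out, np.zeros(3))
        assert label is FatigueLabel.AWAKE

    def test_agrees_with_forward_argmax(self, rng):
        for seed in range(20):
            model = init_model(MLPConfig(seed=seed))
            x = rng.normal(size=2)
            label, _ = predict(model, x)
            _, out = forward(model, x)
            assert int(label) == int(np.argmax(out[0]))


class TestSerialization:
    def test_round_trip_bitwise_predictions(self, tmp_path, rng):
        X = rng.normal(size=(30, 2))
        Y = one_hot_targets(rng.integers(0, 3, size=30))
        model, _ = train(init_model(MLPConfig(max_epochs=50, seed=9)), X, Y)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        for w1, w2 in zip(model.weights, loaded.weights):
            np.testing.assert_array_equal(w1, w2)
        for x in rng.normal(size=(10, 2)):
            _, out1 = predict(model, x)
            _, out2 = predict(loaded, x)
            np.testing.assert_array_equal(out1, out2)
        assert loaded.config == model.config
        assert loaded.trained_epochs == model.trained_epochs
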