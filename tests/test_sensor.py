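"""Perceptron sensor: forward pass, metrics, CV mechanics, persistence."""

import math

import numpy as np
import pytest

from chaossensor import (
    ChaosSensor, SensorWeights, TrainingConfig, build_equal_weight_model,
    load_model, predict_entropy, regression_metrics, save_model,
    smooth_predictions, train_test_cross,
)
from chaossensor.datasets import WindowedDataset

from .oracles import perceptron_forward_naive


def _random_weights(nl, nh, seed=0, norm=0.0):
    rng = np.random.default_rng(seed)
    return SensorWeights(
        nl=nl, nh=nh, norm_const=norm,
        w_in=rng.normal(size=(nh, nl)), b_in=rng.normal(size=nh),
        w_out=rng.normal(size=nh), b_out=float(rng.normal()),
    )


def _mean_dataset(n=300, nl=10, seed=0):
    """Synthetic task: the target is the window mean."""
    rng = np.random.default_rng(seed)
    w = rng.normal(5.0, 1.0, size=(n, nl))
    return WindowedDataset(
        windows=w, targets=w.mean(axis=1), r=np.zeros(n),
        i_ex=np.zeros(n), offset=np.arange(n))


class TestForwardPass:
    def test_matches_naive_loop(self):
        rng = np.random.default_rng(1)
        for nh in (1, 3, 7):
            weights = _random_weights(5, nh, seed=nh, norm=0.37)
            for _ in range(20):
                window = rng.normal(size=5)
                expected = perceptron_forward_naive(
                    window, weights.w_in, weights.b_in, weights.w_out,
                    weights.b_out, weights.norm_const)
                assert predict_entropy(weights, window) == pytest.approx(
                    expected, abs=1e-12)

    def test_zero_output_weights_give_bias(self):
        weights = _random_weights(4, 3)
        weights = SensorWeights(
            nl=4, nh=3, norm_const=0.0, w_in=weights.w_in,
            b_in=weights.b_in, w_out=np.zeros(3), b_out=2.5)
        for window in np.random.default_rng(2).normal(size=(5, 4)):
            assert predict_entropy(weights, window) == pytest.approx(2.5)

    def test_two_unit_hand_calculation(self):
        weights = SensorWeights(
            nl=3, nh=2, norm_const=0.0,
            w_in=np.array([[1.0, 0.0, -1.0], [0.5, 0.5, 0.5]]),
            b_in=np.array([0.1, -0.2]), w_out=np.array([2.0, -1.0]),
            b_out=0.3)
        window = [0.2, -0.1, 0.4]
        z1 = 0.1 + 0.2 - 0.4
        z2 = -0.2 + 0.5 * (0.2 - 0.1 + 0.4)
        expected = (0.3 + 2.0 / (1 + math.exp(-z1))
                    - 1.0 / (1 + math.exp(-z2)))
        assert predict_entropy(weights, window) == pytest.approx(
            expected, abs=1e-14)

    def test_window_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            predict_entropy(_random_weights(5, 2), np.zeros(4))


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        assert regression_metrics([1, 2, 3], [1, 2, 3]) == (1.0, 0.0, 0.0)

    def test_mean_predictor_scores_zero(self):
        y = np.array([1.0, 2, 3, 4])
        r2, _, _ = regression_metrics(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_triple(self):
        r2, rmse, mape = regression_metrics([1, 2, 3], [1, 2, 4])
        assert r2 == pytest.approx(0.5)
        assert rmse == pytest.approx(math.sqrt(1 / 3))
        assert mape == pytest.approx(100 / 9)

    def test_zero_true_values_excluded_from_mape(self):
        _, _, mape = regression_metrics([0.0, 1.0, 2.0], [5.0, 1.1, 2.2])
        assert mape == pytest.approx(10.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            regression_metrics([1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="zero variance"):
            regression_metrics([2, 2, 2], [1, 2, 3])


class TestTraining:
    def test_single_unit_learns_window_mean(self):
        ds = _mean_dataset()
        # small-batch, long-epoch budget: with only 250 rows the default
        # epoch cap gives adam too few updates to move the output layer
        cfg = TrainingConfig(nh=1, normalize=True, seed=0,
                             max_epochs=4000, batch_size=50)
        split = 250
        sensor = ChaosSensor(ds.windows[:split], ds.targets[:split], cfg)
        result = sensor.fit()
        r2, _, _ = regression_metrics(
            ds.targets[split:], result.predict(ds.windows[split:]))
        assert r2 > 0.99

    def test_seeded_determinism(self):
        ds = _mean_dataset(n=120)
        cfg = TrainingConfig(nh=3, seed=7, max_epochs=50)
        a = ChaosSensor.from_dataset(ds, cfg).fit()
        b = ChaosSensor.from_dataset(ds, cfg).fit()
        assert np.array_equal(a.weights.w_in, b.weights.w_in)
        assert np.array_equal(a.weights.w_out, b.weights.w_out)

    def test_normalization_constant_stored(self):
        ds = _mean_dataset()
        result = ChaosSensor.from_dataset(
            ds, TrainingConfig(nh=1, normalize=True, max_epochs=20)).fit()
        assert result.weights.norm_const == pytest.approx(ds.windows.mean())
        raw = ChaosSensor.from_dataset(
            ds, TrainingConfig(nh=1, normalize=False, max_epochs=20)).fit()
        assert raw.weights.norm_const == 0.0

    def test_summary_mentions_architecture(self):
        result = ChaosSensor.from_dataset(
            _mean_dataset(n=100), TrainingConfig(nh=2, max_epochs=20)).fit()
        text = result.summary()
        assert "NH" in text and "R^2" in text


class TestCrossValidation:
    def test_partition_correctness(self):
        ds = _mean_dataset(n=100)
        cfg = TrainingConfig(nh=1, k=5, max_epochs=20)
        cv = ChaosSensor.from_dataset(ds, cfg).cross_validate()
        per_fold = cv.eval_report.per_fold
        assert len(per_fold) == 5
        # every row tested exactly once: all out-of-fold slots filled
        assert np.all(np.isfinite(cv.oof_predictions))
        assert per_fold["n_test"].sum() == 100

    def test_k_larger_than_n_rejected(self):
        ds = _mean_dataset(n=5)
        with pytest.raises(ValueError, match="exceeds"):
            ChaosSensor.from_dataset(
                ds, TrainingConfig(nh=1, k=10)).cross_validate()


class TestCrossDataset:
    def test_nl_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            train_test_cross(_mean_dataset(nl=5), _mean_dataset(nl=6),
                             TrainingConfig(nh=1, max_epochs=10))

    def test_train_equals_test_recovers_in_sample_fit(self):
        ds = _mean_dataset(n=200)
        cfg = TrainingConfig(nh=1, seed=0, max_epochs=4000, batch_size=50)
        rep = train_test_cross(ds, ds, cfg)
        assert rep.r2 > 0.99


class TestEqualWeightModel:
    def test_weights_equalized(self):
        trained = _random_weights(6, 1)
        simple = build_equal_weight_model(trained)
        assert np.unique(simple.w_in).size == 1
        assert simple.w_in[0, 0] == pytest.approx(trained.w_in.mean())
        assert simple.b_in == pytest.approx(trained.b_in)
        assert simple.b_out == trained.b_out

    def test_depends_only_on_window_mean(self):
        simple = build_equal_weight_model(_random_weights(4, 1))
        a = np.array([1.0, 2.0, 3.0, 6.0])   # mean 3
        b = np.array([3.0, 3.0, 3.0, 3.0])   # same mean
        assert predict_entropy(simple, a) == pytest.approx(
            predict_entropy(simple, b), abs=1e-12)
        perm = predict_entropy(simple, a[::-1].copy())
        assert perm == pytest.approx(predict_entropy(simple, a), abs=1e-12)

    def test_requires_single_hidden_unit(self):
        with pytest.raises(ValueError, match="NH=1"):
            build_equal_weight_model(_random_weights(4, 2))


class TestSmoothing:
    def test_constant_preserved(self):
        v = np.full(30, 2.5)
        assert np.allclose(smooth_predictions(v, 20), 2.5)

    def test_variance_contraction(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=200)
        assert smooth_predictions(v, 20).std() <= v.std()

    def test_trailing_alignment(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        out = smooth_predictions(v, 2)
        assert out == pytest.approx([1.0, 1.5, 2.5, 3.5])
        assert np.array_equal(smooth_predictions(v, 1), v)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            smooth_predictions([1.0], 0)


class TestPersistence:
    def test_roundtrip_bitwise(self, tmp_path):
        weights = _random_weights(8, 3, norm=12.34)
        path = tmp_path / "model.json"
        save_model(weights, path)
        back = load_model(path)
        windows = np.random.default_rng(9).normal(size=(100, 8))
        assert np.array_equal(weights.predict(windows), back.predict(windows))

    def test_truncated_file(self, tmp_path):
        path = tmp_path / "model.json"
        save_model(_random_weights(4, 2), path)
        path.write_text(path.read_text()[:40])
        with pytest.raises(ValueError, match="not a valid model file"):
            load_model(path)

    def test_schema_mismatch_names_field(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"nl": 4, "nh": 2}')
        with pytest.raises(ValueError, match="w_in"):
            load_model(path)
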