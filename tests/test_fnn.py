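"""Network training (Levenberg–Marquardt), binning, evaluation, selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import floodscore as fs
from floodscore.fnn_classifier import (N_PARAMS, _forward, _mse,
                                       network_jacobian)


class TestSplit:
    def test_724_records_give_72_test_samples(self):
        split = fs.split_dataset(np.arange(724), seed=0)
        assert len(split.test_ids) == 72

    def test_ten_records_give_one_test_sample(self):
        split = fs.split_dataset(np.arange(10), seed=0)
        assert len(split.test_ids) == 1

    def test_deterministic_and_partitioning(self):
        s1 = fs.split_dataset(np.arange(100), seed=5)
        s2 = fs.split_dataset(np.arange(100), seed=5)
        np.testing.assert_array_equal(s1.test_ids, s2.test_ids)
        np.testing.assert_array_equal(s1.train_ids, s2.train_ids)
        allids = np.concatenate([s1.train_ids, s1.val_ids, s1.test_ids])
        assert sorted(allids) == list(range(100))

    def test_validation_carved_from_training(self):
        split = fs.split_dataset(np.arange(724), seed=1)
        assert len(split.val_ids) == int(0.10 * (724 - 72))
        assert len(split.train_ids) == 724 - 72 - len(split.val_ids)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            fs.split_dataset(np.arange(9), seed=0)


class TestFeatureScaler:
    def test_endpoints_and_midpoint(self):
        X = np.array([[39.0], [41.0], [40.0]])
        scaler = fs.FeatureScaler().fit(X)
        np.testing.assert_allclose(scaler.transform(X).ravel(), [-1, 1, 0])

    def test_extrapolates_without_clipping(self):
        scaler = fs.FeatureScaler().fit(np.array([[0.0], [1.0]]))
        assert scaler.transform(np.array([[2.0]]))[0, 0] == pytest.approx(3.0)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5)) * [1, 10, 100, 0.1, 1000]
        scaler = fs.FeatureScaler().fit(X)
        np.testing.assert_allclose(
            scaler.inverse_transform(scaler.transform(X)), X, atol=1e-12)

    def test_constant_feature_maps_to_zero(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0]])
        out = fs.FeatureScaler().fit(X).transform(X)
        np.testing.assert_allclose(out[:, 1], 0.0)


class TestLevenbergMarquardt:
    def test_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        theta = rng.uniform(-0.5, 0.5, N_PARAMS)
        X = rng.normal(size=(7, 5))
        J = network_jacobian(theta, X)
        eps = 1e-6
        for p in range(0, N_PARAMS, 7):  # probe a spread of parameters
            tp, tm = theta.copy(), theta.copy()
            tp[p] += eps
            tm[p] -= eps
            fd = (_forward(tp, X)[0] - _forward(tm, X)[0]) / (2 * eps)
            np.testing.assert_allclose(J[:, p], fd, rtol=1e-5, atol=1e-8)

    def test_fits_noiseless_linear_target(self):
        """The network subsumes linear maps; LM should drive the loss to
        ~0 on y = x1 within 100 epochs."""
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, (200, 5))
        y = X[:, 0]
        cfg = fs.FNNConfig(seed=0, epochs_max=100)
        model = fs.lm_train(X, y, None, None, config=cfg)
        assert _mse(model.theta, X, y) < 1e-6

    def test_high_goal_stops_immediately(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(30, 5)), rng.normal(size=30)
        model = fs.lm_train(X, y, None, None,
                            config=fs.FNNConfig(seed=0, goal=1e9))
        assert model.stop_reason == "goal"
        assert len(model.trace) == 0

    def test_accepted_steps_decrease_training_loss(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, (120, 5))
        y = np.sin(X[:, 0]) + X[:, 1] ** 2
        model = fs.lm_train(X, y, None, None,
                            config=fs.FNNConfig(seed=1, epochs_max=40))
        losses = model.trace["loss"].to_numpy()
        assert np.all(np.diff(losses) < 0)
        assert np.all(model.trace["mu"] > 0)

    def test_early_stopping_restores_best_validation_weights(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, (60, 5))
        y = X[:, 0] + rng.normal(0, 0.5, 60)       # noisy: overfits quickly
        Xv = rng.uniform(-1, 1, (30, 5))
        yv = Xv[:, 0] + rng.normal(0, 0.5, 30)
        model = fs.lm_train(X, y, Xv, yv, config=fs.FNNConfig(seed=2))
        val = _mse(model.theta, Xv, yv)
        assert val <= model.trace["val_loss"].min() + 1e-12

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X, y = rng.normal(size=(50, 5)), rng.normal(size=50)
        m1 = fs.lm_train(X, y, None, None, config=fs.FNNConfig(seed=7,
                                                               epochs_max=20))
        m2 = fs.lm_train(X, y, None, None, config=fs.FNNConfig(seed=7,
                                                               epochs_max=20))
        np.testing.assert_array_equal(m1.theta, m2.theta)

    def test_parameter_count_is_71(self):
        assert N_PARAMS == 71

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            fs.lm_train(np.zeros((12, 5)), np.zeros(12), None, None,
                        config=fs.FNNConfig(mu_dec=2.0))


class TestPredict:
    def test_zero_weights_output_bias(self):
        model = fs.TrainedFNN(theta=np.zeros(N_PARAMS),
                              scaler=fs.FeatureScaler().fit(np.zeros((2, 5))),
                              config=fs.FNNConfig())
        model.theta[70] = 3.25
        out = fs.predict_continuous(model, np.random.default_rng(0)
                                    .normal(size=(4, 5)))
        np.testing.assert_allclose(out, 3.25)

    def test_hand_computed_single_hidden_unit(self):
        theta = np.zeros(N_PARAMS)
        theta[0:5] = [0.2, -0.1, 0.3, 0.0, 0.5]   # first hidden unit weights
        theta[50] = 0.1                           # its bias
        theta[60] = 2.0                           # output weight
        theta[70] = -0.5                          # output bias
        x = np.array([1.0, 2.0, -1.0, 0.5, 0.2])
        expected = 2.0 * np.tanh(0.2 - 0.2 - 0.3 + 0.0 + 0.1 + 0.1) - 0.5
        out, _ = _forward(theta, x[None, :])
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_batch_equals_per_record(self):
        rng = np.random.default_rng(9)
        theta = rng.uniform(-0.5, 0.5, N_PARAMS)
        X = rng.normal(size=(6, 5))
        batch, _ = _forward(theta, X)
        single = np.array([_forward(theta, x[None, :])[0][0] for x in X])
        np.testing.assert_allclose(batch, single, atol=1e-14)

    def test_feature_count_mismatch_rejected(self):
        model = fs.TrainedFNN(theta=np.zeros(N_PARAMS),
                              scaler=fs.FeatureScaler().fit(np.zeros((2, 5))),
                              config=fs.FNNConfig())
        with pytest.raises(ValueError):
            fs.predict_continuous(model, np.zeros((3, 4)))


class TestBinning:
    @pytest.mark.parametrize("raw,level", [
        (0.0, 1), (1.49, 1), (1.5, 2), (2.49, 2), (2.5, 3), (3.49, 3),
        (3.5, 4), (4.49, 4), (4.5, 5), (99.0, 5), (-0.2, 1)])
    def test_interval_table(self, raw, level):
        assert fs.bin_fis(raw) == level

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fs.bin_fis(float("nan"))

    def test_level_midpoints_are_fixed_points(self):
        for level in range(1, 6):
            assert fs.bin_fis(float(level)) == level

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(-2, 8), st.floats(-2, 8))
    def test_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert fs.bin_fis(lo) <= fs.bin_fis(hi)


class TestEvaluation:
    def test_accuracy_cases(self):
        ones = np.ones(5, int)
        assert fs.accuracy(ones, ones) == 100.0
        assert fs.accuracy(ones, ones + 1) == 0.0
        pred = np.ones(72, int)
        obs = np.ones(72, int)
        obs[:7] = 2
        assert fs.accuracy(pred, obs) == pytest.approx(100 * 65 / 72)

    def test_accuracy_empty_rejected(self):
        with pytest.raises(ValueError):
            fs.accuracy(np.array([]), np.array([]))

    def test_confusion_toy_counts(self):
        table = fs.confusion(np.array([1, 2, 2]), np.array([1, 2, 3]))
        expected = np.zeros((5, 5), int)
        expected[0, 0] = expected[1, 1] = expected[1, 2] = 1
        np.testing.assert_array_equal(table.counts, expected)
        assert table.counts.sum() == 3

    def test_confusion_diagonal_gives_accuracy(self):
        rng = np.random.default_rng(11)
        obs = rng.integers(1, 6, 60)
        pred = obs.copy()
        flip = rng.random(60) < 0.3
        pred[flip] = np.clip(obs[flip] + 1, 1, 5)
        table = fs.confusion(pred, obs)
        assert 100 * np.trace(table.counts) / 60 == pytest.approx(table.accuracy)
        # marginals conserve class counts
        np.testing.assert_array_equal(
            table.counts.sum(axis=0),
            np.bincount(obs, minlength=6)[1:6])

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            fs.confusion(np.array([0]), np.array([1]))


class TestSelection:
    def test_counts_for_72_sample_test_set(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(1, 5, 72)
        ids = [f"p{i:03d}" for i in range(72)]
        assert len(fs.select_top_fraction(raw, ids, 0.10)) == 8
        assert len(fs.select_top_fraction(raw, ids, 0.20)) == 15

    def test_selects_lowest_outputs(self):
        raw = np.array([3.0, 1.0, 2.0, 5.0])
        out = fs.select_top_fraction(raw, ["a", "b", "c", "d"], 0.5)
        assert out == ["b", "c"]

    def test_full_selection_and_tie_break(self):
        raw = np.array([2.0, 2.0, 1.0])
        assert fs.select_top_fraction(raw, ["z", "a", "m"], 1.0) == \
            ["m", "a", "z"]

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            fs.select_top_fraction(np.array([1.0]), ["a"], 0.0)


def test_model_json_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    scaler = fs.FeatureScaler().fit(rng.normal(size=(10, 5)))
    model = fs.TrainedFNN(theta=rng.uniform(-0.5, 0.5, N_PARAMS),
                          scaler=scaler, config=fs.FNNConfig(seed=3),
                          stop_reason="max_fail")
    model.to_json(tmp_path / "m.json")
    back = fs.TrainedFNN.from_json(tmp_path / "m.json")
    X = rng.normal(size=(6, 5))
    np.testing.assert_allclose(fs.predict_continuous(back, X),
                               fs.predict_continuous(model, X), atol=1e-12)
    assert back.stop_reason == "max_fail"
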