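import numpy as np
import pytest

from ppgbp.models import ModelSpec, build_model
from ppgbp.splits import make_calibfree_split
from ppgbp.training import (MedianBaselineRegressor, NeuralBPRegressor,
                            TrainConfig, baseline_predict, find_learning_rate,
                            median_baseline, select_rate_from_curve, train,
                            weighted_mse_loss)

from conftest import make_label_store


class TestWeightedLoss:
    def test_unit_weights_equal_joint_mse(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=(50, 2))
        ref = rng.normal(size=(50, 2))
        joint = ((pred - ref) ** 2).sum(axis=1).mean()
        assert weighted_mse_loss(pred, ref) == pytest.approx(joint)

    def test_perfect_prediction_is_zero(self):
        ref = np.array([[120.0, 60.0], [140.0, 80.0]])
        assert weighted_mse_loss(ref.copy(), ref) == 0.0

    def test_hand_computed_value(self):
        # errors (1,2) and (3,0); weights sbp (2,1), dbp (1,1)
        # -> mean of [2*1 + 1*4, 1*9 + 1*0] = 7.5
        pred = np.array([[1.0, 2.0], [3.0, 0.0]])
        ref = np.zeros((2, 2))
        val = weighted_mse_loss(pred, ref, w_sbp=[2, 1], w_dbp=[1, 1])
        assert val == pytest.approx(7.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_mse_loss(np.zeros((3, 2)), np.zeros((2, 2)))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            weighted_mse_loss(np.zeros((2, 2)), np.zeros((2, 2)),
                              w_sbp=[-1, 1], w_dbp=[1, 1])


class TestMedianBaseline:
    def test_odd_count(self):
        b = median_baseline([100, 120, 140], [50, 60, 70])
        assert b.median_sbp == 120.0

    def test_even_count_interpolates(self):
        b = median_baseline([100, 140], [50, 60])
        assert b.median_sbp == 120.0
        assert b.median_dbp == 55.0

    def test_empty_labels(self):
        with pytest.raises(ValueError):
            median_baseline([], [])

    def test_constant_prediction_mae(self):
        b = median_baseline([100, 140], [50, 70])
        sbp_pred, _ = baseline_predict(b, 2)
        refs = np.array([100.0, 140.0])
        assert np.abs(sbp_pred - refs).mean() == pytest.approx(20.0)

    def test_estimator_api(self):
        y = np.array([[100.0, 50.0], [120.0, 60.0], [150.0, 90.0]])
        est = MedianBaselineRegressor().fit(np.zeros((3, 1)), y)
        out = est.predict(np.zeros((5, 1)))
        assert out.shape == (5, 2)
        np.testing.assert_array_equal(out[0], [120.0, 60.0])


class TestLearningRateFinder:
    def test_flat_then_explosion_returns_decade_below(self):
        rates = np.geomspace(1e-5, 1.0, 11)
        losses = np.where(rates < 0.05, 1.0, 1e6)
        r_star = rates[np.argmax(losses > 10)]
        rate, exploded = select_rate_from_curve(rates, losses)
        assert exploded
        assert rate == pytest.approx(r_star / 10.0)

    def test_monotone_decreasing_returns_max(self):
        rates = np.geomspace(1e-5, 1e-2, 7)
        losses = np.linspace(5.0, 1.0, 7)
        rate, exploded = select_rate_from_curve(rates, losses)
        assert not exploded
        assert rate == pytest.approx(1e-2)

    def test_single_element_grid(self):
        store = make_label_store(n_subjects=6, segments_per_subject=4,
                                 sig_len=262)
        split = make_calibfree_split(store, seed=0)
        model = build_model(ModelSpec(scale=0.25), seed=0)
        assert find_learning_rate(model, store, split, [3e-4]) == 3e-4


def small_train_setup(n_subjects=8, segments_per_subject=4):
    store = make_label_store(n_subjects=n_subjects,
                             segments_per_subject=segments_per_subject,
                             sig_len=262)
    split = make_calibfree_split(store, seed=0)
    config = TrainConfig(epochs=1, effective_batch=32, micro_batch=16, seed=0)
    return store, split, config


class TestTrainLoop:
    def test_one_epoch_smoke(self):
        store, split, config = small_train_setup()
        model = build_model(ModelSpec(scale=0.25), seed=0)
        result = train(model, store, split, config)
        assert len(result.history) == 1
        assert np.isfinite(result.history[0]["train_loss"])
        assert np.isfinite(result.history[0]["val_score"])

    def test_unit_weights_equal_no_weights(self):
        store, split, config = small_train_setup()
        models = []
        for weights in (None, np.ones((len(split.train), 2))):
            model = build_model(ModelSpec(scale=0.25), seed=1)
            train(model, store, split, config, weights=weights)
            models.append(model)
        pa = models[0].net.named_parameters()
        pb = models[1].net.named_parameters()
        for k in pa:
            np.testing.assert_array_equal(pa[k].data, pb[k].data)

    def test_best_epoch_selected_from_injected_curve(self):
        store, split, _ = small_train_setup()
        config = TrainConfig(epochs=3, effective_batch=32, micro_batch=16,
                             seed=0)
        model = build_model(ModelSpec(scale=0.25), seed=0)
        curve = [5.0, 3.0, 4.0]
        result = train(model, store, split, config,
                       val_scorer=lambda m, epoch: curve[epoch])
        assert result.best_epoch == 1
        assert result.history[result.best_epoch]["val_score"] == min(
            h["val_score"] for h in result.history)

    def test_empty_split_rejected(self):
        store, split, config = small_train_setup()
        split.val = np.empty(0, dtype=np.intp)
        model = build_model(ModelSpec(scale=0.25), seed=0)
        with pytest.raises(ValueError, match="nonempty"):
            train(model, store, split, config)

    def test_weight_shape_checked(self):
        store, split, config = small_train_setup()
        model = build_model(ModelSpec(scale=0.25), seed=0)
        with pytest.raises(ValueError, match="weights shape"):
            train(model, store, split, config,
                  weights=np.ones((3, 2)))


class TestEstimatorApi:
    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone
        est = NeuralBPRegressor(architecture="ssm", epochs=2, scale=0.25)
        cloned = clone(est)
        assert cloned.get_params()["architecture"] == "ssm"

    def test_fit_predict_shapes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(24, 262))
        y = np.stack([rng.uniform(100, 140, 24), rng.uniform(50, 80, 24)],
                     axis=1)
        est = NeuralBPRegressor(epochs=1, scale=0.25, effective_batch=16,
                                micro_batch=8)
        est.fit(X, y)
        assert est.predict(X).shape == (24, 2)
        assert est.best_epoch_ == 0
        assert len(est.history_) == 1

    def test_bad_label_shape(self):
        est = NeuralBPRegressor(epochs=1)
        with pytest.raises(ValueError, match="sbp, dbp"):
            est.fit(np.zeros((4, 262)), np.zeros(4))
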