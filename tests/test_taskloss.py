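"""Hybrid loss components, their gradients, and fine-tuning contracts."""

import math

import numpy as np
import pytest

from taskbed.denoiser import DenoiserSpec, TrainSettings, build_denoiser
from taskbed.phantom import InvalidConfigurationError
from taskbed.taskloss import (
    AppendedObserver, HybridConfig, InvalidBatchError, bce_task_loss,
    finetune, hybrid_loss, multiclass_task_loss, physical_loss,
    slnn_ho_task_loss,
)
from taskbed.denoiser import InvalidInputError

from conftest import make_toy_pairs


class TestPhysicalLoss:
    def test_identical_batches_give_zero(self):
        x = np.random.default_rng(0).random((4, 8, 8))
        assert physical_loss(x, x) == 0.0

    def test_unit_offset_equals_pixel_count(self):
        x = np.zeros((1, 8, 8))
        assert physical_loss(x + 1.0, x) == pytest.approx(64.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.random((5, 6, 6))
        b = rng.random((5, 6, 6))
        oracle = np.mean([((a[i] - b[i]) ** 2).sum() for i in range(5)])
        assert physical_loss(a, b) == pytest.approx(oracle, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            physical_loss(np.zeros((2, 4, 4)), np.zeros((2, 5, 5)))


class TestBceLoss:
    def test_maximal_uncertainty_gives_n_log_two(self):
        obs = AppendedObserver("slnn-no", 16)
        obs.w[:] = 0.0
        x = np.random.default_rng(0).random((6, 4, 4))
        y = np.array([0, 1, 0, 1, 0, 1])
        loss, *_ = bce_task_loss(obs, x, y)
        assert loss == pytest.approx(6 * math.log(2))

    def test_confident_correct_predictions_drive_loss_to_zero(self):
        obs = AppendedObserver("slnn-no", 1)
        obs.w[:] = 50.0
        x = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        y = np.array([0, 1, 0, 1])
        loss, *_ = bce_task_loss(obs, x, y)
        assert loss < 1e-8

    def test_matches_per_sample_log_probability_oracle(self):
        rng = np.random.default_rng(2)
        obs = AppendedObserver("slnn-no", 9, rng=rng)
        x = rng.random((8, 3, 3))
        y = rng.integers(0, 2, 8)
        loss, *_ = bce_task_loss(obs, x, y)
        p = obs.probabilities(x)
        oracle = -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert loss == pytest.approx(oracle, rel=1e-10)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        obs = AppendedObserver("slnn-no", 4, rng=rng)
        x = rng.random((6, 4))
        y = rng.integers(0, 2, 6)

        def value():
            return bce_task_loss(obs, x, y)[0]

        _, dX, dw, db = bce_task_loss(obs, x, y)
        eps = 1e-6
        for arr, grad in ((obs.w, dw), (obs.b, db)):
            old = arr[0]
            arr[0] = old + eps
            up = value()
            arr[0] = old - eps
            down = value()
            arr[0] = old
            assert grad[0] == pytest.approx((up - down) / (2 * eps), rel=1e-4)
        old = x[2, 1]
        x[2, 1] = old + eps
        up = value()
        x[2, 1] = old - eps
        down = value()
        x[2, 1] = old
        assert dX[2, 1] == pytest.approx((up - down) / (2 * eps), rel=1e-4)

    def test_non_binary_labels_rejected(self):
        obs = AppendedObserver("slnn-no", 4)
        with pytest.raises(InvalidInputError):
            bce_task_loss(obs, np.zeros((2, 4)), np.array([0, 3]))


class TestHotellingLoss:
    def test_zero_template_gives_zero_loss(self):
        obs = AppendedObserver("slnn-ho", 4)
        x = np.random.default_rng(0).random((8, 4))
        y = np.array([0, 1] * 4)
        loss, _, _ = slnn_ho_task_loss(obs, x, y)
        assert loss == 0.0

    def test_matches_term_by_term_oracle(self):
        """Brute-force evaluation of the quadratic loss on a toy batch."""
        rng = np.random.default_rng(4)
        obs = AppendedObserver("slnn-ho", 4)
        obs.w = rng.standard_normal(4)
        X = rng.random((8, 2, 2))
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        loss, _, _ = slnn_ho_task_loss(obs, X, y)
        flat = X.reshape(8, -1)
        J = 8
        f0 = (2 / J) * flat[y == 0].sum(axis=0)
        f1 = (2 / J) * flat[y == 1].sum(axis=0)
        oracle = 0.0
        for j in range(J):
            ref = f1 if y[j] else f0
            oracle += (1 / J) * float(obs.w @ (flat[j] - ref)) ** 2
        oracle -= 2.0 * float(obs.w @ (f1 - f0))
        assert loss == pytest.approx(oracle, rel=1e-10)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(5)
        obs = AppendedObserver("slnn-ho", 4)
        obs.w = rng.standard_normal(4)
        x = rng.random((6, 4))
        y = np.array([0, 0, 0, 1, 1, 1])

        def value():
            return slnn_ho_task_loss(obs, x, y)[0]

        _, dX, dw = slnn_ho_task_loss(obs, x, y)
        eps = 1e-6
        old = obs.w[1]
        obs.w[1] = old + eps
        up = value()
        obs.w[1] = old - eps
        down = value()
        obs.w[1] = old
        assert dw[1] == pytest.approx((up - down) / (2 * eps), rel=1e-5)
        for (i, j) in ((0, 2), (4, 0)):
            old = x[i, j]
            x[i, j] = old + eps
            up = value()
            x[i, j] = old - eps
            down = value()
            x[i, j] = old
            assert dX[i, j] == pytest.approx((up - down) / (2 * eps), rel=1e-4)

    def test_single_class_batch_rejected(self):
        obs = AppendedObserver("slnn-ho", 4)
        with pytest.raises(InvalidBatchError):
            slnn_ho_task_loss(obs, np.zeros((4, 4)), np.zeros(4, dtype=int))


class TestMulticlassLoss:
    def test_uniform_probabilities_give_n_log_classes(self):
        obs = AppendedObserver("slnn-multiclass", 9, n_classes=4)
        obs.w[:] = 0.0
        x = np.random.default_rng(0).random((6, 3, 3))
        y = np.array([0, 1, 2, 3, 0, 1])
        loss, *_ = multiclass_task_loss(obs, x, y)
        assert loss == pytest.approx(6 * math.log(4))

    def test_one_hot_correct_predictions_give_zero(self):
        obs = AppendedObserver("slnn-multiclass", 3, n_classes=3)
        obs.w = 100.0 * np.eye(3)
        obs.b[:] = 0.0
        x = np.eye(3)
        y = np.array([0, 1, 2])
        loss, *_ = multiclass_task_loss(obs, x, y)
        assert loss < 1e-8

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(6)
        obs = AppendedObserver("slnn-multiclass", 4, n_classes=3, rng=rng)
        x = rng.random((7, 4))
        y = rng.integers(0, 3, 7)
        loss, *_ = multiclass_task_loss(obs, x, y)
        P = obs.probabilities(x)
        oracle = -np.log(P[np.arange(7), y]).sum()
        assert loss == pytest.approx(oracle, rel=1e-10)

    def test_out_of_range_labels_rejected(self):
        obs = AppendedObserver("slnn-multiclass", 4, n_classes=3)
        with pytest.raises(InvalidInputError):
            multiclass_task_loss(obs, np.zeros((2, 4)), np.array([0, 5]))


class TestHybridLoss:
    def test_direct_arithmetic(self):
        assert hybrid_loss(HybridConfig(0.7), 2.0, 10.0) == pytest.approx(7.6)

    def test_lambda_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            HybridConfig(lambda_weight=1.5)
        with pytest.raises(InvalidConfigurationError):
            HybridConfig(lambda_weight=-0.1)


class TestFinetuneContracts:
    def test_ntrain_exceeding_depth_rejected(self):
        model = build_denoiser(DenoiserSpec(depth_D=5, filters_per_layer=3), 0)
        train = make_toy_pairs(8, seed=0)
        with pytest.raises(InvalidConfigurationError):
            finetune(model, HybridConfig(0.5, 6, "slnn-no"), train, train,
                     TrainSettings(epochs=1))

    def test_multiclass_finetune_runs_and_freezes(self):
        train = make_toy_pairs(n_per_class=12, side=16, seed=4, n_classes=3)
        val = make_toy_pairs(n_per_class=6, side=16, seed=5, n_classes=3)
        model = build_denoiser(DenoiserSpec(depth_D=5, filters_per_layer=3), 0)
        tuned, obs, _ = finetune(
            model, HybridConfig(0.5, 2, "slnn-multiclass"), train, val,
            TrainSettings(learning_rate=1e-3, batch_size=8, epochs=2),
            rng_seed=0,
        )
        assert obs.n_classes == 3
        before, after = model.state(), tuned.state()
        for i in range(len(before) - 2):
            for name, arr in before[i].items():
                assert np.array_equal(arr, after[i][name])
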