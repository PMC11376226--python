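"""Linear and learned numerical observers."""

import numpy as np
import pytest

from taskbed.evaluate import empirical_auc
from taskbed.fixtures import GaussianTwoClassSpec, make_gaussian_ensemble
from taskbed.observers import (
    DogChannelSet, EmpiricalStats, InsufficientDataError,
    SingularCovarianceError, build_dog_channels, channelize, cho_statistic,
    estimate_stats, hotelling_template, regularized_hotelling_template,
    select_rho_alpha, train_slnn_multiclass, train_slnn_no,
)
from taskbed.denoiser import TrainSettings


class TestEstimateStats:
    def test_two_pixel_toy_oracle(self):
        """Hand-computed means and covariances on a 4-image toy set."""
        absent = np.array([[0.0, 0.0], [2.0, 0.0]])
        present = np.array([[1.0, 1.0], [3.0, 1.0]])
        stats = estimate_stats(present, absent)
        assert np.allclose(stats.delta_mean, [1.0, 1.0])
        assert np.allclose(stats.covariance, [[2.0, 0.0], [0.0, 0.0]])
        assert stats.n_absent == stats.n_present == 2

    def test_degenerate_constant_images(self):
        imgs = np.ones((3, 4))
        stats = estimate_stats(imgs, imgs)
        assert np.all(stats.covariance == 0)
        assert np.all(stats.delta_mean == 0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.random((10, 6))
        a = rng.random((10, 6))
        s1 = estimate_stats(p, a)
        s2 = estimate_stats(p[::-1], a[::-1])
        assert np.allclose(s1.covariance, s2.covariance)
        assert np.allclose(s1.delta_mean, s2.delta_mean)

    def test_single_image_per_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_stats(np.ones((1, 4)), np.ones((5, 4)))


class TestHotelling:
    def test_identity_covariance_returns_delta_mean(self):
        stats = EmpiricalStats(np.zeros(3), np.array([1.0, 0, 0]),
                               np.array([1.0, 0, 0]), np.eye(3), 10, 10)
        obs = hotelling_template(stats)
        assert np.allclose(obs.template_w, [1.0, 0, 0])

    def test_scaling_delta_mean_scales_template_not_auc(self):
        rng = np.random.default_rng(1)
        sample = make_gaussian_ensemble(
            GaussianTwoClassSpec(4, np.eye(4), np.array([1.0, 0.5, 0, 0]),
                                 500, seed=0)
        )
        stats = estimate_stats(sample.present, sample.absent)
        w1 = hotelling_template(stats).template_w
        stats2 = EmpiricalStats(stats.mean_absent, stats.mean_present,
                                3.0 * stats.delta_mean, stats.covariance,
                                stats.n_absent, stats.n_present)
        w3 = hotelling_template(stats2).template_w
        assert np.allclose(w3, 3.0 * w1)
        auc1 = empirical_auc(sample.samples @ w1, sample.labels).auc
        auc3 = empirical_auc(sample.samples @ w3, sample.labels).auc
        assert auc1 == pytest.approx(auc3, abs=1e-12)

    def test_singular_covariance_raises_towards_rho(self):
        stats = EmpiricalStats(np.zeros(3), np.ones(3), np.ones(3),
                               np.diag([1.0, 1.0, 0.0]), 5, 5)
        with pytest.raises(SingularCovarianceError):
            hotelling_template(stats)


class TestRegularizedHotelling:
    def test_rank_one_closed_form(self):
        u = np.array([0.6, 0.8])
        sigma = 2.5
        K = sigma * np.outer(u, u)
        dmu = 1.3 * u
        stats = EmpiricalStats(np.zeros(2), dmu, dmu, K, 5, 5)
        obs = regularized_hotelling_template(stats, 0.5)
        assert np.allclose(obs.template_w, (1.3 / sigma) * u)
        assert obs.aux["rank"] == 1

    def test_full_truncation_warns_and_returns_zero(self):
        stats = EmpiricalStats(np.zeros(2), np.ones(2), np.ones(2),
                               np.zeros((2, 2)), 5, 5)
        with pytest.warns(UserWarning):
            obs = regularized_hotelling_template(stats, 0.5)
        assert np.all(obs.template_w == 0)

    def test_validation_selection_beats_plain_inverse_when_ill_conditioned(self):
        """RHO with a validation-selected threshold outperforms the HO on a
        rank-deficient covariance with tiny jitter (median over seeds)."""
        dim, n = 16, 60
        wins = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            basis = rng.standard_normal((dim, 3))
            dmu = basis @ np.array([1.0, 0.5, 0.2]) * 0.8
            def draw(n, mean):
                z = rng.standard_normal((n, 3)) @ basis.T
                return z + mean + 1e-4 * rng.standard_normal((n, dim))
            tr_p, tr_a = draw(n, dmu), draw(n, 0.0)
            va_p, va_a = draw(n, dmu), draw(n, 0.0)
            te_p, te_a = draw(200, dmu), draw(200, 0.0)
            stats = estimate_stats(tr_p, tr_a)
            rho = select_rho_alpha(stats, va_p, va_a)
            test = np.concatenate([te_a, te_p])
            labels = np.r_[np.zeros(200, int), np.ones(200, int)]
            auc_rho = empirical_auc(rho.statistic(test), labels).auc
            try:
                ho = hotelling_template(stats)
                auc_ho = empirical_auc(ho.statistic(test), labels).auc
            except SingularCovarianceError:
                auc_ho = 0.5
            wins.append(auc_rho - auc_ho)
        assert np.median(wins) >= 0


class TestDogChannels:
    cs = DogChannelSet()

    def test_profiles_nonnegative_when_q_above_one(self):
        freqs = np.linspace(0, 0.5, 200)
        for j in range(1, self.cs.n_channels + 1):
            sj = self.cs.sigma0 * self.cs.alpha_dog ** j
            prof = (np.exp(-0.5 * (freqs / (self.cs.Q_dog * sj)) ** 2)
                    - np.exp(-0.5 * (freqs / sj) ** 2))
            assert np.all(prof >= -1e-15)

    def test_constant_image_has_zero_response(self):
        T = build_dog_channels(self.cs, 32)
        v = channelize(T, np.ones((1, 32, 32)))
        assert np.allclose(v, 0.0, atol=1e-12)

    def test_cosine_image_response_matches_frequency_profile(self):
        """Channel response to a pure spatial frequency equals the DOG
        profile sampled at that frequency (FFT-grid oracle)."""
        side = 32
        T = build_dog_channels(self.cs, side)
        k = (3, 5)  # FFT-grid integer frequency
        yy, xx = np.mgrid[0:side, 0:side]
        img = np.cos(2 * np.pi * (k[0] * yy + k[1] * xx) / side)
        rho = np.hypot(k[0] / side, k[1] / side)
        v = channelize(T, img[None])[0]
        for j in range(1, self.cs.n_channels + 1):
            sj = self.cs.sigma0 * self.cs.alpha_dog ** j
            expected = (np.exp(-0.5 * (rho / (self.cs.Q_dog * sj)) ** 2)
                        - np.exp(-0.5 * (rho / sj) ** 2))
            assert v[j - 1] == pytest.approx(expected, abs=1e-10)


class TestCho:
    def test_internal_noise_uses_dedicated_seed(self):
        rng = np.random.default_rng(2)
        imgs = rng.random((20, 5))
        stats = estimate_stats(imgs[:10] + 0.5, imgs[10:])
        T = np.eye(5)
        a = cho_statistic(T, stats, 1.0, imgs, rng_seed=3)
        b = cho_statistic(T, stats, 1.0, imgs, rng_seed=3)
        c = cho_statistic(T, stats, 1.0, imgs, rng_seed=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestLearnedObservers:
    settings = TrainSettings(learning_rate=1e-2, batch_size=32, epochs=150)

    def test_separable_toy_data_reaches_perfect_auc(self):
        rng = np.random.default_rng(0)
        present = rng.random((40, 4)) + 3.0
        absent = rng.random((40, 4))
        obs = train_slnn_no(present, absent, present, absent,
                            self.settings, 0)
        stat = obs.detection_statistic(np.vstack([absent, present]))
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        assert empirical_auc(stat, labels).auc == 1.0

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(1)
        pool = rng.random((160, 6))
        half = 80
        obs = train_slnn_no(pool[:half], pool[half:],
                            pool[:half], pool[half:],
                            TrainSettings(learning_rate=1e-2, epochs=30), 0)
        fresh = rng.random((400, 6))
        stat = obs.detection_statistic(fresh)
        labels = rng.integers(0, 2, 400)
        auc = empirical_auc(stat, labels).auc
        assert abs(auc - 0.5) < 3 * 0.029  # binomial-scale error at n=400

    def test_learned_direction_approaches_hotelling_on_gaussians(self):
        """Logistic SLNN on equal-covariance Gaussians aligns with the
        analytic discriminant direction K^-1 dmu (cosine >= 0.95)."""
        rng = np.random.default_rng(3)
        dim = 8
        A = rng.standard_normal((dim, dim)) * 0.3
        K = A @ A.T + np.eye(dim)
        dmu = rng.standard_normal(dim)
        dmu *= 1.5 / np.sqrt(dmu @ np.linalg.solve(K, dmu))
        sample = make_gaussian_ensemble(
            GaussianTwoClassSpec(dim, K, dmu, n_per_class=10000, seed=5)
        )
        obs = train_slnn_no(sample.present, sample.absent,
                            sample.present[:500], sample.absent[:500],
                            TrainSettings(learning_rate=1e-2, batch_size=256,
                                          epochs=60), 0)
        w_true = np.linalg.solve(K, dmu)
        cos = obs.w @ w_true / (np.linalg.norm(obs.w) * np.linalg.norm(w_true))
        assert cos >= 0.95

    def test_two_class_multiclass_matches_binary_slnn(self):
        rng = np.random.default_rng(4)
        present = rng.standard_normal((300, 6)) + 0.8
        absent = rng.standard_normal((300, 6))
        images = np.vstack([absent, present])
        labels = np.r_[np.zeros(300, int), np.ones(300, int)]
        binary = train_slnn_no(present, absent, present, absent,
                               self.settings, 0)
        multi = train_slnn_multiclass(images, labels, images, labels,
                                      self.settings, 0)
        a1 = empirical_auc(binary.detection_statistic(images), labels).auc
        a2 = empirical_auc(multi.detection_statistic(images), labels).auc
        assert abs(a1 - a2) < 0.01

    def test_uninformative_multiclass_observer_gives_chance_detection(self):
        from taskbed.taskloss import AppendedObserver
        obs = AppendedObserver("slnn-multiclass", 6, n_classes=3)
        obs.w[:] = 0.0
        rng = np.random.default_rng(5)
        imgs = rng.random((100, 6))
        labels = rng.integers(0, 3, 100)
        stat = obs.detection_statistic(imgs)
        assert np.allclose(stat, stat[0])  # constant => AUC 1/2 by ties
        auc = empirical_auc(stat, (labels > 0).astype(int)).auc
        assert auc == 0.5

    def test_separable_three_class_task_reaches_perfect_detection(self):
        rng = np.random.default_rng(6)
        n = 60
        absent = rng.random((n, 4))
        c1 = rng.random((n, 4)) + np.array([4, 0, 0, 0])
        c2 = rng.random((n, 4)) + np.array([0, 4, 0, 0])
        images = np.vstack([absent, c1, c2])
        labels = np.r_[np.zeros(n, int), np.ones(n, int), np.full(n, 2)]
        obs = train_slnn_multiclass(images, labels, images, labels,
                                    self.settings, 0)
        auc = empirical_auc(obs.detection_statistic(images),
                            (labels > 0).astype(int)).auc
        assert auc == 1.0
        loc = obs.localize(images[labels > 0])
        assert (loc == labels[labels > 0]).mean() > 0.95

    def test_missing_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            train_slnn_multiclass(np.zeros((4, 3)), np.array([0, 0, 2, 2]),
                                  np.zeros((2, 3)), np.array([0, 2]),
                                  self.settings, 0)

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            train_slnn_no(np.zeros((0, 4)), np.ones((4, 4)),
                          np.zeros((0, 4)), np.ones((2, 4)),
                          self.settings, 0)


def test_linear_statistics_invariant_to_constant_image_shift():
    """Adding the same constant image to every member leaves AUC unchanged."""
    rng = np.random.default_rng(7)
    sample = make_gaussian_ensemble(
        GaussianTwoClassSpec(5, np.eye(5), np.r_[1.0, np.zeros(4)], 400, 1)
    )
    stats = estimate_stats(sample.present, sample.absent)
    obs = hotelling_template(stats)
    auc0 = empirical_auc(obs.statistic(sample.samples), sample.labels).auc
    shifted_p = sample.present + 7.5
    shifted_a = sample.absent + 7.5
    stats2 = estimate_stats(shifted_p, shifted_a)
    obs2 = hotelling_template(stats2)
    shifted = np.concatenate([shifted_a, shifted_p])
    auc1 = empirical_auc(obs2.statistic(shifted), sample.labels).auc
    assert auc0 == pytest.approx(auc1, abs=1e-9)
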