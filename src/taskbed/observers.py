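"""Evaluation-side numerical observers.

Implements the linear-observer family — Hotelling observer (HO), regularized
HO (RHO, truncated-SVD pseudo-inverse), and the difference-of-Gaussians
channelized HO (DOG-CHO) with an internal-noise mechanism — plus the learned
single-layer observers (SLNN-NO for binary detection, a softmax SLNN for
detection-localization), each producing a scalar test statistic per image.

The Hotelling template is ``w = K^-1 dmean`` with
``K = (K0 + K1) / 2`` the average of the class-conditional sample
covariances; its test statistic maximizes the detection SNR among linear
observers. The CHO applies the same construction to channelized data
``v = T f`` with internal noise of covariance ``eps * diag(Kv)`` added to
both the covariance and (as a random draw) to each channel output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .containers import ImageEnsemble
from .denoiser import TrainSettings, InvalidInputError
from .evaluate import empirical_auc
from .phantom import InvalidConfigurationError
from .taskloss import AppendedObserver, bce_task_loss, multiclass_task_loss
from . import nn


class InsufficientDataError(ValueError):
    pass


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


# ---------------------------------------------------------------------------
# empirical second-order statistics
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalStats:
    mean_absent: np.ndarray
    mean_present: np.ndarray
    delta_mean: np.ndarray
    covariance: np.ndarray  # (K0 + K1) / 2
    n_absent: int
    n_present: int


def _flatten(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float64)
    return images.reshape(images.shape[0], -1)


def estimate_stats(present: np.ndarray, absent: np.ndarray) -> EmpiricalStats:
    """Class means and the averaged sample covariance (divisor n - 1)."""
    p = _flatten(present)
    a = _flatten(absent)
    if len(p) < 2 or len(a) < 2:
        raise InsufficientDataError("need at least 2 images per class")
    m1 = p.mean(axis=0)
    m0 = a.mean(axis=0)
    k1 = np.cov(p, rowvar=False)
    k0 = np.cov(a, rowvar=False)
    return EmpiricalStats(m0, m1, m1 - m0, 0.5 * (np.atleast_2d(k0) + np.atleast_2d(k1)),
                          len(a), len(p))


# ---------------------------------------------------------------------------
# linear observers
# ---------------------------------------------------------------------------

@dataclass
class LinearObserver:
    template_w: np.ndarray
    kind: str  # ho | rho | cho
    aux: dict = field(default_factory=dict)

    def statistic(self, images: np.ndarray) -> np.ndarray:
        return _flatten(images) @ self.template_w


def hotelling_template(stats: EmpiricalStats,
                       cond_limit: float = 1e12) -> LinearObserver:
    """HO template ``w = K^-1 dmean`` via a symmetric eigen-solve.

    Raises :class:`SingularCovarianceError` when the covariance is singular
    or numerically ill-conditioned beyond ``cond_limit``; callers should
    then use :func:`regularized_hotelling_template`.
    """
    K = stats.covariance
    evals, evecs = scipy.linalg.eigh(K)
    if evals[-1] <= 0 or evals[0] <= 0 or evals[-1] / evals[0] > cond_limit:
        raise SingularCovarianceError(
            "covariance is singular or ill-conditioned; use the regularized "
            "Hotelling observer"
        )
    w = evecs @ ((evecs.T @ stats.delta_mean) / evals)
    return LinearObserver(w, "ho")


def regularized_hotelling_template(stats: EmpiricalStats,
                                   alpha_rho: float) -> LinearObserver:
    """RHO template: truncated-SVD pseudo-inverse of the covariance.

    Singular values of K no greater than ``alpha_rho * sigma_max`` are
    discarded before the Moore-Penrose inverse is applied to ``dmean``.
    """
    if not 0.0 < alpha_rho < 1.0:
        raise InvalidConfigurationError("alpha_rho must lie in (0, 1)")
    K = stats.covariance
    evals, evecs = scipy.linalg.eigh(K)
    sigma_max = evals[-1]
    keep = evals > alpha_rho * sigma_max
    if not np.any(keep):
        warnings.warn("RHO truncation removed every singular value; w = 0")
        return LinearObserver(np.zeros_like(stats.delta_mean), "rho",
                              {"alpha_rho": alpha_rho, "rank": 0})
    vk = evecs[:, keep]
    w = vk @ ((vk.T @ stats.delta_mean) / evals[keep])
    return LinearObserver(w, "rho", {"alpha_rho": alpha_rho,
                                     "rank": int(keep.sum())})


def select_rho_alpha(stats: EmpiricalStats, val_present: np.ndarray,
                     val_absent: np.ndarray,
                     alphas=(1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7)
                     ) -> LinearObserver:
    """Sweep the RHO threshold and keep the best validation AUC."""
    best = None
    best_auc = -1.0
    for alpha in alphas:
        obs = regularized_hotelling_template(stats, alpha)
        t = np.concatenate([obs.statistic(val_absent), obs.statistic(val_present)])
        y = np.concatenate([np.zeros(len(val_absent)), np.ones(len(val_present))])
        auc = empirical_auc(t, y).auc
        if auc > best_auc:
            best_auc = auc
            best = obs
    best.aux["validation_auc"] = best_auc
    return best


# ---------------------------------------------------------------------------
# DOG channels and the channelized HO
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DogChannelSet:
    n_channels: int = 10
    sigma0: float = 0.005  # cycles / pixel
    alpha_dog: float = 1.4
    Q_dog: float = 1.67


def build_dog_channels(channel_set: DogChannelSet, image_side: int) -> np.ndarray:
    """Dense difference-of-Gaussians channel matrix T (rows = channels).

    Channel j (j = 1..n) has the radial frequency profile

        C_j(rho) = exp(-(rho / (Q sigma_j))^2 / 2) - exp(-(rho / sigma_j)^2 / 2),

    sigma_j = sigma0 * alpha^j, sampled on the discrete FFT frequency grid
    and inverse-transformed to a spatial-domain channel vector.
    """
    if image_side < 16:
        raise InvalidConfigurationError("image_side must be >= 16")
    freqs = np.fft.fftfreq(image_side)
    rho = np.hypot(freqs[:, None], freqs[None, :])
    rows = []
    for j in range(1, channel_set.n_channels + 1):
        sj = channel_set.sigma0 * channel_set.alpha_dog ** j
        prof = (np.exp(-0.5 * (rho / (channel_set.Q_dog * sj)) ** 2)
                - np.exp(-0.5 * (rho / sj) ** 2))
        spatial = np.fft.ifft2(prof).real
        rows.append(spatial.ravel())
    return np.asarray(rows)


def channelize(channels: np.ndarray, images: np.ndarray) -> np.ndarray:
    return _flatten(images) @ channels.T


def cho_statistic(channels: np.ndarray, channel_stats: EmpiricalStats,
                  epsilon: float, images: np.ndarray, rng_seed) -> np.ndarray:
    """CHO test statistic with internal channel noise.

    ``channel_stats`` must be estimated from channelized data (see
    :func:`estimate_stats` on ``channelize`` outputs). The internal-noise
    covariance is ``eps * diag(Kv)``; a fresh noise vector is drawn per
    image from the dedicated ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    kv = channel_stats.covariance
    kint = epsilon * np.diag(np.diag(kv))
    try:
        template = scipy.linalg.solve(kv + kint, channel_stats.delta_mean,
                                      assume_a="sym")
    except scipy.linalg.LinAlgError as err:  # pragma: no cover
        raise SingularCovarianceError(str(err)) from err
    v = channelize(channels, images)
    v_int = rng.standard_normal(v.shape) * np.sqrt(np.diag(kint))[None, :]
    return (v + v_int) @ template


# ---------------------------------------------------------------------------
# learned single-layer observers (evaluation side)
# ---------------------------------------------------------------------------

def _detection_auc(obs: AppendedObserver, images: np.ndarray,
                   labels: np.ndarray) -> float:
    return empirical_auc(obs.detection_statistic(images),
                         (labels > 0).astype(int)).auc


def _train_slnn(kind: str, images: np.ndarray, labels: np.ndarray,
                val_images: np.ndarray, val_labels: np.ndarray,
                settings: TrainSettings, rng_seed) -> AppendedObserver:
    rng = np.random.default_rng(rng_seed)
    n_classes = int(labels.max()) + 1
    X = _flatten(images)
    obs = AppendedObserver(kind, X.shape[1], max(n_classes, 2), rng)
    opt = nn.Adam(lr=settings.learning_rate)
    best_auc = _detection_auc(obs, val_images, val_labels)
    best = (obs.w.copy(), obs.b.copy())
    for _ in range(settings.epochs):
        for idx in nn.balanced_batches(labels, settings.batch_size, rng):
            if kind == "slnn-no":
                _, _, dw, db = bce_task_loss(obs, X[idx],
                                             (labels[idx] > 0).astype(int),
                                             reduction="mean")
            else:
                _, _, dw, db = multiclass_task_loss(obs, X[idx], labels[idx],
                                                    reduction="mean")
            obs.grads = {"w": dw, "b": db}
            opt.step(list(obs.named_params()))
        auc = _detection_auc(obs, val_images, val_labels)
        if auc > best_auc:
            best_auc = auc
            best = (obs.w.copy(), obs.b.copy())
    obs.w, obs.b = best
    return obs


def train_slnn_no(train_present: np.ndarray, train_absent: np.ndarray,
                  val_present: np.ndarray, val_absent: np.ndarray,
                  settings: TrainSettings = TrainSettings(epochs=100),
                  rng_seed: int = 0) -> AppendedObserver:
    """Train an independent evaluation SLNN-NO with the BCE loss.

    The checkpoint with the best validation detection AUC is returned.
    """
    if len(train_present) == 0 or len(train_absent) == 0:
        raise InsufficientDataError("both classes are required")
    images = np.concatenate([train_absent, train_present])
    labels = np.concatenate([
        np.zeros(len(train_absent), dtype=int),
        np.ones(len(train_present), dtype=int),
    ])
    val_images = np.concatenate([val_absent, val_present])
    val_labels = np.concatenate([
        np.zeros(len(val_absent), dtype=int), np.ones(len(val_present), dtype=int)
    ])
    return _train_slnn("slnn-no", images, labels, val_images, val_labels,
                       settings, rng_seed)


def train_slnn_multiclass(images: np.ndarray, labels: np.ndarray,
                          val_images: np.ndarray, val_labels: np.ndarray,
                          settings: TrainSettings = TrainSettings(epochs=100),
                          rng_seed: int = 0) -> AppendedObserver:
    """Train the softmax SLNN for a detection-localization task.

    Labels are 0..J and every class must appear in the training data. The
    scalar detection statistic of the returned observer is
    ``1 - P(class 0)``; localization is the argmax over classes 1..J.
    """
    labels = np.asarray(labels)
    n_classes = int(labels.max()) + 1
    present_classes = np.unique(labels)
    if len(present_classes) != n_classes:
        raise InsufficientDataError("every class 0..J must appear in the data")
    return _train_slnn("slnn-multiclass", np.asarray(images), labels,
                       np.asarray(val_images), np.asarray(val_labels),
                       settings, rng_seed)


def train_evaluation_slnn(train: ImageEnsemble, val: ImageEnsemble,
                          variant: str, task_kind: str = "binary-detection",
                          settings: TrainSettings = TrainSettings(epochs=100),
                          rng_seed: int = 0) -> AppendedObserver:
    """Convenience wrapper: fit the evaluation observer on an ensemble variant."""
    if task_kind == "detection-localization":
        return train_slnn_multiclass(
            train.variant(variant), train.labels,
            val.variant(variant), val.labels, settings, rng_seed,
        )
    return train_slnn_no(
        train.present(variant), train.absent(variant),
        val.present(variant), val.absent(variant), settings, rng_seed,
    )
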