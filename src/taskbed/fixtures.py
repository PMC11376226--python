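"""Deterministic miniature fixtures with closed-form properties.

The central fixture is a two-class multivariate Gaussian ensemble with a
known shared covariance ``K`` and mean shift ``dmu``: the ideal linear
(Hotelling) observer for this family has the test statistic
``t = (K^-1 dmu)^T x`` with equal class variances SNR^2 and mean separation
SNR^2, hence the closed-form AUC

    AUC = Phi(SNR / sqrt(2)),    SNR^2 = dmu^T K^-1 dmu,

which anchors the observer implementations to an analytic value. A smooth
blob phantom generator supports projector/reconstruction round-trip checks.
These fixtures exist to make the mathematics testable, not to be realistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass(frozen=True)
class GaussianTwoClassSpec:
    dimension: int
    covariance: np.ndarray
    mean_shift: np.ndarray
    n_per_class: int
    seed: int = 0

    def __post_init__(self) -> None:
        K = np.asarray(self.covariance, dtype=np.float64)
        if K.shape != (self.dimension, self.dimension):
            raise ValueError("covariance shape mismatch")
        if not np.allclose(K, K.T):
            raise ValueError("covariance must be symmetric")
        evals = np.linalg.eigvalsh(K)
        if evals[0] <= 0:
            raise ValueError("covariance must be positive definite")


@dataclass
class TwoClassSample:
    """Draws from the two Gaussians; absent ~ N(0, K), present ~ N(dmu, K)."""

    absent: np.ndarray   # (n, d)
    present: np.ndarray  # (n, d)

    @property
    def samples(self) -> np.ndarray:
        return np.concatenate([self.absent, self.present])

    @property
    def labels(self) -> np.ndarray:
        n0, n1 = len(self.absent), len(self.present)
        return np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])


def make_gaussian_ensemble(spec: GaussianTwoClassSpec) -> TwoClassSample:
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(np.asarray(spec.covariance, dtype=np.float64))
    z0 = rng.standard_normal((spec.n_per_class, spec.dimension))
    z1 = rng.standard_normal((spec.n_per_class, spec.dimension))
    mu = np.asarray(spec.mean_shift, dtype=np.float64)
    return TwoClassSample(absent=z0 @ L.T, present=z1 @ L.T + mu)


def analytic_hotelling_auc(spec: GaussianTwoClassSpec) -> float:
    """Closed-form ideal linear-observer AUC: Phi(SNR / sqrt(2))."""
    K = np.asarray(spec.covariance, dtype=np.float64)
    dmu = np.asarray(spec.mean_shift, dtype=np.float64)
    snr = float(np.sqrt(dmu @ np.linalg.solve(K, dmu)))
    return float(norm.cdf(snr / math.sqrt(2.0)))


def make_smooth_phantom(side: int, n_blobs: int = 40, amplitude: float = 0.01,
                        width: float = 6.0, dc: float = 0.02,
                        seed: int = 0) -> np.ndarray:
    """Smooth nonnegative blob phantom for projection round-trip checks."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    img = np.full((side, side), dc)
    margin = side // 8
    for _ in range(n_blobs):
        r0, c0 = rng.uniform(margin, side - margin, 2)
        img += amplitude * np.exp(-((yy - r0) ** 2 + (xx - c0) ** 2)
                                  / (2.0 * width ** 2))
    return img
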