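"""Figures of merit: empirical ROC/AUC, RMSE, SSIM, covariance spectra.

AUC is the nonparametric Mann-Whitney estimate (ties counted one half) with
the Hanley-McNeil standard error; it equals the probability that a randomly
chosen signal-present statistic exceeds a signal-absent one and is invariant
under any strictly increasing transform of the statistics. SSIM uses the
standard 11-pixel Gaussian window with K1 = 0.01, K2 = 0.03 and a dynamic
range taken from the reference ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from skimage.metrics import structural_similarity

from .denoiser import InvalidInputError


class SingleClassError(ValueError):
    pass


@dataclass
class RocResult:
    auc: float
    se: float
    n_present: int
    n_absent: int
    statistic_values: np.ndarray
    labels: np.ndarray


def empirical_auc(statistics: np.ndarray, labels: np.ndarray) -> RocResult:
    """Mann-Whitney AUC with ties counted one half, and Hanley-McNeil SE."""
    statistics = np.asarray(statistics, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels > 0
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    if n0 == 0 or n1 == 0:
        raise SingleClassError("empirical_auc requires both classes")
    ranks = rankdata(statistics)  # average ranks implement the ties-1/2 rule
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
           + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
    return RocResult(float(auc), float(np.sqrt(max(var, 0.0))), n1, n0,
                     statistics, labels)


def rmse(images_a: np.ndarray, images_b: np.ndarray) -> float:
    """Root mean squared pixel difference over the whole ensemble."""
    a = np.asarray(images_a, dtype=np.float64)
    b = np.asarray(images_b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidInputError("shape mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def ssim(images_a: np.ndarray, images_b: np.ndarray,
         data_range: float | None = None) -> float:
    """Mean SSIM over the ensemble (Gaussian 11-pixel window, K1/K2 standard).

    ``data_range`` defaults to the peak-to-peak range of ``images_b`` (the
    reference/target ensemble).
    """
    a = np.asarray(images_a, dtype=np.float64)
    b = np.asarray(images_b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidInputError("shape mismatch")
    if a.ndim == 2:
        a, b = a[None], b[None]
    if data_range is None:
        data_range = float(b.max() - b.min())
    vals = [
        structural_similarity(
            x, y, data_range=data_range, gaussian_weights=True,
            sigma=1.5, win_size=11, K1=0.01, K2=0.03,
        )
        for x, y in zip(a, b)
    ]
    return float(np.mean(vals))


@dataclass
class SpectrumResult:
    singular_values: np.ndarray  # descending, >= 0
    condition_ratio: float
    rank_k: int


def covariance_spectrum(stats, rank_k: int = 100) -> SpectrumResult:
    """Singular values of a covariance matrix, descending, plus a condition
    ratio sigma_max / sigma_k at the configured rank.

    ``stats`` may be an object with a ``covariance`` attribute or the matrix
    itself.
    """
    K = getattr(stats, "covariance", stats)
    K = np.asarray(K, dtype=np.float64)
    if np.allclose(K, K.T):
        # symmetric: singular values are |eigenvalues|, via the faster eigh
        sv = np.abs(np.linalg.eigvalsh(K))
    else:
        sv = np.linalg.svd(K, compute_uv=False)
    sv = np.sort(sv)[::-1]
    k = min(rank_k, sv.size) - 1
    ratio = float(sv[0] / sv[k]) if sv[k] > 0 else float("inf")
    return SpectrumResult(sv, ratio, k + 1)
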