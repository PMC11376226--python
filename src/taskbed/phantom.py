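"""Stochastic object models for signal-detection tasks.

Backgrounds are *lumpy*: a constant offset plus a Poisson-distributed number
of Gaussian blobs with uniformly random centres — the standard seedable
background-known-statistically (BKS) object model of the model-observer
literature. Signals are compact Gaussian blobs inserted additively at a
location drawn from a configurable law (fixed, uniform in a disc, or one of
J discrete sites), which realizes signal-known-statistically (SKS)
variability. A :class:`TaskSpec` bundles background, signal, location law,
and the incident photon flux that sets the measurement-noise level.

Lumps and signals are evaluated on the full pixel grid using the minimal
torus (wrap-around) distance for backgrounds, which makes the background
process exactly stationary: the ensemble pixel mean is
``dc_offset + mean_lump_count * lump_integral / area`` everywhere.
Coordinates are 0-based (row, col) with pixel centres at integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import ImageEnsemble, TARGET


class InvalidConfigurationError(ValueError):
    pass


class InvalidLocationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# object models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundModel:
    """Stationary lumpy background.

    Parameters
    ----------
    image_side
        Grid side in pixels (>= 16).
    mean_lump_count
        Mean of the Poisson number of lumps per realization.
    lump_amplitude, lump_width
        Peak value and Gaussian scale (pixels) of each lump.
    dc_offset
        Constant added to every pixel.
    """

    image_side: int = 64
    mean_lump_count: float = 30.0
    lump_amplitude: float = 0.035
    lump_width: float = 6.0
    dc_offset: float = 0.05

    def __post_init__(self) -> None:
        if self.image_side < 16:
            raise InvalidConfigurationError("image_side must be >= 16")
        if self.mean_lump_count < 0:
            raise InvalidConfigurationError("mean_lump_count must be >= 0")


@dataclass(frozen=True)
class SignalModel:
    """Compact Gaussian signal blob.

    ``shape='elliptical-gaussian'`` stretches the row axis by ``eccentricity``
    and shrinks the column axis by the same factor, preserving area.
    """

    amplitude: float = 0.4
    width: float = 1.0
    shape: str = "isotropic-gaussian"
    eccentricity: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("isotropic-gaussian", "elliptical-gaussian"):
            raise InvalidConfigurationError(f"unknown signal shape {self.shape!r}")
        if self.eccentricity <= 0:
            raise InvalidConfigurationError("eccentricity must be > 0")


@dataclass(frozen=True)
class LocationLaw:
    """Signal-location randomness: fixed, uniform-disc, or discrete-sites."""

    mode: str = "fixed"
    center: tuple[float, float] | None = None
    radius_r: float = 0.0
    sites: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "uniform-disc", "discrete-sites"):
            raise InvalidConfigurationError(f"unknown location mode {self.mode!r}")
        if self.mode in ("fixed", "uniform-disc") and self.center is None:
            raise InvalidConfigurationError(f"{self.mode} requires a center")
        if self.mode == "uniform-disc" and self.radius_r <= 0:
            raise InvalidConfigurationError("uniform-disc requires radius_r > 0")
        if self.mode == "discrete-sites" and len(self.sites) < 1:
            raise InvalidConfigurationError("discrete-sites requires sites")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample(self, rng: np.random.Generator) -> tuple[tuple[float, float], int]:
        """Draw one location; returns ((row, col), label).

        Labels are 1 for fixed/uniform-disc draws and 1..J for site draws.
        """
        if self.mode == "fixed":
            return tuple(self.center), 1
        if self.mode == "uniform-disc":
            # sqrt radial sampling => uniform density over the disc
            r = self.radius_r * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            return (self.center[0] + r * math.sin(theta),
                    self.center[1] + r * math.cos(theta)), 1
        j = int(rng.integers(len(self.sites)))
        return tuple(self.sites[j]), j + 1


@dataclass(frozen=True)
class TaskSpec:
    """Full description of a detection or detection-localization task."""

    task_kind: str = "binary-detection"
    background: BackgroundModel = field(default_factory=BackgroundModel)
    signal: SignalModel = field(default_factory=SignalModel)
    location: LocationLaw = field(
        default_factory=lambda: LocationLaw(mode="fixed", center=(31.5, 31.5))
    )
    incident_flux_I0: float = math.e ** 11

    def __post_init__(self) -> None:
        if self.task_kind not in ("binary-detection", "detection-localization"):
            raise InvalidConfigurationError(f"unknown task kind {self.task_kind!r}")
        if self.task_kind == "detection-localization":
            if self.location.mode != "discrete-sites" or self.location.n_sites < 2:
                raise InvalidConfigurationError(
                    "detection-localization requires discrete-sites with J >= 2"
                )
        if self.incident_flux_I0 <= 0:
            raise InvalidConfigurationError("incident_flux_I0 must be > 0")

    @property
    def n_classes(self) -> int:
        """Number of hypothesis classes including signal-absent."""
        if self.task_kind == "detection-localization":
            return self.location.n_sites + 1
        return 2

    def manifest(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# realization sampling
# ---------------------------------------------------------------------------

def _torus_gaussian(side: int, centers: np.ndarray, amps: np.ndarray,
                    width: float) -> np.ndarray:
    """Sum of Gaussian lumps on a torus (minimal wrap-around distance)."""
    rows = np.arange(side, dtype=np.float64)
    out = np.zeros((side, side))
    if centers.size == 0:
        return out
    dr = np.abs(rows[None, :] - centers[:, 0:1])
    dr = np.minimum(dr, side - dr)  # (n_lumps, side)
    dc = np.abs(rows[None, :] - centers[:, 1:2])
    dc = np.minimum(dc, side - dc)
    er = np.exp(-0.5 * (dr / width) ** 2)
    ec = np.exp(-0.5 * (dc / width) ** 2)
    # separable outer product per lump, accumulated
    out = np.einsum("kr,kc,k->rc", er, ec, amps)
    return out


def sample_background(model: BackgroundModel, rng_seed) -> np.ndarray:
    """Draw one noiseless signal-absent background realization.

    ``rng_seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(rng_seed)
    side = model.image_side
    n = int(rng.poisson(model.mean_lump_count))
    centers = rng.uniform(0.0, side, size=(n, 2))
    amps = np.full(n, model.lump_amplitude)
    return model.dc_offset + _torus_gaussian(side, centers, amps, model.lump_width)


def render_signal(model: SignalModel, center: tuple[float, float],
                  image_side: int) -> np.ndarray:
    """Render the signal image f_s at a (row, col) centre (no wrap-around)."""
    r0, c0 = center
    if not (0 <= r0 <= image_side - 1 and 0 <= c0 <= image_side - 1):
        raise InvalidLocationError(f"center {center} outside image bounds")
    rows = np.arange(image_side, dtype=np.float64)
    if model.shape == "elliptical-gaussian":
        sr = model.width * model.eccentricity
        sc = model.width / model.eccentricity
    else:
        sr = sc = model.width
    er = np.exp(-0.5 * ((rows - r0) / sr) ** 2)
    ec = np.exp(-0.5 * ((rows - c0) / sc) ** 2)
    return model.amplitude * np.outer(er, ec)


def build_ensemble(task: TaskSpec, n_present: int, n_absent: int,
                   rng_seed) -> ImageEnsemble:
    """Assemble noiseless target images for a task.

    Signal-present images are ``f_b + f_s`` with the location drawn from the
    task's location law; labels record the location class (1..J for
    detection-localization, 1 for binary tasks).
    """
    if n_present < 0 or n_absent < 0:
        raise InvalidConfigurationError("counts must be >= 0")
    rng = np.random.default_rng(rng_seed)
    side = task.background.image_side
    n = n_present + n_absent
    pixels = np.empty((n, side, side), dtype=np.float64)
    labels = np.zeros(n, dtype=np.int64)
    centers = np.full((n, 2), np.nan)
    for i in range(n_absent):
        pixels[i] = sample_background(task.background, rng)
    for i in range(n_absent, n):
        bg = sample_background(task.background, rng)
        center, label = task.location.sample(rng)
        pixels[i] = bg + render_signal(task.signal, center, side)
        labels[i] = label
        centers[i] = center
    # interleave classes deterministically so contiguous slices stay balanced
    order = rng.permutation(n)
    return ImageEnsemble(
        {TARGET: pixels[order]}, labels[order], centers[order], task.manifest()
    )
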