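"""Stylized fan-beam CT: forward projection, Poisson noise, Ram-Lak FBP.

The forward model is a discrete-to-discrete approximation ``H`` of the
fan-beam transform: for every view the source moves on a circle of radius
``source_to_center`` and a flat detector of equispaced elements sits on the
opposite side; each sinogram entry is the line integral along the ray from
the source through a detector-element centre, evaluated by equidistant
sampling with bilinear interpolation (step = half a pixel).

Low-dose data follow the exponential transmission model

    g = T^-1( Poi( T(Hf) ) ),   T(x) = I0 exp(-x),   T^-1(x) = log(I0 / x),

where ``I0`` is the incident photon flux per detector element (default
``e^11``). A Poisson draw of zero counts is clamped to a configurable floor
(default 1 count) before the log.

Reconstruction is full-scan fan-beam filtered back-projection for a flat
equidistant detector: cosine weighting, Ram-Lak (ramp) filtering in the
detector variable (frequency domain, zero-padded to the next power of two,
no apodization window), and distance-weighted back-projection.

Geometry conventions: world coordinates in mm, origin at the image centre,
x to the right (+columns), y up (-rows); view angles are measured
counterclockwise from the +x axis; the detector coordinate increases with
the element index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp

from .containers import ImageEnsemble, TARGET, LOWDOSE
from .phantom import InvalidConfigurationError


@dataclass(frozen=True)
class ScannerGeometry:
    n_views: int = 256
    angular_range: float = 360.0
    n_detector_elements: int = 512
    detector_element_size: float = 0.8
    source_to_center: float = 400.0
    detector_to_center: float = 400.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise InvalidConfigurationError("n_views must be >= 1")
        if self.n_detector_elements < 2:
            raise InvalidConfigurationError("need at least 2 detector elements")
        if self.source_to_center <= 0 or self.detector_to_center < 0:
            raise InvalidConfigurationError("invalid source/detector distances")

    @property
    def view_angles(self) -> np.ndarray:
        span = math.radians(self.angular_range)
        return span * np.arange(self.n_views) / self.n_views

    def manifest(self) -> dict:
        return asdict(self)


@dataclass
class Sinogram:
    values: np.ndarray  # (n_views, n_detector_elements)
    geometry: ScannerGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_views, self.geometry.n_detector_elements)
        if self.values.shape != expected:
            raise InvalidConfigurationError(
                f"sinogram shape {self.values.shape} != geometry {expected}"
            )


@dataclass(frozen=True)
class NoiseModel:
    incident_flux_I0: float = math.e ** 11
    count_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.incident_flux_I0 <= 0:
            raise InvalidConfigurationError("I0 must be > 0")


# ---------------------------------------------------------------------------
# fan-beam system (cached per geometry + grid)
# ---------------------------------------------------------------------------

class FanBeamSystem:
    """Forward projector + FBP for one (geometry, image grid) pair.

    When the ray-sampling footprint is small enough, the projector and the
    FBP back-projector are materialized as sparse matrices so ensembles are
    projected/reconstructed as single sparse products; otherwise the same
    sampling scheme is evaluated on the fly view by view. Both paths use
    identical sample positions and weights.
    """

    def __init__(self, geometry: ScannerGeometry, image_side: int,
                 step_fraction: float = 0.5, max_sparse_nnz: float = 4e7):
        if image_side < 16:
            raise InvalidConfigurationError("image_side must be >= 16")
        self.geometry = geometry
        self.side = int(image_side)
        ps = geometry.pixel_size
        self.step = step_fraction * ps
        # half-diagonal of the pixel grid: rays sample the whole square
        self.r_img = 0.5 * math.sqrt(2.0) * self.side * ps
        self.n_samples = int(math.ceil(2.0 * self.r_img / self.step)) + 1
        nnz_est = (geometry.n_views * geometry.n_detector_elements
                   * self.n_samples * 4)
        self._use_sparse = nnz_est <= max_sparse_nnz
        self._P: sp.csr_matrix | None = None
        self._B: sp.csr_matrix | None = None
        self._init_filter()

    # -- ray sampling --------------------------------------------------------
    def _view_samples(self, beta: float):
        """Bilinear gather (indices, weights) for all rays of one view."""
        g = self.geometry
        ps = g.pixel_size
        s_pos = g.source_to_center * np.array([math.cos(beta), math.sin(beta)])
        d0 = -g.detector_to_center * np.array([math.cos(beta), math.sin(beta)])
        e_u = np.array([-math.sin(beta), math.cos(beta)])
        u = (np.arange(g.n_detector_elements) - (g.n_detector_elements - 1) / 2.0) \
            * g.detector_element_size
        p_det = d0[None, :] + u[:, None] * e_u[None, :]  # (n_det, 2)
        direction = p_det - s_pos[None, :]
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        t_ca = -(s_pos[None, :] * direction).sum(axis=1)  # closest approach to origin
        offs = (np.arange(self.n_samples) - (self.n_samples - 1) / 2.0) * self.step
        t = t_ca[:, None] + offs[None, :]  # (n_det, K)
        xy = s_pos[None, None, :] + t[..., None] * direction[:, None, :]
        # world -> pixel indices (row down, col right)
        col = xy[..., 0] / ps + (self.side - 1) / 2.0
        row = (self.side - 1) / 2.0 - xy[..., 1] / ps
        r0 = np.floor(row).astype(np.int64)
        c0 = np.floor(col).astype(np.int64)
        fr = row - r0
        fc = col - c0
        idx, wts = [], []
        for dr, dc, w in (
            (0, 0, (1 - fr) * (1 - fc)),
            (0, 1, (1 - fr) * fc),
            (1, 0, fr * (1 - fc)),
            (1, 1, fr * fc),
        ):
            rr = r0 + dr
            cc = c0 + dc
            valid = (rr >= 0) & (rr < self.side) & (cc >= 0) & (cc < self.side)
            idx.append(np.where(valid, rr * self.side + cc, 0))
            wts.append(np.where(valid, w, 0.0) * self.step)
        return idx, wts

    def _build_projection_matrix(self) -> sp.csr_matrix:
        g = self.geometry
        rows, cols, data = [], [], []
        ray_base = np.arange(g.n_detector_elements)[:, None]
        ray_base = np.broadcast_to(ray_base, (g.n_detector_elements, self.n_samples))
        for k, beta in enumerate(g.view_angles):
            idx, wts = self._view_samples(beta)
            ray_ids = (k * g.n_detector_elements + ray_base).ravel()
            for ii, ww in zip(idx, wts):
                keep = ww.ravel() > 0
                rows.append(ray_ids[keep])
                cols.append(ii.ravel()[keep])
                data.append(ww.ravel()[keep])
        n_rays = g.n_views * g.n_detector_elements
        P = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_rays, self.side * self.side),
        ).tocsr()
        return P

    @property
    def projection_matrix(self) -> sp.csr_matrix:
        if self._P is None:
            self._P = self._build_projection_matrix()
        return self._P

    def project_batch(self, images: np.ndarray) -> np.ndarray:
        """Project images of shape (B, side, side) -> (B, n_views, n_det)."""
        g = self.geometry
        images = np.asarray(images, dtype=np.float64)
        B = images.shape[0]
        flat = images.reshape(B, -1)
        if self._use_sparse:
            out = self.projection_matrix @ flat.T  # (n_rays, B)
            return out.T.reshape(B, g.n_views, g.n_detector_elements)
        sino = np.empty((B, g.n_views, g.n_detector_elements))
        for k, beta in enumerate(g.view_angles):
            idx, wts = self._view_samples(beta)
            acc = np.zeros((B, g.n_detector_elements, self.n_samples))
            for ii, ww in zip(idx, wts):
                acc += flat[:, ii.ravel()].reshape(B, *ii.shape) * ww[None]
            sino[:, k, :] = acc.sum(axis=2)
        return sino

    def project(self, image: np.ndarray) -> np.ndarray:
        return self.project_batch(image[None])[0]

    def backproject_adjoint(self, sino: np.ndarray) -> np.ndarray:
        """Exact transpose of the forward projector (not the FBP)."""
        g = self.geometry
        flat = np.asarray(sino, dtype=np.float64).reshape(-1)
        if self._use_sparse:
            return (self.projection_matrix.T @ flat).reshape(self.side, self.side)
        out = np.zeros(self.side * self.side)
        for k, beta in enumerate(g.view_angles):
            idx, wts = self._view_samples(beta)
            row = sino[k]  # (n_det,)
            for ii, ww in zip(idx, wts):
                np.add.at(out, ii.ravel(), (ww * row[:, None]).ravel())
        return out.reshape(self.side, self.side)

    # -- FBP -----------------------------------------------------------------
    def _init_filter(self) -> None:
        g = self.geometry
        # virtual detector rebinned to the isocenter
        mag = g.source_to_center / (g.source_to_center + g.detector_to_center)
        self.du_iso = g.detector_element_size * mag
        u_iso = (np.arange(g.n_detector_elements)
                 - (g.n_detector_elements - 1) / 2.0) * self.du_iso
        self.cos_weight = g.source_to_center / np.sqrt(
            g.source_to_center ** 2 + u_iso ** 2
        )
        n_pad = 1 << int(math.ceil(math.log2(2 * g.n_detector_elements)))
        n = np.fft.fftfreq(n_pad) * n_pad  # 0, 1, ..., -1 ordering
        h = np.zeros(n_pad)
        h[0] = 1.0 / (4.0 * self.du_iso ** 2)
        odd = (np.abs(n) % 2) == 1
        h[odd] = -1.0 / (np.pi * n[odd] * self.du_iso) ** 2
        self._n_pad = n_pad
        # h is even-symmetric on the circulant grid: its spectrum is real
        self._ramp_rfft = np.fft.rfft(h).real

    def filter_sinogram(self, sino: np.ndarray) -> np.ndarray:
        """Cosine-weight and ramp-filter; accepts (..., n_views, n_det)."""
        g = self.geometry
        sino = np.asarray(sino, dtype=np.float64)
        out = np.empty_like(sino)
        flat_in = sino.reshape(-1, g.n_views, g.n_detector_elements)
        flat_out = out.reshape(-1, g.n_views, g.n_detector_elements)
        chunk = max(1, int(2e6 // (g.n_views * self._n_pad)))
        for a in range(0, flat_in.shape[0], chunk):
            weighted = flat_in[a : a + chunk] * self.cos_weight
            spec = np.fft.rfft(weighted, n=self._n_pad, axis=-1)
            filt = np.fft.irfft(spec * self._ramp_rfft, n=self._n_pad, axis=-1)
            flat_out[a : a + chunk] = filt[..., : g.n_detector_elements]
        return out * self.du_iso

    def _build_backprojection_matrix(self) -> sp.csr_matrix:
        g = self.geometry
        ps = g.pixel_size
        R = g.source_to_center
        half = (self.side - 1) / 2.0
        cols_px = np.arange(self.side)
        x = (cols_px - half) * ps
        y = (half - np.arange(self.side)) * ps
        X = np.broadcast_to(x[None, :], (self.side, self.side)).ravel()
        Y = np.broadcast_to(y[:, None], (self.side, self.side)).ravel()
        dbeta = math.radians(g.angular_range) / g.n_views
        # full 360-degree scan covers every ray twice
        scale = 0.5 * dbeta * (360.0 / g.angular_range)
        rows, cols, data = [], [], []
        pix_ids = np.arange(self.side * self.side)
        for k, beta in enumerate(g.view_angles):
            L = R - X * math.cos(beta) - Y * math.sin(beta)
            p = -X * math.sin(beta) + Y * math.cos(beta)
            u = p * R / L
            fi = u / self.du_iso + (g.n_detector_elements - 1) / 2.0
            i0 = np.floor(fi).astype(np.int64)
            f = fi - i0
            w = scale * (R / L) ** 2
            for di, wi in ((0, (1 - f) * w), (1, f * w)):
                ii = i0 + di
                valid = (ii >= 0) & (ii < g.n_detector_elements)
                rows.append(pix_ids[valid])
                cols.append(k * g.n_detector_elements + ii[valid])
                data.append(wi[valid])
        B = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.side * self.side, g.n_views * g.n_detector_elements),
        ).tocsr()
        return B

    @property
    def backprojection_matrix(self) -> sp.csr_matrix:
        if self._B is None:
            self._B = self._build_backprojection_matrix()
        return self._B

    def fbp_batch(self, sinos: np.ndarray) -> np.ndarray:
        filtered = self.filter_sinogram(sinos)
        B = filtered.shape[0]
        out = self.backprojection_matrix @ filtered.reshape(B, -1).T
        return out.T.reshape(B, self.side, self.side)

    def fbp(self, sino: np.ndarray) -> np.ndarray:
        return self.fbp_batch(np.asarray(sino)[None])[0]


_SYSTEM_CACHE: dict[tuple, FanBeamSystem] = {}


def get_system(geometry: ScannerGeometry, image_side: int) -> FanBeamSystem:
    key = (geometry, int(image_side))
    if key not in _SYSTEM_CACHE:
        _SYSTEM_CACHE[key] = FanBeamSystem(geometry, image_side)
    return _SYSTEM_CACHE[key]


# ---------------------------------------------------------------------------
# spec-level operations
# ---------------------------------------------------------------------------

def forward_project(image: np.ndarray, geometry: ScannerGeometry) -> Sinogram:
    """Discrete-to-discrete fan-beam projection of a square image."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise InvalidConfigurationError("image must be 2-D square")
    system = get_system(geometry, image.shape[0])
    return Sinogram(system.project(image), geometry)


def apply_noise(sinogram: Sinogram, noise: NoiseModel, rng_seed) -> Sinogram:
    """Exponential-transform Poisson noise: T^-1(Poi(T(Hf)))."""
    rng = np.random.default_rng(rng_seed)
    x = sinogram.values
    if not np.all(np.isfinite(x)):
        raise InvalidConfigurationError("sinogram contains non-finite values")
    lam = noise.incident_flux_I0 * np.exp(-x)
    counts = rng.poisson(lam).astype(np.float64)
    counts = np.maximum(counts, noise.count_floor)  # zero counts -> floor before log
    return Sinogram(np.log(noise.incident_flux_I0 / counts), sinogram.geometry)


def fbp_reconstruct(sinogram: Sinogram, image_side: int) -> np.ndarray:
    """Fan-beam Ram-Lak filtered back-projection onto a square pixel grid."""
    system = get_system(sinogram.geometry, image_side)
    return system.fbp(sinogram.values)


def crop_center(images: np.ndarray, side: int) -> np.ndarray:
    full = images.shape[-1]
    if side > full:
        raise InvalidConfigurationError("crop side exceeds image side")
    a = (full - side) // 2
    return images[..., a : a + side, a : a + side]


def simulate_lowdose(ensemble: ImageEnsemble, geometry: ScannerGeometry,
                     noise: NoiseModel, rng_seed, roi_side: int | None = None
                     ) -> ImageEnsemble:
    """Project, corrupt, and reconstruct every noiseless target image.

    Each target ``f`` yields the paired low-dose image
    ``f_n = FBP(T^-1(Poi(T(Hf))))``. If ``roi_side`` is given the ensemble
    is assumed to hold full-field targets; both variants are centre-cropped
    to the ROI after reconstruction and signal centres are shifted
    accordingly.
    """
    if len(ensemble) == 0:
        raise InvalidConfigurationError("ensemble is empty")
    rng = np.random.default_rng(rng_seed)
    targets = ensemble.variant(TARGET)
    system = get_system(geometry, targets.shape[-1])
    sinos = system.project_batch(targets)
    lam = noise.incident_flux_I0 * np.exp(-sinos)
    counts = np.maximum(rng.poisson(lam).astype(np.float64), noise.count_floor)
    noisy = np.log(noise.incident_flux_I0 / counts)
    lowdose = system.fbp_batch(noisy)
    centers = ensemble.signal_centers
    if roi_side is not None:
        off = (targets.shape[-1] - roi_side) // 2
        targets = crop_center(targets, roi_side)
        lowdose = crop_center(lowdose, roi_side)
        centers = centers - off
    manifest = dict(ensemble.task_manifest)
    manifest["geometry"] = geometry.manifest()
    manifest["noise"] = {"incident_flux_I0": noise.incident_flux_I0,
                         "count_floor": noise.count_floor}
    return ImageEnsemble(
        {TARGET: targets, LOWDOSE: lowdose}, ensemble.labels, centers, manifest
    )
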