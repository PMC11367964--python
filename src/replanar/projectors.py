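"""Forward models: attenuated anterior projection, multi-angle SPECT
acquisition, and CT-number-to-attenuation conversion.

The anterior planar model mimics a conventional gamma camera: every voxel
contributes its activity weighted by the survival probability
``exp(-sum mu * step)`` of a photon travelling from that voxel to the
anterior face of the grid (midpoint convention: the emitting voxel itself
contributes half a step).  The multi-angle model is a parallel-beam
abstraction of a ring-detector SPECT acquisition: the volume is rotated
about the z axis and projected with the same attenuated kernel at each
detector azimuth.  Both share one slab kernel, so reconstruction uses the
identical system model that generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ._rotation import plane_rotation_matrix
from .geometry import (ActivityVolume, CTVolume, MuMap,
                       PlanarImage, ProjectionSet)
from .phantom import MU_SOFT_TISSUE, MU_BONE

__all__ = [
    "DetectorModel",
    "attenuation_path_factor",
    "anterior_attenuation_factors",
    "simulate_planar",
    "simulate_spect",
    "default_spect_angles",
    "hu_to_mu",
    "RotationProjector",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class DetectorModel:
    """Detector response: sensitivity scale and an optional depth-dependent
    Gaussian PSF approximating a low-energy high-resolution collimator
    (FWHM = fwhm0 + slope * source-detector distance)."""

    sensitivity: float = 1.0      # expected counts per activity-unit * mm
    psf: bool = False
    psf_fwhm0_mm: float = 4.0
    psf_slope: float = 0.04       # mm of FWHM per mm of distance

    def __post_init__(self) -> None:
        if self.psf_fwhm0_mm < 0 or self.psf_slope < 0:
            raise ValueError("PSF parameters must be >= 0")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")

    def sigma_pix(self, distance_mm: float, pixel_size_mm: float) -> float:
        fwhm = self.psf_fwhm0_mm + self.psf_slope * distance_mm
        return fwhm * _FWHM_TO_SIGMA / pixel_size_mm


def anterior_attenuation_factors(mu: np.ndarray, voxel_size_mm: float) -> np.ndarray:
    """Per-voxel survival factor toward the anterior (y=0) face.

    ``exp(-step * (sum of mu over voxels nearer the face + mu_self / 2))``.
    """
    csum = np.cumsum(mu, axis=1)
    return np.exp(-voxel_size_mm * (csum - 0.5 * mu))


def attenuation_path_factor(mu: MuMap, voxel_index: tuple[int, int, int],
                            direction: str = "anterior") -> float:
    """Survival probability for a photon from one voxel to the grid edge."""
    if direction != "anterior":
        raise ValueError("only the anterior direction is supported")
    z, y, x = voxel_index
    nz, ny, nx = mu.grid.shape
    if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx):
        raise IndexError(f"voxel index {voxel_index} outside grid {mu.grid.shape}")
    d = mu.grid.voxel_size_mm
    path = mu.data[z, :y, x].sum() + 0.5 * mu.data[z, y, x]
    return float(np.exp(-d * path))


def _slab_project(act: np.ndarray, factors: np.ndarray, det: DetectorModel,
                  voxel_size_mm: float) -> np.ndarray:
    """Shared anterior projection kernel: (nz, ny, nx) -> (nz, nx)."""
    term = act * factors
    if det.psf:
        term = term.copy()
        for iy in range(term.shape[1]):
            sigma = det.sigma_pix((iy + 0.5) * voxel_size_mm, voxel_size_mm)
            if sigma > 0:
                term[:, iy, :] = gaussian_filter(term[:, iy, :], sigma,
                                                 mode="constant")
    return det.sensitivity * voxel_size_mm * term.sum(axis=1)


def _slab_backproject(proj: np.ndarray, factors: np.ndarray, det: DetectorModel,
                      voxel_size_mm: float) -> np.ndarray:
    """Exact adjoint of :func:`_slab_project`: (nz, nx) -> (nz, ny, nx)."""
    nz, ny, nx = factors.shape
    vol = np.broadcast_to(proj[:, None, :],
                          (nz, ny, nx)) * (det.sensitivity * voxel_size_mm)
    if det.psf:
        vol = vol.copy()
        for iy in range(ny):
            sigma = det.sigma_pix((iy + 0.5) * voxel_size_mm, voxel_size_mm)
            if sigma > 0:
                # Gaussian correlation with zero padding is self-adjoint
                vol[:, iy, :] = gaussian_filter(vol[:, iy, :], sigma,
                                                mode="constant")
    return vol * factors


def simulate_planar(activity: ActivityVolume, mu: MuMap,
                    det: DetectorModel | None = None, seed: int | None = None,
                    noiseless: bool = True) -> PlanarImage:
    """Simulate an anterior planar acquisition on a conventional camera.

    Noiseless pixel (z, x) = sensitivity * step * sum_y activity * survival
    factor; with ``noiseless=False`` each pixel is replaced by a seeded
    Poisson draw with that mean.
    """
    if activity.grid != mu.grid:
        raise ValueError("activity and mu must share one grid")
    det = det or DetectorModel()
    d = activity.grid.voxel_size_mm
    factors = anterior_attenuation_factors(mu.data, d)
    img = _slab_project(activity.data, factors, det, d)
    if not noiseless:
        rng = np.random.default_rng(seed)
        img = rng.poisson(img).astype(float)
    return PlanarImage(img, pixel_size_mm=d, provenance="conventional",
                       noiseless=noiseless)


def default_spect_angles(n: int = 60) -> np.ndarray:
    """N evenly spaced detector azimuths over 360 degrees, starting anterior."""
    if n < 2:
        raise ValueError("need at least 2 angles")
    return np.arange(n) * (360.0 / n)


class RotationProjector:
    """Attenuated parallel-beam system model over a fixed set of azimuths.

    Forward: rotate the activity into each detector frame (sparse bilinear
    operator), weight by the survival factors of the similarly rotated
    attenuation map, and collapse along y.  The adjoint applies the exact
    transposes in reverse order, so ``<P x, y> == <x, P^T y>`` holds to
    rounding error — the matched-pair property EM-type algorithms assume.
    """

    def __init__(self, mu: MuMap, angles_deg: np.ndarray,
                 det: DetectorModel | None = None):
        angles = np.asarray(angles_deg, dtype=float)
        if angles.size < 2:
            raise ValueError("need at least 2 angles")
        grid = mu.grid
        if grid.ny != grid.nx:
            raise ValueError("rotation projector requires square axial planes")
        self.grid = grid
        self.det = det or DetectorModel()
        self.angles_deg = angles
        d = grid.voxel_size_mm
        self._rot = [plane_rotation_matrix(grid.ny, grid.nx, -a) for a in angles]
        self._factors = []
        for mat in self._rot:
            mu_rot = self._apply(mat, mu.data)
            self._factors.append(anterior_attenuation_factors(mu_rot, d))

    def _apply(self, mat, vol: np.ndarray) -> np.ndarray:
        nz, ny, nx = vol.shape
        out = mat @ vol.reshape(nz, ny * nx).T
        return np.ascontiguousarray(out.T).reshape(nz, ny, nx)

    @property
    def n_angles(self) -> int:
        return len(self._rot)

    def forward(self, f: np.ndarray, angle_indices=None) -> np.ndarray:
        """Project (nz, ny, nx) -> (n_selected_angles, nz, nx)."""
        idx = list(range(self.n_angles)) if angle_indices is None else list(angle_indices)
        d = self.grid.voxel_size_mm
        out = np.empty((len(idx), self.grid.nz, self.grid.nx))
        for k, a in enumerate(idx):
            f_rot = self._apply(self._rot[a], f)
            out[k] = _slab_project(f_rot, self._factors[a], self.det, d)
        return out

    def adjoint(self, p: np.ndarray, angle_indices=None) -> np.ndarray:
        """Back-project (n_selected_angles, nz, nx) -> (nz, ny, nx)."""
        idx = list(range(self.n_angles)) if angle_indices is None else list(angle_indices)
        d = self.grid.voxel_size_mm
        out = np.zeros(self.grid.shape)
        for k, a in enumerate(idx):
            vol = _slab_backproject(p[k], self._factors[a], self.det, d)
            out += self._apply(self._rot[a].T, vol)
        return out


def simulate_spect(activity: ActivityVolume, mu: MuMap,
                   det: DetectorModel | None = None,
                   angles_deg: np.ndarray | None = None,
                   seed: int | None = None,
                   noiseless: bool = True) -> ProjectionSet:
    """Simulate a multi-angle SPECT acquisition (parallel-beam abstraction)."""
    if activity.grid != mu.grid:
        raise ValueError("activity and mu must share one grid")
    angles = default_spect_angles() if angles_deg is None else np.asarray(
        angles_deg, dtype=float)
    projector = RotationProjector(mu, angles, det)
    data = projector.forward(activity.data)
    if not noiseless:
        rng = np.random.default_rng(seed)
        data = rng.poisson(data).astype(float)
    return ProjectionSet(data, angles, pixel_size_mm=activity.grid.voxel_size_mm,
                         noiseless=noiseless)


def hu_to_mu(ct: CTVolume, energy_keV: float = 140.0,
             mu_water: float = MU_SOFT_TISSUE,
             k_bone: float = (MU_BONE - MU_SOFT_TISSUE) / 1000.0) -> MuMap:
    """Bilinear CT-number to attenuation conversion at the emission energy.

    HU <= 0: mu = mu_water * (1 + HU/1000) (air-water line); HU > 0:
    mu = mu_water + HU * k_bone, with ``k_bone`` defaulting so that
    HU = +1000 maps onto the package's bone surrogate.  Output clipped at 0.
    """
    if energy_keV <= 0:
        raise ValueError("energy must be positive")
    hu = ct.data
    mu = np.where(hu <= 0, mu_water * (1.0 + hu / 1000.0), mu_water + hu * k_bone)
    return MuMap(np.clip(mu, 0.0, None), ct.grid)
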