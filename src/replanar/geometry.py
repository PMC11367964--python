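"""Voxel-grid geometry and the basic volume / image containers.

Axis convention for all 3D arrays, indexed ``[z, y, x]``:

* axis 0 (z): caudal -> cranial,
* axis 1 (y): anterior -> posterior — index 0 is the anterior face, the
  direction a virtual anterior detector looks along,
* axis 2 (x): patient-right -> patient-left — index 0 is patient right.

Anterior planar images are 2D arrays indexed ``[z, x]`` so that the image
row axis is the cranio-caudal axis and the column axis runs from patient
right to patient left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "GridGeometry",
    "ActivityVolume",
    "MuMap",
    "PlanarImage",
    "ProjectionSet",
    "CTVolume",
]


@dataclass(frozen=True)
class GridGeometry:
    """Isotropic voxel grid: ``shape`` is (nz, ny, nx)."""

    shape: tuple[int, int, int]
    voxel_size_mm: float = 2.46

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError("shape must be (nz, ny, nx)")
        if any(int(n) < 8 for n in self.shape):
            raise ValueError(f"all grid dims must be >= 8, got {self.shape}")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def nz(self) -> int:
        return self.shape[0]

    @property
    def ny(self) -> int:
        return self.shape[1]

    @property
    def nx(self) -> int:
        return self.shape[2]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size (z, y, x) in mm."""
        return tuple(n * self.voxel_size_mm for n in self.shape)


def _check_grid(data: np.ndarray, grid: GridGeometry, name: str) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.shape != grid.shape:
        raise ValueError(f"{name} shape {data.shape} does not match grid {grid.shape}")
    return data


@dataclass
class ActivityVolume:
    """3D nonnegative emission map (arbitrary activity units per voxel)."""

    data: np.ndarray
    grid: GridGeometry
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _check_grid(self.data, self.grid, "activity")
        if np.any(self.data < 0):
            raise ValueError("activity must be nonnegative")

    def total_activity(self) -> float:
        return float(self.data.sum())


@dataclass
class MuMap:
    """3D linear-attenuation-coefficient map in 1/mm at the emission energy."""

    data: np.ndarray
    grid: GridGeometry

    def __post_init__(self) -> None:
        self.data = _check_grid(self.data, self.grid, "mu")
        if np.any(self.data < 0):
            raise ValueError("mu must be nonnegative")


@dataclass
class CTVolume:
    """3D CT-number volume (Hounsfield units)."""

    data: np.ndarray
    grid: GridGeometry

    def __post_init__(self) -> None:
        self.data = _check_grid(self.data, self.grid, "ct")
        if np.any(self.data < -1024):
            raise ValueError("HU values below -1024 are not valid")


@dataclass
class PlanarImage:
    """2D anterior-view count image.

    ``data`` is (nz_pix, nx_pix); real-valued for noiseless expectations,
    integer-valued after Poisson sampling.  ``provenance`` distinguishes a
    directly simulated conventional-camera image from a reprojected one.
    """

    data: np.ndarray
    pixel_size_mm: float
    view: str = "anterior"
    provenance: str = "conventional"
    noiseless: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("planar image must be 2D")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")
        if np.any(self.data < 0):
            raise ValueError("planar image counts must be nonnegative")
        if self.provenance not in ("conventional", "reprojected"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (self.data.shape[0] * self.pixel_size_mm,
                self.data.shape[1] * self.pixel_size_mm)


@dataclass
class ProjectionSet:
    """Multi-angle parallel-beam projections, ``data`` shaped (n_angles, nz, nx).

    Angle 0 coincides with the anterior view; angles are degrees of rotation
    of the detector normal in the axial plane, strictly increasing in
    [0, 360).
    """

    data: np.ndarray
    angles_deg: np.ndarray
    pixel_size_mm: float
    noiseless: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("projection data must be (n_angles, nz, nx)")
        if self.data.shape[0] != self.angles_deg.size:
            raise ValueError("number of projections does not match angle list")
        if self.angles_deg.size < 2:
            raise ValueError("at least 2 angles required")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles_deg[0] < 0 or self.angles_deg[-1] >= 360:
            raise ValueError("angles must lie in [0, 360)")

    @property
    def n_angles(self) -> int:
        return int(self.angles_deg.size)
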