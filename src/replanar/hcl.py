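"""Heart-to-contralateral (H/CL) ratio quantification.

A 7-cm circular region of interest is placed over the heart on the
anterior planar image; a contralateral ROI of the same size is mirrored
across the mid-sagittal line into the right thorax.  The ratio of mean
counts per pixel, H/CL = heart mean / contralateral mean, supports an
ATTR-positive read when >= 1.5 (boundary inclusive).

All geometry is metric (mm): pixel (i, j) has its centre at
((i + 0.5) * pixel_size, (j + 0.5) * pixel_size), and a pixel belongs to an
ROI when its centre lies inside the circle (no partial-area weighting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate

from .geometry import PlanarImage

__all__ = ["RoiSpec", "HclResult", "auto_place_heart_roi", "mirror_roi",
           "compute_hcl", "hcl_from_image"]

logger = logging.getLogger(__name__)

HCL_CUTOFF = 1.5
DEFAULT_ROI_DIAMETER_MM = 70.0


@dataclass(frozen=True)
class RoiSpec:
    """Circular ROI in image metric coordinates (z down the rows, x across
    the columns, mm)."""

    center_z_mm: float
    center_x_mm: float
    diameter_mm: float = DEFAULT_ROI_DIAMETER_MM
    side: str = "heart"
    adjusted: bool = False

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError("diameter must be positive")
        if self.side not in ("heart", "contralateral"):
            raise ValueError(f"unknown ROI side {self.side!r}")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class HclResult:
    heart_mean: float
    cl_mean: float
    ratio: float
    positive: bool
    n_pixels_heart: int
    n_pixels_cl: int


def _check_inside(roi: RoiSpec, img: PlanarImage) -> None:
    ez, ex = img.extent_mm
    r = roi.radius_mm
    if (roi.center_z_mm - r < 0 or roi.center_z_mm + r > ez
            or roi.center_x_mm - r < 0 or roi.center_x_mm + r > ex):
        raise ValueError(
            f"{roi.side} ROI (centre ({roi.center_z_mm:.1f}, {roi.center_x_mm:.1f}) mm,"
            f" diameter {roi.diameter_mm} mm) exits the {ez:.0f}x{ex:.0f} mm image")


def _roi_mask(roi: RoiSpec, img: PlanarImage) -> np.ndarray:
    nz, nx = img.data.shape
    p = img.pixel_size_mm
    zc = (np.arange(nz) + 0.5) * p
    xc = (np.arange(nx) + 0.5) * p
    zz, xx = np.meshgrid(zc, xc, indexing="ij")
    return ((zz - roi.center_z_mm) ** 2 + (xx - roi.center_x_mm) ** 2
            <= roi.radius_mm ** 2)


def auto_place_heart_roi(img: PlanarImage,
                         diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
                         search: str = "patient-left") -> RoiSpec:
    """Place the heart ROI at the disc centre maximizing mean counts.

    Candidate centres are pixel centres in the patient-left half of the
    thorax (or the whole image with ``search="full"``) for which the disc
    lies fully inside the image.  Ties break toward the smallest z, then
    the smallest x, so placement is deterministic.
    """
    nz, nx = img.data.shape
    p = img.pixel_size_mm
    r = diameter_mm / 2.0
    ez, ex = img.extent_mm
    if 2 * r > ez or 2 * r > ex:
        raise ValueError(
            f"image ({ez:.0f}x{ex:.0f} mm) cannot contain a {diameter_mm}-mm ROI")

    # disc membership depends only on integer pixel offsets, so one kernel
    # correlation yields the ROI mean around every candidate centre
    max_off = int(np.floor(r / p))
    off = np.arange(-max_off, max_off + 1)
    dz, dx = np.meshgrid(off, off, indexing="ij")
    kernel = ((dz * p) ** 2 + (dx * p) ** 2 <= r ** 2).astype(float)
    mean_map = correlate(img.data, kernel / kernel.sum(), mode="constant")

    zc = (np.arange(nz) + 0.5) * p
    xc = (np.arange(nx) + 0.5) * p
    feasible = ((zc[:, None] - r >= 0) & (zc[:, None] + r <= ez)
                & (xc[None, :] - r >= 0) & (xc[None, :] + r <= ex))
    if search == "patient-left":
        feasible &= xc[None, :] >= ex / 2.0
    elif search != "full":
        raise ValueError(f"unknown search region {search!r}")
    if not feasible.any():
        raise ValueError("no feasible ROI centre in the search region")

    scores = np.where(feasible, mean_map, -np.inf)
    best = np.argwhere(scores == scores.max())[0]  # argwhere is row-major: min z, then min x
    return RoiSpec(center_z_mm=float(zc[best[0]]), center_x_mm=float(xc[best[1]]),
                   diameter_mm=diameter_mm, side="heart")


def mirror_roi(heart: RoiSpec, img: PlanarImage,
               midline_x_mm: float | None = None) -> RoiSpec:
    """Mirror the heart ROI across the mid-sagittal line.

    The midline defaults to the image centre; ``midline_x_mm`` accommodates
    a patient positioned off-centre.  If the mirrored disc would exit the
    image it is shifted minimally inward along x (logged), reflecting the
    manual adjustment of the contralateral region to an equivalent area.
    """
    _check_inside(heart, img)
    _, ex = img.extent_mm
    mid = ex / 2.0 if midline_x_mm is None else midline_x_mm
    cx = 2.0 * mid - heart.center_x_mm
    adjusted = False
    r = heart.radius_mm
    if cx - r < 0:
        cx, adjusted = r, True
    elif cx + r > ex:
        cx, adjusted = ex - r, True
    if adjusted:
        logger.info("contralateral ROI shifted inward to x=%.1f mm", cx)
    if abs(cx - heart.center_x_mm) < img.pixel_size_mm / 2:
        logger.warning("heart ROI sits on the midline; contralateral ROI overlaps it")
    return RoiSpec(center_z_mm=heart.center_z_mm, center_x_mm=cx,
                   diameter_mm=heart.diameter_mm, side="contralateral",
                   adjusted=adjusted)


def compute_hcl(img: PlanarImage, heart: RoiSpec, cl: RoiSpec) -> HclResult:
    """Mean counts/pixel in each ROI and their ratio with the >=1.5 rule."""
    _check_inside(heart, img)
    _check_inside(cl, img)
    hm = _roi_mask(heart, img)
    cm = _roi_mask(cl, img)
    heart_mean = float(img.data[hm].mean())
    cl_mean = float(img.data[cm].mean())
    if cl_mean == 0:
        raise ZeroDivisionError(
            "contralateral ROI mean is zero: H/CL ratio undefined")
    ratio = heart_mean / cl_mean
    return HclResult(heart_mean=heart_mean, cl_mean=cl_mean, ratio=ratio,
                     positive=bool(ratio >= HCL_CUTOFF),
                     n_pixels_heart=int(hm.sum()), n_pixels_cl=int(cm.sum()))


def hcl_from_image(img: PlanarImage,
                   center: tuple[float, float] | None = None,
                   diameter_mm: float = DEFAULT_ROI_DIAMETER_MM) -> HclResult:
    """Full H/CL workflow: place (or accept) the heart ROI, mirror it,
    compute the ratio.  ``center`` = (z_mm, x_mm) overrides automatic
    placement, mirroring the manual clinical workflow."""
    if center is None:
        heart = auto_place_heart_roi(img, diameter_mm)
    else:
        heart = RoiSpec(center_z_mm=center[0], center_x_mm=center[1],
                        diameter_mm=diameter_mm, side="heart")
    cl = mirror_roi(heart, img)
    return compute_hcl(img, heart, cl)
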