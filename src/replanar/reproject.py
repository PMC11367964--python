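"""Virtual anterior planar images from reconstructed SPECT volumes.

A ring-detector SPECT-only system cannot acquire planar scintigraphy.  The
replacement is a *reprojected* planar image: every voxel of the
reconstructed activity volume is weighted by the survival factor obtained
by integrating the attenuation coefficients from that voxel to the edge of
the object along the anterior line of projection, and the weighted volume
is collapsed into a 2D matrix.  With a perfect reconstruction and matched
conventions this operator reproduces the noiseless conventional planar
image exactly — the identity the test suite verifies.
"""

from __future__ import annotations

import numpy as np

from .geometry import ActivityVolume, MuMap, PlanarImage
from .phantom import PhantomSpec, make_phantom
from .projectors import (DetectorModel, anterior_attenuation_factors,
                         default_spect_angles, simulate_planar, simulate_spect)
from .recon import reconstruct_for_study

__all__ = ["reproject_planar", "paired_study_images"]


def reproject_planar(recon: ActivityVolume, mu: MuMap, view: str = "anterior",
                     scale: float = 1.0) -> PlanarImage:
    """Attenuation-weighted forward projection of a reconstructed volume.

    Pixel (z, x) = scale * step * sum_y recon(z, y, x) * exp(-line integral
    of mu from the voxel to the anterior grid face).  The output pixel grid
    equals the reconstruction grid (no resampling); no PSF is applied —
    resolution handling lives in the reconstruction.
    """
    if recon.grid != mu.grid:
        raise ValueError("reconstruction and mu must share one grid")
    if np.any(recon.data < 0):
        raise ValueError("reconstructed activity must be nonnegative")
    if view != "anterior":
        raise ValueError("only the anterior view is supported")
    d = recon.grid.voxel_size_mm
    factors = anterior_attenuation_factors(mu.data, d)
    img = scale * d * (recon.data * factors).sum(axis=1)
    return PlanarImage(img, pixel_size_mm=d, provenance="reprojected",
                       noiseless=True)


def paired_study_images(activity: ActivityVolume, mu: MuMap,
                        det: DetectorModel | None = None,
                        seed: int = 0,
                        noiseless: bool = False,
                        n_angles: int = 60,
                        recon_iterations: int = 20,
                        recon_subsets: int = 6,
                        perfect_reconstruction: bool = False
                        ) -> tuple[PlanarImage, PlanarImage]:
    """Both acquisition pathways for one phantom.

    Conventional: direct anterior planar simulation of the true activity.
    Reprojected: SPECT acquisition -> study reconstruction (BSREM + RDP)
    -> attenuation-weighted reprojection.  ``perfect_reconstruction``
    bypasses the reconstruction with the true activity (end-to-end
    consistency oracle).  Seeds for the two acquisitions are derived
    deterministically from ``seed``.
    """
    det = det or DetectorModel()
    seed_planar, seed_spect = (int(s) for s in
                               np.random.SeedSequence(seed).generate_state(2) % (2 ** 31))
    conventional = simulate_planar(activity, mu, det, seed=seed_planar,
                                   noiseless=noiseless)
    if perfect_reconstruction:
        recon = activity
    else:
        angles = default_spect_angles(n_angles)
        proj = simulate_spect(activity, mu, det, angles, seed=seed_spect,
                              noiseless=noiseless)
        recon = reconstruct_for_study(proj, mu, det,
                                      n_iterations=recon_iterations,
                                      n_subsets=recon_subsets)
    reprojected = reproject_planar(recon, mu)
    return conventional, reprojected


def demo_pair(seed: int = 0, **kwargs):
    """Convenience: default phantom -> paired images (used by examples)."""
    activity, mu, truth = make_phantom(PhantomSpec(), seed=seed)
    conv, repro = paired_study_images(activity, mu, seed=seed, **kwargs)
    return conv, repro, truth
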