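"""NIfTI / CSV / JSON plumbing for volumes, planar images and tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import ActivityVolume, GridGeometry, MuMap, PlanarImage
from .phantom import PhantomTruth

__all__ = [
    "save_volume", "load_volume", "save_mu", "load_mu",
    "save_planar", "load_planar", "truths_to_frame", "save_truths",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_volume(vol: ActivityVolume | MuMap, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32),
                          _affine(vol.grid.voxel_size_mm))
    img.header.set_zooms((vol.grid.voxel_size_mm,) * 3)
    nib.save(img, str(path))
    return path


def _load_grid(img) -> tuple[np.ndarray, GridGeometry]:
    data = np.asarray(img.dataobj, dtype=float)
    zoom = float(img.header.get_zooms()[0])
    return data, GridGeometry(tuple(data.shape), voxel_size_mm=zoom)


def load_volume(path) -> ActivityVolume:
    data, grid = _load_grid(nib.load(str(path)))
    return ActivityVolume(data, grid)


def save_mu(mu: MuMap, path) -> Path:
    return save_volume(mu, path)


def load_mu(path) -> MuMap:
    data, grid = _load_grid(nib.load(str(path)))
    return MuMap(data, grid)


def save_planar(img: PlanarImage, path) -> Path:
    """2D NIfTI with provenance in the header description + sidecar JSON."""
    path = Path(path)
    nii = nib.Nifti1Image(np.asarray(img.data, dtype=np.float32),
                          np.diag([img.pixel_size_mm, img.pixel_size_mm, 1.0, 1.0]))
    nii.header["descrip"] = f"{img.view};{img.provenance}".encode()
    nib.save(nii, str(path))
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") \
        else path.with_suffix("")
    meta = {"view": img.view, "provenance": img.provenance,
            "pixel_size_mm": img.pixel_size_mm, "noiseless": img.noiseless}
    Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=1))
    return path


def load_planar(path) -> PlanarImage:
    path = Path(path)
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj, dtype=float)
    pix = float(nii.header.get_zooms()[0])
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") \
        else path.with_suffix("")
    meta_path = Path(str(sidecar) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return PlanarImage(data, pixel_size_mm=meta.get("pixel_size_mm", pix),
                       view=meta.get("view", "anterior"),
                       provenance=meta.get("provenance", "conventional"),
                       noiseless=meta.get("noiseless", True))


def truths_to_frame(truths: list[PhantomTruth]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": t.subject_id,
        "perugini_class_truth": t.perugini_class_truth,
        "myo_to_rib_ratio": t.myo_to_rib_ratio,
        "heart_z_mm": t.heart_center_mm[0],
        "heart_y_mm": t.heart_center_mm[1],
        "heart_x_mm": t.heart_center_mm[2],
        "total_activity": t.total_activity,
        "seed": t.seed,
    } for t in truths])


def save_truths(truths: list[PhantomTruth], path) -> Path:
    path = Path(path)
    truths_to_frame(truths).to_csv(path, index=False)
    return path
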