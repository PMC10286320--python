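"""NIfTI and manifest I/O.

Arrays are held in (z, y, x) order internally; NIfTI files store (x, y, z),
so axes are transposed on the way in and out and the voxel spacing is taken
from (or written to) the header zooms.  Masks must be co-registered with
their images; no resampling is performed.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import CTVolume, DEFAULT_THRESHOLDS, NoduleMask, threshold_column
from .volumetry import measure_nodule

__all__ = ["save_nifti_pair", "load_nifti_pair", "quantify_manifest"]


def save_nifti_pair(volume: CTVolume, mask: NoduleMask, image_path, mask_path) -> None:
    """Write an image/mask pair as .nii or .nii.gz with spacing in the header."""
    dz, dy, dx = volume.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(volume.values.transpose(2, 1, 0).astype(np.float32), affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(image_path))
    m = nib.Nifti1Image(mask.values.transpose(2, 1, 0).astype(np.uint8), affine)
    m.header.set_zooms((dx, dy, dz))
    nib.save(m, str(mask_path))


def load_nifti_pair(image_path, mask_path) -> tuple[CTVolume, NoduleMask]:
    """Read an image/mask pair; returns (z, y, x)-ordered arrays."""
    img = nib.load(str(image_path))
    dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
    values = np.asarray(img.dataobj, dtype=float).transpose(2, 1, 0)
    volume = CTVolume(values, (dz, dy, dx))
    mask_img = nib.load(str(mask_path))
    mask = NoduleMask(np.asarray(mask_img.dataobj) > 0.5)
    if mask.values.ndim != 3:
        raise ValueError("mask NIfTI must be 3D")
    mask = NoduleMask(mask.values.transpose(2, 1, 0))
    return volume, mask


def quantify_manifest(
    manifest,
    thresholds=DEFAULT_THRESHOLDS,
    solid_display_threshold: float = -160.0,
) -> pd.DataFrame:
    """Run volumetry over a CSV manifest (nodule_id, image, mask columns).

    Returns one row per nodule with volume, mean attenuation, diameter, CTR
    and one ``ctrv_*`` column per threshold.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    required = {"nodule_id", "image", "mask"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    missing = [
        p for p in (*manifest["image"], *manifest["mask"]) if not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError("missing input files: " + ", ".join(map(str, missing)))
    rows = []
    for rec in manifest.itertuples(index=False):
        volume, mask = load_nifti_pair(rec.image, rec.mask)
        res = measure_nodule(volume, mask, thresholds, solid_display_threshold)
        row = {
            "nodule_id": rec.nodule_id,
            "volume_mm3": res.volume_mm3,
            "mean_attenuation_hu": res.mean_attenuation_hu,
            "diameter_mm": res.diameter_mm,
            "ctr_percent": res.ctr_percent,
        }
        for t, v in res.ctrv_percent.items():
            row[threshold_column(t)] = v
        rows.append(row)
    return pd.DataFrame(rows)
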