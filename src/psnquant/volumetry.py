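"""3D and 2D quantification of the solid component of part-solid nodules.

The central quantity is the consolidation/tumor ratio of volume (CTRV): the
fraction of nodule voxels whose attenuation lies at or above a threshold,
expressed in percent.  A sweep over thresholds from -400 to 50 HU (step
50 HU) profiles how the apparent solid volume shrinks as the threshold
rises; within a nodule the sweep is non-increasing by construction.

"Beyond a threshold" is interpreted inclusively (HU >= threshold); the
``inclusive`` flag switches to a strict comparison for sensitivity checks.
Voxels are counted by their centers with no partial-volume weighting,
matching plain voxel-count volumetry.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from scipy.stats import norm

from .types import AttenuationMixture, CTVolume, DEFAULT_THRESHOLDS, NoduleMask

__all__ = [
    "nodule_volume",
    "mean_attenuation",
    "ctrv",
    "ctrv_sweep",
    "ctrv_from_mixture",
    "max_axial_diameter",
    "ctr_2d",
    "measure_nodule",
]


def _check_mask(mask: NoduleMask) -> np.ndarray:
    m = mask.values
    if not m.any():
        raise ValueError("mask is empty: no voxels are segmented")
    return m


def nodule_volume(mask: NoduleMask, spacing: tuple[float, float, float]) -> float:
    """Nodule volume in mm^3: voxel count times voxel volume."""
    m = _check_mask(mask)
    return float(m.sum()) * float(np.prod(spacing))


def mean_attenuation(volume: CTVolume, mask: NoduleMask) -> float:
    """Arithmetic mean of in-mask attenuation, in HU."""
    m = _check_mask(mask)
    _check_aligned(volume, mask)
    return float(volume.values[m].mean())


def _check_aligned(volume: CTVolume, mask: NoduleMask) -> None:
    if volume.values.shape != mask.values.shape:
        raise ValueError(
            f"mask shape {mask.values.shape} does not match volume shape "
            f"{volume.values.shape}; masks must be co-registered"
        )


def ctrv(
    volume: CTVolume,
    mask: NoduleMask,
    threshold: float,
    inclusive: bool = True,
) -> float:
    """CTRV at one attenuation threshold, in percent.

    100 x (# in-mask voxels with HU >= threshold) / (# in-mask voxels).
    """
    m = _check_mask(mask)
    _check_aligned(volume, mask)
    hu = volume.values[m]
    solid = (hu >= threshold) if inclusive else (hu > threshold)
    return 100.0 * float(solid.sum()) / hu.size


def ctrv_sweep(
    volume: CTVolume,
    mask: NoduleMask,
    thresholds=DEFAULT_THRESHOLDS,
    inclusive: bool = True,
) -> dict[float, float]:
    """CTRV at every threshold of a strictly increasing grid.

    The resulting sequence is non-increasing in the threshold (the solid sets
    are nested), which downstream code may rely on.
    """
    thresholds = [float(t) for t in thresholds]
    if not thresholds:
        raise ValueError("threshold grid is empty")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    return {t: ctrv(volume, mask, t, inclusive=inclusive) for t in thresholds}


def ctrv_from_mixture(mixture: AttenuationMixture, threshold) -> float | np.ndarray:
    """Closed-form CTRV (percent) implied by a two-Gaussian attenuation model.

    The population fraction of voxels at or above ``threshold`` is the
    mixture survival function
    ``(1 - f) * S_ggo(threshold) + f * S_solid(threshold)``
    with S the Gaussian survival function.  Accepts a scalar or an array of
    thresholds.
    """
    t = np.asarray(threshold, dtype=float)
    s_ggo = norm.sf((t - mixture.mu_ggo) / mixture.sigma_ggo)
    s_solid = norm.sf((t - mixture.mu_solid) / mixture.sigma_solid)
    out = 100.0 * ((1.0 - mixture.f) * s_ggo + mixture.f * s_solid)
    return float(out) if out.ndim == 0 else out


def _slice_feret(points_mm: np.ndarray) -> float:
    """Max pairwise distance between in-plane voxel centers (mm)."""
    if len(points_mm) < 2:
        return 0.0
    if len(points_mm) > 16:
        # Feret diameter is attained on the convex hull; Qhull rejects
        # degenerate (collinear) inputs, for which brute force is cheap.
        try:
            points_mm = points_mm[ConvexHull(points_mm).vertices]
        except QhullError:
            pass
    return float(pdist(points_mm).max())


def max_axial_diameter(mask: NoduleMask, spacing: tuple[float, float, float]) -> float:
    """Maximal axial diameter in mm.

    The maximum over axial (z) slices of the in-plane Feret diameter of the
    mask, measured between voxel centers.  A single-voxel mask yields 0 mm
    and a warning.
    """
    m = _check_mask(mask)
    if m.sum() == 1:
        warnings.warn("single-voxel mask: axial diameter is degenerate (0 mm)")
        return 0.0
    dy, dx = float(spacing[1]), float(spacing[2])
    best = 0.0
    for z in np.flatnonzero(m.any(axis=(1, 2))):
        yy, xx = np.nonzero(m[z])
        pts = np.column_stack([yy * dy, xx * dx])
        best = max(best, _slice_feret(pts))
    return best


def ctr_2d(
    volume: CTVolume,
    mask: NoduleMask,
    spacing: tuple[float, float, float],
    solid_display_threshold: float = -160.0,
) -> float:
    """Consolidation-to-tumor ratio (percent) from emulated 2D reading.

    Ratio of the maximal axial Feret diameter of the displayed solid
    component (HU >= ``solid_display_threshold``, a soft-tissue-window
    visibility proxy) to the maximal axial Feret diameter of the whole
    nodule.  Returns 0 when no voxel passes the display threshold.
    """
    m = _check_mask(mask)
    _check_aligned(volume, mask)
    nodule_d = max_axial_diameter(mask, spacing)
    if nodule_d == 0.0:
        return 0.0
    solid = m & (volume.values >= solid_display_threshold)
    if not solid.any():
        return 0.0
    solid_d = max_axial_diameter(NoduleMask(solid), spacing)
    return 100.0 * solid_d / nodule_d


def measure_nodule(
    volume: CTVolume,
    mask: NoduleMask,
    thresholds=DEFAULT_THRESHOLDS,
    solid_display_threshold: float = -160.0,
):
    """All 2D/3D measures of one segmented nodule in a single pass."""
    from .types import VolumetryResult

    spacing = volume.spacing
    return VolumetryResult(
        volume_mm3=nodule_volume(mask, spacing),
        mean_attenuation_hu=mean_attenuation(volume, mask),
        ctrv_percent=ctrv_sweep(volume, mask, thresholds),
        diameter_mm=max_axial_diameter(mask, spacing),
        ctr_percent=ctr_2d(volume, mask, spacing, solid_display_threshold),
    )
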