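"""Core containers shared across the package.

Conventions
-----------
* Image grids are indexed ``(z, y, x)``; ``spacing`` gives the voxel edge
  lengths in millimetres in the same order.
* Attenuation is in Hounsfield units (HU) throughout.
* Histologic grade is coded ordinally: 0 = MIA, 1 = Grade 1 IPA,
  2 = Grade 2 IPA, 3 = Grade 3 IPA.  The binary outcome used by the risk
  models groups MIA/Grade 1 as *low risk* and Grade 2/3 as *high risk*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GRADE_NAMES = {0: "MIA", 1: "IPA grade 1", 2: "IPA grade 2", 3: "IPA grade 3"}

#: Attenuation thresholds (HU) scanned when profiling the solid component:
#: -400 to 50 HU in steps of 50 HU.
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(float(t) for t in range(-400, 51, 50))


def is_high_risk(grade) -> np.ndarray | bool:
    """Binary risk class from ordinal grade: high risk iff grade >= 2."""
    return np.asarray(grade) >= 2


def threshold_column(threshold: float) -> str:
    """CSV column name for a CTRV threshold, e.g. -250 -> ``ctrv_m250``."""
    t = int(round(threshold))
    return f"ctrv_m{-t}" if t < 0 else f"ctrv_p{t}"


@dataclass(frozen=True)
class AttenuationMixture:
    """Two-component Gaussian attenuation model of a part-solid nodule.

    The in-nodule HU histogram is modelled as a mixture of a ground-glass
    component and a denser solid component; ``f`` is the volume fraction of
    the solid component.
    """

    f: float
    mu_ggo: float
    sigma_ggo: float
    mu_solid: float
    sigma_solid: float

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"solid fraction f={self.f} outside [0, 1]")
        if self.sigma_ggo <= 0 or self.sigma_solid <= 0:
            raise ValueError("mixture component SDs must be positive")
        if self.mu_solid <= self.mu_ggo:
            raise ValueError("solid component mean must exceed ground-glass mean")


@dataclass
class CTVolume:
    """A 3D attenuation grid (HU) with voxel spacing in mm, (z, y, x) order."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("CTVolume expects a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on every axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CTVolume contains non-finite values")


@dataclass
class NoduleMask:
    """Binary segmentation aligned voxel-for-voxel with a CTVolume."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("NoduleMask expects a 3D array")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class VolumetryResult:
    """All 2D/3D measures extracted from one nodule."""

    volume_mm3: float
    mean_attenuation_hu: float
    ctrv_percent: dict[float, float] = field(default_factory=dict)
    diameter_mm: float = float("nan")
    ctr_percent: float = float("nan")
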