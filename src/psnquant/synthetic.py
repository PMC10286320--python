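"""Synthetic cohorts of part-solid nodules with grade-linked structure.

Every downstream stage (threshold sweep, risk models, evaluation) is
exercised on cohorts produced here, so the generator encodes the study
conditions explicitly:

* fixed per-grade counts (default 15/62/151/11 for the training cohort,
  9/19/52/7 for the testing cohort);
* per-grade truncated-normal continuous measures (maximal diameter, CTR,
  volume, mean attenuation), sampled by rejection so physical bounds hold
  while the nominal mean/SD are approximately preserved;
* per-grade Bernoulli semantic features at the empirical frequencies of the
  reference cohort;
* a per-nodule two-component Gaussian attenuation mixture from which CTRV
  at *all* thresholds derives in closed form, guaranteeing within-nodule
  monotonicity of the threshold sweep.

The mixture law is the generative heart.  Each nodule draws a solid
fraction ``f`` from a per-grade Beta distribution, a ground-glass component
mean around -600 HU, and a solid component mean whose per-grade location
rises with grade (denser consolidation in higher grades).  The Beta
parameters were calibrated once, via the closed-form mixture survival
function, so that per-grade CTRV at -250 HU has mean
(3.4, 7.5, 26.5, 40.6)% and SD (2.9, 7.6, 16.7, 9.7)%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats as sps

from .types import AttenuationMixture, CTVolume, DEFAULT_THRESHOLDS, NoduleMask, threshold_column
from .volumetry import ctrv_from_mixture

__all__ = [
    "SEMANTIC_FEATURES",
    "GradeParams",
    "CohortSpec",
    "NoduleTruth",
    "default_training_spec",
    "default_testing_spec",
    "sample_cohort",
    "truth_from_record",
    "render_nodule_image",
    "duplicate_observer_measures",
    "split_cohorts",
]

#: The eight binary semantic features read by radiologists.
SEMANTIC_FEATURES = (
    "shape_irregular",
    "margin_coarse",
    "lobulation",
    "spiculation",
    "pleural_indentation",
    "air_bronchogram",
    "vacuole",
    "vessel_convergence",
)

#: Physical ranges used to truncate continuous measures.
MEASURE_RANGES = {
    "diameter_mm": (1e-6, math.inf),
    "ctr_percent": (0.0, 100.0),
    "volume_mm3": (1e-6, math.inf),
    "mean_attenuation_hu": (-1000.0, 100.0),
}

# Per-grade defaults for the four continuous measures: (mean, SD) for
# grades 0..3 (MIA, IPA grade 1, 2, 3).
_MEASURE_DEFAULTS = {
    "diameter_mm": ((10.1, 2.5), (17.6, 6.4), (20.5, 7.0), (24.0, 6.6)),
    "ctr_percent": ((38.6, 10.6), (38.9, 13.1), (53.4, 15.8), (64.1, 14.1)),
    "volume_mm3": ((363.8, 266.0), (2051.1, 2019.0), (2770.3, 2305.2), (3526.0, 2096.0)),
    "mean_attenuation_hu": ((-598.3, 70.1), (-578.5, 90.3), (-426.0, 118.5), (-331.4, 55.0)),
}

# Per-grade Bernoulli rates of the semantic features (empirical frequencies
# of the reference training cohort, n = 15/62/151/11 per grade).
_SEMANTIC_DEFAULTS = {
    "shape_irregular": (15 / 15, 60 / 62, 147 / 151, 11 / 11),
    "margin_coarse": (15 / 15, 61 / 62, 149 / 151, 11 / 11),
    "lobulation": (14 / 15, 24 / 62, 134 / 151, 11 / 11),
    "spiculation": (0 / 15, 0 / 62, 2 / 151, 1 / 11),
    "pleural_indentation": (1 / 15, 29 / 62, 102 / 151, 10 / 11),
    "air_bronchogram": (0 / 15, 14 / 62, 80 / 151, 6 / 11),
    # vacuole uses the pooled prevalence for every grade: its weak grade
    # association is noise-level in cohorts of this size, and an
    # uninformative rate keeps the univariable screen's selection pattern
    # stable (vacuole is not a risk predictor here)
    "vacuole": (19 / 239, 19 / 239, 19 / 239, 19 / 239),
    "vessel_convergence": (0 / 15, 18 / 62, 78 / 151, 5 / 11),
}

# Mixture defaults.  Solid-fraction Beta moments were calibrated once so the
# closed-form CTRV at -250 HU reproduces the per-grade target mean/SD after
# accounting for ground-glass tail leakage; component-mean jitters emulate
# between-nodule attenuation heterogeneity.
_F_BETA_MEAN = (0.0499, 0.0907, 0.3037, 0.4463)
_F_BETA_SD = (0.0403, 0.0920, 0.1825, 0.0855)
# The testing cohort came from a different scanner and separated less
# cleanly: its low-risk group had higher CTRV (8.7 +/- 9.4%) than the
# training low-risk group.  Its solid-fraction moments are therefore
# calibrated separately, to per-grade CTRV targets whose risk-group
# mixtures (9+19 low, 52+7 high) reproduce the testing-cohort group
# means/SDs (8.7 +/- 9.4 and 27.6 +/- 17.3%).
_F_BETA_MEAN_TEST = (0.0738, 0.1304, 0.2967, 0.4363)
_F_BETA_SD_TEST = (0.0559, 0.1294, 0.1941, 0.0840)
_MU_SOLID = (-230.0, -180.0, -150.0, -130.0)
_MU_GGO, _MU_GGO_JITTER, _SIGMA_GGO = -600.0, 40.0, 130.0
_MU_SOLID_JITTER, _SIGMA_SOLID = 60.0, 70.0

# Within-grade dependence structure.  A per-nodule "solid burden" latent
# drives the solid fraction and, through a Gaussian copula, the nodule
# volume; mean attenuation derives from the attenuation mixture itself.  A
# separate "morphology" latent is shared by the semantic features so they
# co-occur, as they do in readings of real nodules.  Without these
# couplings every measure would carry independent information about risk,
# which real cohorts do not exhibit.
_RHO_VOLUME = 0.3
#: Loadings of each semantic feature on the shared morphology latent.
#: Vessel convergence loads strongly: it co-occurs with the other
#: invasiveness signs and is therefore largely redundant once they are in a
#: model, which is what drives its elimination during backward selection.
_SEMANTIC_LOADINGS = {
    "lobulation": 0.40,
    "pleural_indentation": 0.40,
    "air_bronchogram": 0.40,
    "vessel_convergence": 0.92,
}
_DEFAULT_LOADING = 0.30


@dataclass(frozen=True)
class GradeParams:
    """All generative parameters for one histologic grade."""

    measures: dict[str, tuple[float, float]]  # measure -> (mean, SD)
    semantic_probs: dict[str, float]
    f_beta_mean: float
    f_beta_sd: float
    mu_solid: float

    def validate(self) -> None:
        for name, (mu, sd) in self.measures.items():
            if sd < 0:
                raise ValueError(f"{name}: negative SD {sd}")
        for name, p in self.semantic_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}: probability {p} outside [0, 1]")
        if not 0.0 < self.f_beta_mean < 1.0:
            raise ValueError("solid-fraction Beta mean must lie strictly in (0, 1)")
        if self.f_beta_sd < 0:
            raise ValueError("solid-fraction Beta SD must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic cohort."""

    n_per_grade: tuple[int, int, int, int]
    grades: tuple[GradeParams, GradeParams, GradeParams, GradeParams]
    mu_ggo: float = _MU_GGO
    mu_ggo_jitter: float = _MU_GGO_JITTER
    sigma_ggo: float = _SIGMA_GGO
    mu_solid_jitter: float = _MU_SOLID_JITTER
    sigma_solid: float = _SIGMA_SOLID
    rho_volume: float = _RHO_VOLUME
    semantic_loadings: dict[str, float] = field(
        default_factory=lambda: dict(_SEMANTIC_LOADINGS)
    )
    observer_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"diameter_mm": 2.2, "ctr_percent": 5.7}
    )
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_grade):
            raise ValueError("per-grade counts must be nonnegative")
        for g in self.grades:
            g.validate()
        if any(sd < 0 for sd in self.observer_noise_sd.values()):
            raise ValueError("observer noise SDs must be nonnegative")
        if self.mu_ggo_jitter < 0 or self.mu_solid_jitter < 0:
            raise ValueError("component-mean jitters must be nonnegative")
        if self.sigma_ggo <= 0 or self.sigma_solid <= 0:
            raise ValueError("component SDs must be positive")
        loadings = [self.rho_volume, *self.semantic_loadings.values()]
        if any(not abs(l) < 1 for l in loadings):
            raise ValueError("latent loadings must lie in (-1, 1)")


@dataclass(frozen=True)
class NoduleTruth:
    """Ground truth for rendering one nodule as a voxel image."""

    nodule_id: str
    grade: int
    mixture: AttenuationMixture
    semantic: dict[str, bool]
    diameter_mm: float
    volume_mm3: float

    def __post_init__(self):
        if self.diameter_mm <= 0 or self.volume_mm3 <= 0:
            raise ValueError("diameter and volume must be positive")


def _grade_params(grade: int) -> GradeParams:
    return GradeParams(
        measures={m: _MEASURE_DEFAULTS[m][grade] for m in _MEASURE_DEFAULTS},
        semantic_probs={s: _SEMANTIC_DEFAULTS[s][grade] for s in SEMANTIC_FEATURES},
        f_beta_mean=_F_BETA_MEAN[grade],
        f_beta_sd=_F_BETA_SD[grade],
        mu_solid=_MU_SOLID[grade],
    )


def default_training_spec() -> CohortSpec:
    """Training-cohort conditions: 239 nodules, 15/62/151/11 per grade."""
    return CohortSpec(n_per_grade=(15, 62, 151, 11), grades=tuple(_grade_params(g) for g in range(4)))


def default_testing_spec() -> CohortSpec:
    """Testing-cohort conditions: 87 nodules, 9/19/52/7 per grade.

    Continuous measures and semantic rates are shared with the training
    conditions; the solid-fraction distribution is cohort-specific (the
    testing scanner's risk groups overlap more), so CTRV discrimination is
    weaker here, as it is in the reference cohorts.
    """
    grades = tuple(
        replace(_grade_params(g), f_beta_mean=_F_BETA_MEAN_TEST[g], f_beta_sd=_F_BETA_SD_TEST[g])
        for g in range(4)
    )
    return CohortSpec(n_per_grade=(9, 19, 52, 7), grades=grades)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection sampling from N(mean, sd) restricted to [lo, hi]."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0:
        return math.inf, math.inf  # degenerate: handled by caller
    nu = mean * (1 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError(f"Beta SD {sd} too large for mean {mean}")
    return mean * nu, (1 - mean) * nu


def _truncnorm_from_quantile(q, mean, sd, lo, hi):
    """Quantile transform onto a truncated normal (degenerate sd = 0 ok)."""
    if sd == 0:
        return np.full(np.shape(q), float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.ppf(q, a, b, loc=mean, scale=sd)


def _mixture_mean_moments(spec: CohortSpec, gp: GradeParams) -> tuple[float, float]:
    """Mean and variance of the per-nodule mixture mean attenuation."""
    m, s = gp.f_beta_mean, gp.f_beta_sd
    e_f2 = s**2 + m**2
    e_1mf2 = s**2 + (1 - m) ** 2
    d = gp.mu_solid - spec.mu_ggo
    mean = spec.mu_ggo + m * d
    var = d**2 * s**2 + e_1mf2 * spec.mu_ggo_jitter**2 + e_f2 * spec.mu_solid_jitter**2
    return mean, var


def _attenuation_affine(spec: CohortSpec) -> tuple[float, float]:
    """Global affine map from mixture mean to reported mean attenuation.

    A single (alpha, beta) for the whole cohort, least-squares fitted so
    per-grade expectations track the per-grade targets.  Deliberately not
    grade-specific: a per-grade offset would inject grade information into
    mean attenuation beyond what the attenuation mixture itself carries,
    which real measurements cannot do.
    """
    e_mix = np.array([_mixture_mean_moments(spec, gp)[0] for gp in spec.grades])
    target = np.array([gp.measures["mean_attenuation_hu"][0] for gp in spec.grades])
    dx = e_mix - e_mix.mean()
    if np.allclose(dx, 0):
        return float(target.mean() - e_mix.mean()), 1.0
    beta = float(np.dot(dx, target - target.mean()) / np.dot(dx, dx))
    alpha = float(target.mean() - beta * e_mix.mean())
    return alpha, beta


def sample_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw one cohort: one row per nodule, columns for every measure.

    Identical (spec, seed) pairs yield identical tables.  CTRV columns are
    computed in closed form from each nodule's attenuation mixture, so the
    sweep is monotone non-increasing within every row.  Mean attenuation is
    the mixture mean plus a grade-specific offset and residual noise (so it
    is coherent with CTRV); volume shares the solid-burden latent through a
    Gaussian copula; semantic features share a morphology latent.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for grade, (n, gp) in enumerate(zip(spec.n_per_grade, spec.grades)):
        if n == 0:
            continue
        burden = rng.normal(size=n)  # solid-burden latent
        morph = rng.normal(size=n)  # morphology latent
        if gp.f_beta_sd == 0:
            f = np.full(n, gp.f_beta_mean)
        else:
            a, b = _beta_from_moments(gp.f_beta_mean, gp.f_beta_sd)
            f = sps.beta.ppf(sps.norm.cdf(burden), a, b)
        measures = {
            m: _truncated_normal(rng, *gp.measures[m], *MEASURE_RANGES[m], n)
            for m in ("diameter_mm", "ctr_percent")
        }
        rho = spec.rho_volume
        z_vol = rho * burden + math.sqrt(1 - rho**2) * rng.normal(size=n)
        measures["volume_mm3"] = _truncnorm_from_quantile(
            sps.norm.cdf(z_vol), *gp.measures["volume_mm3"], *MEASURE_RANGES["volume_mm3"]
        )
        semantic = {}
        for s_name in SEMANTIC_FEATURES:
            lam = spec.semantic_loadings.get(s_name, _DEFAULT_LOADING)
            z = lam * morph + math.sqrt(1 - lam**2) * rng.normal(size=n)
            semantic[s_name] = z < sps.norm.ppf(gp.semantic_probs[s_name])
        mu_ggo = np.full(n, spec.mu_ggo)
        if spec.mu_ggo_jitter:
            mu_ggo += rng.normal(0.0, spec.mu_ggo_jitter, n)
        mu_solid = np.full(n, gp.mu_solid)
        if spec.mu_solid_jitter:
            mu_solid += rng.normal(0.0, spec.mu_solid_jitter, n)
        # keep the mixture well ordered even in the jitter tails
        mu_solid = np.maximum(mu_solid, mu_ggo + 1.0)
        mix_mean = (1 - f) * mu_ggo + f * mu_solid
        _, target_sd = gp.measures["mean_attenuation_hu"]
        _, v_mix = _mixture_mean_moments(spec, gp)
        alpha, beta_hu = _attenuation_affine(spec)
        resid_sd = math.sqrt(max(target_sd**2 - beta_hu**2 * v_mix, 0.0))
        lo, hi = MEASURE_RANGES["mean_attenuation_hu"]
        mean_hu = alpha + beta_hu * mix_mean
        if resid_sd > 0:
            noise = rng.normal(0.0, resid_sd, n)
            bad = (mean_hu + noise < lo) | (mean_hu + noise > hi)
            while bad.any():
                noise[bad] = rng.normal(0.0, resid_sd, int(bad.sum()))
                bad = (mean_hu + noise < lo) | (mean_hu + noise > hi)
            mean_hu = mean_hu + noise
        measures["mean_attenuation_hu"] = np.clip(mean_hu, lo, hi)
        for i in range(n):
            row = {
                "nodule_id": f"g{grade}_{i:04d}",
                "grade": grade,
                "high_risk": int(grade >= 2),
                **{s: int(semantic[s][i]) for s in SEMANTIC_FEATURES},
                **{m: float(measures[m][i]) for m in measures},
                "f_solid": float(f[i]),
                "mu_ggo": float(mu_ggo[i]),
                "sigma_ggo": spec.sigma_ggo,
                "mu_solid": float(mu_solid[i]),
                "sigma_solid": spec.sigma_solid,
            }
            mixture = AttenuationMixture(
                f=row["f_solid"], mu_ggo=row["mu_ggo"], sigma_ggo=spec.sigma_ggo,
                mu_solid=row["mu_solid"], sigma_solid=spec.sigma_solid,
            )
            sweep = ctrv_from_mixture(mixture, np.asarray(spec.thresholds))
            for t, v in zip(spec.thresholds, np.atleast_1d(sweep)):
                row[threshold_column(t)] = float(v)
            rows.append(row)
    if not rows:
        cols = (
            ["nodule_id", "grade", "high_risk", *SEMANTIC_FEATURES, *_MEASURE_DEFAULTS,
             "f_solid", "mu_ggo", "sigma_ggo", "mu_solid", "sigma_solid"]
            + [threshold_column(t) for t in spec.thresholds]
        )
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def truth_from_record(record) -> NoduleTruth:
    """Reconstruct a renderable ground truth from one cohort table row."""
    mixture = AttenuationMixture(
        f=float(record["f_solid"]),
        mu_ggo=float(record["mu_ggo"]),
        sigma_ggo=float(record["sigma_ggo"]),
        mu_solid=float(record["mu_solid"]),
        sigma_solid=float(record["sigma_solid"]),
    )
    return NoduleTruth(
        nodule_id=str(record["nodule_id"]),
        grade=int(record["grade"]),
        mixture=mixture,
        semantic={s: bool(record[s]) for s in SEMANTIC_FEATURES},
        diameter_mm=float(record["diameter_mm"]),
        volume_mm3=float(record["volume_mm3"]),
    )


def render_nodule_image(
    truth: NoduleTruth,
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    background_hu: float = -880.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CTVolume, NoduleMask]:
    """Voxelize one nodule as an ellipsoid in an aerated-lung background.

    The mask is an oblate ellipsoid (z semi-axis = 0.75 of the in-plane
    semi-axis) whose analytic volume equals ``truth.volume_mm3``; voxels are
    included when their centers fall inside.  In-mask attenuation follows
    the nodule's two-component mixture, with the solid component realized
    as a compact concentric core holding a fraction ``f`` of the mask
    voxels, so solid voxels are spatially contiguous.  Gaussian acquisition
    noise of SD ``noise_sd`` is added everywhere.
    """
    if any(s <= 0 for s in voxel_spacing):
        raise ValueError("voxel spacing must be positive")
    rng = np.random.default_rng(seed)
    dz, dy, dx = (float(s) for s in voxel_spacing)
    # semi-axes: a in-plane, c = 0.75 a axially; (4/3) pi a^2 c = volume
    a = (truth.volume_mm3 / ((4.0 / 3.0) * math.pi * 0.75)) ** (1.0 / 3.0)
    c = 0.75 * a
    if truth.volume_mm3 < 8.0 * dz * dy * dx:
        raise ValueError(
            f"requested volume {truth.volume_mm3:.1f} mm^3 spans fewer than 8 voxels "
            f"at spacing ({dz}, {dy}, {dx}); use finer spacing"
        )
    margin = 3
    nz = 2 * (int(math.ceil(c / dz)) + margin) + 1
    ny = 2 * (int(math.ceil(a / dy)) + margin) + 1
    nx = 2 * (int(math.ceil(a / dx)) + margin) + 1
    zc = (np.arange(nz) - nz // 2) * dz
    yc = (np.arange(ny) - ny // 2) * dy
    xc = (np.arange(nx) - nx // 2) * dx
    # squared ellipsoidal radius of every voxel center
    r2 = (
        (zc[:, None, None] / c) ** 2
        + (yc[None, :, None] / a) ** 2
        + (xc[None, None, :] / a) ** 2
    )
    mask = r2 <= 1.0
    n_mask = int(mask.sum())
    if n_mask < 8:
        raise ValueError("mask smaller than 8 voxels; use finer spacing")

    mix = truth.mixture
    n_solid = int(round(mix.f * n_mask))
    values = np.full((nz, ny, nx), float(background_hu))
    inside_r2 = r2[mask]
    order = np.argsort(inside_r2, kind="stable")
    hu = np.empty(n_mask)
    solid_idx = order[:n_solid]
    ggo_idx = order[n_solid:]
    hu[solid_idx] = rng.normal(mix.mu_solid, mix.sigma_solid, n_solid)
    hu[ggo_idx] = rng.normal(mix.mu_ggo, mix.sigma_ggo, n_mask - n_solid)
    values[mask] = hu
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, values.shape)
    return CTVolume(values, (dz, dy, dx)), NoduleMask(mask)


def duplicate_observer_measures(
    records: pd.DataFrame,
    observer_noise_sd: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate a second observer re-measuring the 2D quantities.

    Observer A reports the recorded value; observer B adds independent
    Gaussian error, truncated back to the measure's valid range.  The
    default error SDs (2.2 mm for diameter, 5.7 percentage points for CTR)
    put downstream ICC(2,1) near the high-agreement regime (~0.95).
    """
    if observer_noise_sd is None:
        observer_noise_sd = {"diameter_mm": 2.2, "ctr_percent": 5.7}
    if any(sd < 0 for sd in observer_noise_sd.values()):
        raise ValueError("observer noise SDs must be nonnegative")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame({"nodule_id": records["nodule_id"].to_numpy()})
    for measure, sd in observer_noise_sd.items():
        lo, hi = MEASURE_RANGES[measure]
        a = records[measure].to_numpy(dtype=float)
        b = a + rng.normal(0.0, sd, a.size) if sd > 0 else a.copy()
        out[f"{measure}_obs1"] = a
        out[f"{measure}_obs2"] = np.clip(b, lo, hi)
    return out


def split_cohorts(
    records: pd.DataFrame,
    counts: tuple[int, int] | None = None,
    fraction: float | None = None,
    stratify: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split one table into disjoint, exhaustive training/testing tables.

    Either explicit ``counts=(n_train, n_test)`` (must sum to the table
    size) or a training ``fraction``.  Stratification keeps per-grade
    proportions equal across the two parts up to rounding.
    """
    n = len(records)
    if (counts is None) == (fraction is None):
        raise ValueError("provide exactly one of counts or fraction")
    if counts is not None:
        if counts[0] + counts[1] != n or min(counts) < 0:
            raise ValueError(f"counts {counts} inconsistent with table size {n}")
        n_train = counts[0]
    else:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        n_train = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    if stratify and "grade" in records.columns and n > 0:
        train_idx: list[np.ndarray] = []
        remaining = n_train
        groups = list(records.groupby("grade").groups.items())
        for k, (_, idx) in enumerate(groups):
            idx = np.asarray(idx)
            left = sum(len(np.asarray(i)) for _, i in groups[k + 1 :])
            take = int(round(n_train * len(idx) / n))
            take = min(max(take, remaining - left), remaining, len(idx))
            train_idx.append(rng.permutation(idx)[:take])
            remaining -= take
        chosen = np.concatenate(train_idx) if train_idx else np.array([], dtype=int)
    else:
        chosen = rng.permutation(records.index.to_numpy())[:n_train]
    mask = records.index.isin(chosen)
    return records[mask].copy(), records[~mask].copy()
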