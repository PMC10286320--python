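"""Cohort generator: marginals, dependence, rendering, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, truncnorm

from psnquant.stats import icc_agreement
from psnquant.synthetic import (
    SEMANTIC_FEATURES,
    CohortSpec,
    GradeParams,
    NoduleTruth,
    default_training_spec,
    duplicate_observer_measures,
    render_nodule_image,
    sample_cohort,
    split_cohorts,
    truth_from_record,
)
from psnquant.types import AttenuationMixture, threshold_column
from psnquant.volumetry import ctrv, ctrv_from_mixture, mean_attenuation


def _degenerate_spec(training_spec):
    """All randomness removed: zero SDs, probabilities in {0, 1}."""
    grades = []
    for gp in training_spec.grades:
        grades.append(
            GradeParams(
                measures={m: (mu, 0.0) for m, (mu, _) in gp.measures.items()},
                semantic_probs={s: float(p > 0.5) for s, p in gp.semantic_probs.items()},
                f_beta_mean=gp.f_beta_mean,
                f_beta_sd=0.0,
                mu_solid=gp.mu_solid,
            )
        )
    return dataclasses.replace(
        training_spec,
        grades=tuple(grades),
        mu_ggo_jitter=0.0,
        mu_solid_jitter=0.0,
        n_per_grade=(5, 5, 5, 5),
    )


class TestSampleCohort:
    def test_training_cohort_size_and_composition(self, training_cohort):
        assert len(training_cohort) == 239
        assert training_cohort["grade"].value_counts().sort_index().tolist() == [15, 62, 151, 11]
        assert training_cohort["high_risk"].sum() == 162

    def test_zero_count_gives_empty_table(self, training_spec):
        spec = dataclasses.replace(training_spec, n_per_grade=(0, 0, 0, 0))
        table = sample_cohort(spec, seed=0)
        assert len(table) == 0 and "ctrv_m250" in table.columns

    def test_negative_sd_rejected(self, training_spec):
        bad = dataclasses.replace(
            training_spec.grades[0],
            measures={**training_spec.grades[0].measures, "diameter_mm": (10.0, -1.0)},
        )
        spec = dataclasses.replace(training_spec, grades=(bad, *training_spec.grades[1:]))
        with pytest.raises(ValueError, match="negative SD"):
            sample_cohort(spec, seed=0)

    def test_degenerate_spec_gives_identical_records(self, training_spec):
        table = sample_cohort(_degenerate_spec(training_spec), seed=3)
        for _, grp in table.groupby("grade"):
            grp = grp.drop(columns="nodule_id")
            assert (grp.nunique() == 1).all()

    def test_identical_seed_reproduces_byte_identical_table(self, training_spec):
        a = sample_cohort(training_spec, seed=11).to_csv(index=False)
        b = sample_cohort(training_spec, seed=11).to_csv(index=False)
        assert a == b
        c = sample_cohort(training_spec, seed=12).to_csv(index=False)
        assert a != c

    def test_ctrv_monotone_within_every_record(self, training_cohort):
        cols = [threshold_column(t) for t in range(-400, 51, 50)]
        values = training_cohort[cols].to_numpy()
        assert (np.diff(values, axis=1) <= 1e-12).all()

    def test_lobulation_frequencies_match_binomial_oracle(self, training_spec):
        """At n = 10,000 per grade the empirical yes-rates sit within 2
        binomial SEs of the generating probabilities."""
        spec = dataclasses.replace(training_spec, n_per_grade=(10_000,) * 4)
        table = sample_cohort(spec, seed=1)
        probs = (14 / 15, 24 / 62, 134 / 151, 11 / 11)
        for g, p in enumerate(probs):
            freq = table.loc[table["grade"] == g, "lobulation"].mean()
            se = np.sqrt(p * (1 - p) / 10_000)
            assert abs(freq - p) <= max(2 * se, 1e-9)

    def test_moments_converge_to_spec_values(self, training_spec):
        """Diameter tracks the truncated-normal law; CTRV at -250 HU tracks
        the calibrated per-grade targets (3 SE at n = 10,000)."""
        spec = dataclasses.replace(training_spec, n_per_grade=(10_000,) * 4)
        table = sample_cohort(spec, seed=2)
        ctrv_targets = [(3.4, 2.9), (7.5, 7.6), (26.5, 16.7), (40.6, 9.7)]
        for g in range(4):
            grp = table[table["grade"] == g]
            mu, sd = spec.grades[g].measures["diameter_mm"]
            a = (1e-6 - mu) / sd
            expected = truncnorm.mean(a, np.inf, loc=mu, scale=sd)
            exp_sd = truncnorm.std(a, np.inf, loc=mu, scale=sd)
            assert grp["diameter_mm"].mean() == pytest.approx(
                expected, abs=3 * exp_sd / 100
            )
            t_mu, t_sd = ctrv_targets[g]
            assert grp["ctrv_m250"].mean() == pytest.approx(t_mu, abs=3 * t_sd / 100 + 0.15)
            assert grp["ctrv_m250"].std() == pytest.approx(t_sd, rel=0.1)

    def test_volume_couples_to_solid_fraction(self, training_cohort):
        sub = training_cohort[training_cohort["grade"] == 2]
        r = np.corrcoef(sub["volume_mm3"], sub["f_solid"])[0, 1]
        assert r > 0.2  # within-grade dependence, not just grade-driven


class TestRenderNodule:
    def test_degenerate_mixture_renders_constant(self):
        truth = NoduleTruth(
            "n0", 3, AttenuationMixture(1.0, -600, 1e-9, -50, 1e-9),
            {}, diameter_mm=12.0, volume_mm3=800.0,
        )
        vol, mask = render_nodule_image(truth, noise_sd=0.0, seed=0)
        assert np.allclose(vol.values[mask.values], -50.0)

    def test_ellipsoid_volume_matches_within_a_voxel_layer(self):
        truth = NoduleTruth(
            "n1", 2, AttenuationMixture(0.3, -600, 70, -150, 70),
            {}, diameter_mm=12.0, volume_mm3=1000.0,
        )
        _, mask = render_nodule_image(truth, (1.0, 1.0, 1.0), seed=1)
        assert mask.n_voxels == pytest.approx(1000, abs=50)

    def test_too_small_volume_raises(self):
        truth = NoduleTruth(
            "n2", 0, AttenuationMixture(0.1, -600, 70, -200, 70),
            {}, diameter_mm=1.0, volume_mm3=4.0,
        )
        with pytest.raises(ValueError, match="finer spacing"):
            render_nodule_image(truth, (1.0, 1.0, 1.0), seed=0)

    def test_voxel_ctrv_matches_mixture_survival(self):
        """With >= 1e5 mask voxels the voxel fraction above -250 HU lands
        within 3 Monte Carlo SEs of the closed-form mixture value."""
        mix = AttenuationMixture(0.3, -600, 60, -50, 60)
        truth = NoduleTruth("n3", 2, mix, {}, diameter_mm=60.0, volume_mm3=150_000.0)
        vol, mask = render_nodule_image(truth, (1.0, 1.0, 1.0), noise_sd=0.0, seed=4)
        n = mask.n_voxels
        assert n >= 100_000
        expected = ctrv_from_mixture(mix, -250.0)
        se = 100 * np.sqrt(expected / 100 * (1 - expected / 100) / n)
        got = ctrv(vol, mask, -250.0)
        # the compact core fixes the solid count at round(f * n): add the
        # rounding slack to the sampling SE
        assert got == pytest.approx(expected, abs=3 * se + 100 / n)

    def test_rendered_mean_attenuation_matches_mixture_mean(self):
        mix = AttenuationMixture(0.4, -600, 60, -100, 60)
        truth = NoduleTruth("n4", 2, mix, {}, diameter_mm=40.0, volume_mm3=50_000.0)
        vol, mask = render_nodule_image(truth, (1.0, 1.0, 1.0), noise_sd=0.0, seed=5)
        expected = (1 - mix.f) * mix.mu_ggo + mix.f * mix.mu_solid
        sd = np.sqrt(60**2 + mix.f * (1 - mix.f) * 500**2)
        assert mean_attenuation(vol, mask) == pytest.approx(
            expected, abs=3 * sd / np.sqrt(mask.n_voxels)
        )

    def test_solid_core_is_contiguous_and_sized(self):
        mix = AttenuationMixture(0.3, -600, 40, -50, 40)
        truth = NoduleTruth("n5", 2, mix, {}, diameter_mm=25.0, volume_mm3=8000.0)
        vol, mask = render_nodule_image(truth, (1.0, 1.0, 1.0), noise_sd=0.0, seed=6)
        from scipy.ndimage import label

        solid = mask.values & (vol.values >= -325.0)  # between the two modes
        n_solid = solid.sum()
        assert n_solid == pytest.approx(0.3 * mask.n_voxels, rel=0.02)
        _, n_components = label(solid)
        assert n_components == 1

    def test_reproducible_under_fixed_seed(self):
        mix = AttenuationMixture(0.2, -600, 70, -150, 70)
        truth = NoduleTruth("n6", 1, mix, {}, diameter_mm=12.0, volume_mm3=900.0)
        v1, _ = render_nodule_image(truth, seed=9, noise_sd=15.0)
        v2, _ = render_nodule_image(truth, seed=9, noise_sd=15.0)
        assert np.array_equal(v1.values, v2.values)


class TestObserverPairs:
    def test_zero_noise_gives_perfect_agreement(self, training_cohort):
        pairs = duplicate_observer_measures(
            training_cohort, {"diameter_mm": 0.0}, seed=0
        )
        icc, _ = icc_agreement(pairs[["diameter_mm_obs1", "diameter_mm_obs2"]].to_numpy())
        assert icc == pytest.approx(1.0)

    def test_default_noise_calibrated_to_high_agreement(
        self, training_cohort, testing_cohort
    ):
        """On the combined 326-nodule sample the diameter ICC sits near the
        high-agreement benchmark (~0.95)."""
        both = pd.concat([training_cohort, testing_cohort], ignore_index=True)
        pairs = duplicate_observer_measures(both, seed=7)
        icc, _ = icc_agreement(pairs[["diameter_mm_obs1", "diameter_mm_obs2"]].to_numpy())
        assert icc == pytest.approx(0.95, abs=0.02)

    def test_deterministic_under_fixed_seed(self, training_cohort):
        a = duplicate_observer_measures(training_cohort, seed=3)
        b = duplicate_observer_measures(training_cohort, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestSplitCohorts:
    def test_explicit_counts(self, training_cohort, testing_cohort):
        both = pd.concat([training_cohort, testing_cohort], ignore_index=True)
        train, test = split_cohorts(both, counts=(239, 87), seed=0)
        assert len(train) == 239 and len(test) == 87
        assert set(train.index).isdisjoint(test.index)

    def test_full_fraction_gives_empty_test(self, training_cohort):
        train, test = split_cohorts(training_cohort, fraction=1.0, seed=0)
        assert len(test) == 0 and len(train) == len(training_cohort)

    def test_stratified_proportions(self, training_cohort):
        train, test = split_cohorts(training_cohort, fraction=0.6, stratify=True, seed=2)
        for g, total in training_cohort["grade"].value_counts().items():
            got = (train["grade"] == g).sum()
            assert abs(got - 0.6 * total) <= 1.0

    def test_inconsistent_counts_rejected(self, training_cohort):
        with pytest.raises(ValueError, match="inconsistent"):
            split_cohorts(training_cohort, counts=(300, 87))

    def test_truth_roundtrip(self, training_cohort):
        truth = truth_from_record(training_cohort.iloc[17])
        assert truth.grade == training_cohort.iloc[17]["grade"]
        assert truth.mixture.f == training_cohort.iloc[17]["f_solid"]
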