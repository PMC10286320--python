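"""ROC/AUC machinery, DeLong, Youden, exact intervals, calibration."""

import numpy as np
import pytest
from scipy.stats import norm

from psnquant.evaluation import (
    auc_ci,
    auc_mw,
    clopper_pearson,
    delong_test,
    delong_variance,
    evaluate_scores,
    hosmer_lemeshow,
    roc_curve_points,
    youden_cutoff,
)


def _labels(n_pos, n_neg):
    return np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]


class TestAUC:
    def test_perfect_separation(self):
        assert auc_mw([0.9, 0.8, 0.1, 0.2], _labels(2, 2)) == 1.0

    def test_pair_counting_example(self):
        # pairs: (0.8 vs 0.5, 0.8 vs 0.1, 0.3 vs 0.5, 0.3 vs 0.1) -> 3/4
        assert auc_mw([0.8, 0.3, 0.5, 0.1], _labels(2, 2)) == 0.75

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        assert auc_mw(scores, rng.integers(0, 2, 2000)) == pytest.approx(0.5, abs=0.05)

    def test_equals_trapezoid_under_roc_curve(self, rng):
        """Oracle: trapezoidal area under the empirical ROC, and sklearn."""
        from sklearn.metrics import roc_auc_score

        for _ in range(15):
            n = rng.integers(6, 20)
            labels = np.zeros(n, int)
            labels[: rng.integers(1, n - 1)] = 1
            scores = np.round(rng.normal(size=n), 1)  # provoke ties
            pts = roc_curve_points(scores, labels)
            trap = float(np.trapezoid(pts[:, 1], pts[:, 0]))
            got = auc_mw(scores, labels)
            assert got == pytest.approx(trap, abs=1e-12)
            assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        base = auc_mw(scores, labels)
        assert auc_mw(np.exp(scores), labels) == base
        assert auc_mw(scores**3 + scores, labels) == base

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_mw([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_self_comparison_is_null(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        comp = delong_test(scores, scores, labels)
        assert comp.z == 0.0 and comp.p == 1.0

    def test_monotone_transform_is_null(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        comp = delong_test(scores, np.exp(scores), labels)
        assert comp.p == 1.0

    def test_antisymmetric(self, rng):
        a, b = rng.normal(size=100), rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        ab = delong_test(a, b, labels)
        ba = delong_test(b, a, labels)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p == pytest.approx(ba.p)

    def test_se_matches_bootstrap_oracle(self):
        """DeLong SE of one AUC vs a 10^4-resample bootstrap on n = 10."""
        rng = np.random.default_rng(3)
        pos = rng.normal(1.0, 1.0, 5)
        neg = rng.normal(0.0, 1.0, 5)
        scores = np.r_[pos, neg]
        labels = _labels(5, 5)
        _, var = delong_variance(scores, labels)
        boots = np.empty(10_000)
        for i in range(10_000):
            p = rng.choice(pos, 5)
            n = rng.choice(neg, 5)
            boots[i] = ((p[:, None] > n[None, :]) + 0.5 * (p[:, None] == n[None, :])).mean()
        assert np.sqrt(var) == pytest.approx(boots.std(), rel=0.15)


class TestAUCConfidenceIntervals:
    def test_perfect_separation_clips_to_one(self):
        lo, hi = auc_ci([3, 4, 1, 2], _labels(2, 2))
        assert hi == 1.0 and lo <= 1.0

    def test_width_shrinks_with_n(self, rng):
        widths = []
        for n in (25, 100, 400):
            w = []
            for _ in range(30):
                scores = np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)]
                lo, hi = auc_ci(scores, _labels(n, n))
                w.append(hi - lo)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]

    def test_null_interval_roughly_symmetric(self, rng):
        scores = rng.normal(size=400)
        labels = _labels(200, 200)
        auc = auc_mw(scores, labels)
        lo, hi = auc_ci(scores, labels)
        assert (auc - lo) == pytest.approx(hi - auc, abs=1e-9)

    def test_exact_binomial_variant_stays_in_unit_interval(self, rng):
        scores = np.r_[rng.normal(1.5, 1, 30), rng.normal(0, 1, 40)]
        labels = _labels(30, 40)
        lo, hi = auc_ci(scores, labels, method="exact-binomial")
        auc = auc_mw(scores, labels)
        assert 0.0 <= lo < auc < hi <= 1.0


class TestYouden:
    def test_separable_groups(self):
        cutoff, sens, spec, degenerate = youden_cutoff([3, 4, 1, 2], _labels(2, 2))
        assert 2 < cutoff < 3
        assert sens == 1.0 and spec == 1.0 and not degenerate

    def test_all_equal_scores_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            _, _, _, degenerate = youden_cutoff([1, 1, 1, 1], _labels(2, 2))
        assert degenerate

    def test_tie_broken_toward_specificity(self):
        scores = [0.9, 0.7, 0.4, 0.6, 0.3, 0.2]
        cutoff, sens, spec, _ = youden_cutoff(scores, _labels(3, 3))
        assert 0.6 < cutoff < 0.7
        assert sens == pytest.approx(2 / 3) and spec == 1.0

    def test_reported_rates_reproduce_direct_thresholding(self, rng):
        """Bit-exact agreement between the reported operating point and the
        confusion matrix from thresholding at the returned cutoff."""
        for _ in range(20):
            n = int(rng.integers(10, 40))
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            scores = np.round(rng.normal(size=n), 1)
            cutoff, sens, spec, _ = youden_cutoff(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            assert sens == (pos > cutoff).mean()
            assert spec == (neg <= cutoff).mean()


class TestClopperPearson:
    def test_certain_success_upper_bound(self):
        lo, hi = clopper_pearson(10, 10)
        assert hi == 1.0 and lo == pytest.approx(0.025 ** (1 / 10), abs=1e-9)

    def test_zero_successes_closed_form(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-4)
        assert hi == pytest.approx(0.3085, abs=1e-4)

    def test_sensitivity_interval_141_of_162(self):
        lo, hi = clopper_pearson(141, 162)
        assert 141 / 162 == pytest.approx(0.870, abs=0.001)
        assert lo == pytest.approx(0.809, abs=0.001)
        assert hi == pytest.approx(0.918, abs=0.001)

    def test_coverage_at_least_nominal(self, rng):
        """Exact intervals cover the true proportion in >= 95% of draws."""
        for p in (0.1, 0.5, 0.87):
            k = rng.binomial(60, p, size=400)
            covered = 0
            for ki in k:
                lo, hi = clopper_pearson(int(ki), 60)
                covered += lo <= p <= hi
            assert covered / 400 >= 0.945

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(1, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 3)


class TestHosmerLemeshow:
    def test_chi2_calibrated_under_correct_model(self, rng):
        """When outcomes are drawn from the stated probabilities the
        statistic is a sum over g bins of ~unit-mean terms, so its mean over
        replicates approaches g (the g - 2 df convention applies to fitted
        probabilities, which lose two parameters)."""
        stats = []
        for _ in range(400):
            p = rng.uniform(0.05, 0.95, 500)
            y = (rng.random(500) < p).astype(int)
            chi2, _ = hosmer_lemeshow(p, y)
            stats.append(chi2)
        assert np.mean(stats) == pytest.approx(10.0, abs=1.0)

    def test_perfectly_calibrated_bins_give_zero(self):
        # ten bins, each with probability equal to the bin's event rate
        p = np.repeat(np.linspace(0.05, 0.95, 10), 20)
        y = np.concatenate([
            np.r_[np.ones(round(20 * q)), np.zeros(20 - round(20 * q))]
            for q in np.linspace(0.05, 0.95, 10)
        ]).astype(int)
        chi2, pval = hosmer_lemeshow(p, y)
        assert chi2 == pytest.approx(0.0, abs=1e-9) and pval == pytest.approx(1.0)

    def test_anticalibrated_probabilities_rejected(self, rng):
        p = rng.uniform(0.1, 0.9, 1000)
        y = (rng.random(1000) < p).astype(int)
        _, pval = hosmer_lemeshow(1 - p, y)
        assert pval < 1e-3

    def test_few_distinct_probabilities_merge_bins(self, rng):
        p = np.repeat([0.2, 0.5, 0.8], 50)
        y = (rng.random(150) < p).astype(int)
        with pytest.warns(UserWarning, match="merged"):
            chi2, pval = hosmer_lemeshow(p, y)
        assert 0 <= pval <= 1


class TestEvaluateScores:
    def test_bundle_consistency(self, rng):
        scores = np.r_[rng.normal(1.2, 1, 80), rng.normal(0, 1, 60)]
        labels = _labels(80, 60)
        ev = evaluate_scores(scores, labels)
        assert ev.auc_ci_low <= ev.auc <= ev.auc_ci_high
        assert ev.n_pos == 80 and ev.n_neg == 60
        assert 0 <= ev.sensitivity <= 1 and 0 <= ev.specificity <= 1
        assert ev.sensitivity_ci[0] <= ev.sensitivity <= ev.sensitivity_ci[1]
        assert ev.hosmer_lemeshow_p is None

    def test_probability_scores_add_calibration(self, rng):
        p = rng.uniform(0.05, 0.95, 400)
        y = (rng.random(400) < p).astype(int)
        ev = evaluate_scores(p, y, probabilities=p)
        assert ev.hosmer_lemeshow_p is not None and ev.hosmer_lemeshow_p > 0.001
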