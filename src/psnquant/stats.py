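"""Nonparametric, agreement and correlation-comparison statistics.

Thin, explicitly-contracted wrappers around scipy/pingouin plus two
procedures not available there: the Fisher Z-transform comparison of two
correlation coefficients (independent samples) and Steiger's Z for two
dependent, overlapping correlations (two predictors correlated with the
same outcome on the same subjects).

Tie handling is mid-rank everywhere.  Grade enters rank correlations as its
ordinal code 0-3; only the order matters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "CorrelationResult",
    "CorrelationComparison",
    "spearman",
    "compare_correlations",
    "mann_whitney_u",
    "kruskal_wallis",
    "fisher_exact",
    "icc_agreement",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation with its two-sided p-value and sample size."""

    r: float
    p: float
    n: int
    valid: bool = True


@dataclass(frozen=True)
class CorrelationComparison:
    """Z test of the difference between two correlation coefficients."""

    z: float
    p: float
    method: str  # "independent-fisher" or "dependent-steiger"
    valid: bool = True


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with a t-approximation p-value (n-2 df).

    A constant input vector leaves the coefficient undefined; the result is
    returned flagged (``valid=False``) rather than propagating NaN silently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, valid=False)
    res = sps.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), n)


def _atanh_checked(r: float) -> float:
    if abs(r) >= 1.0:
        raise FloatingPointError
    return math.atanh(r)


def compare_correlations(
    result_a: CorrelationResult,
    result_b: CorrelationResult,
    r_ab: float | None = None,
    method: str = "dependent-steiger",
) -> CorrelationComparison:
    """Test whether two correlation coefficients differ.

    ``independent-fisher``
        Fisher Z-transform test for correlations estimated on independent
        samples: ``z = (atanh(rA) - atanh(rB)) / sqrt(1/(nA-3) + 1/(nB-3))``.

    ``dependent-steiger``
        Steiger's Z for overlapping correlations: rA = corr(outcome, A) and
        rB = corr(outcome, B) share the outcome variable and the subjects,
        so the two transformed coefficients are themselves correlated;
        ``r_ab`` (the correlation between predictors A and B) supplies the
        dependence.  Requires equal n.  As r_ab -> 0 and the coefficients
        shrink, the statistic tends to the independent formula with pooled
        variance 2/(n-3).

    A coefficient of +/-1 makes the transform infinite; the comparison is
    returned flagged.
    """
    ra, rb = result_a.r, result_b.r
    try:
        za, zb = _atanh_checked(ra), _atanh_checked(rb)
    except FloatingPointError:
        return CorrelationComparison(float("inf"), 0.0, method, valid=False)

    if method == "independent-fisher":
        if result_a.n <= 3 or result_b.n <= 3:
            raise ValueError("Fisher Z comparison requires n > 3 in both samples")
        se = math.sqrt(1.0 / (result_a.n - 3) + 1.0 / (result_b.n - 3))
        z = (za - zb) / se
    elif method == "dependent-steiger":
        if result_a.n != result_b.n:
            raise ValueError("dependent comparison requires the same subjects (equal n)")
        if r_ab is None:
            raise ValueError("dependent comparison requires r_ab, the predictor intercorrelation")
        n = result_a.n
        if n <= 3:
            raise ValueError("dependent comparison requires n > 3")
        rbar = 0.5 * (ra + rb)
        rbar2 = rbar * rbar
        # Covariance of the two Fisher-transformed coefficients (pooled form).
        psi = r_ab * (1.0 - 2.0 * rbar2) - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r_ab * r_ab)
        s = psi / (1.0 - rbar2) ** 2
        denom = 2.0 - 2.0 * s
        if denom <= 1e-12:
            # perfectly dependent coefficients (e.g. identical predictors):
            # the difference has zero variance
            if abs(za - zb) <= 1e-12:
                return CorrelationComparison(0.0, 1.0, method)
            return CorrelationComparison(math.copysign(float("inf"), za - zb), 0.0, method, valid=False)
        z = (za - zb) * math.sqrt((n - 3) / denom)
    else:
        raise ValueError(f"unknown method {method!r}")

    p = 2.0 * sps.norm.sf(abs(z))
    return CorrelationComparison(float(z), float(min(p, 1.0)), method)


def mann_whitney_u(group0, group1) -> tuple[float, float]:
    """Mann-Whitney U (for group0 over group1) with two-sided p.

    Exact p by enumeration for small samples (n0+n1 <= 12) without ties;
    otherwise the normal approximation with tie correction and continuity
    correction.
    """
    g0 = np.asarray(group0, dtype=float)
    g1 = np.asarray(group1, dtype=float)
    if g0.size == 0 or g1.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([g0, g1])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (g0.size + g1.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(g0, g1, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("Kruskal-Wallis requires >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0  # all observations tied: no evidence of any difference
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _table_logprob(tables: np.ndarray) -> np.ndarray:
    """Log hypergeometric probability of r x c tables with fixed margins.

    Margin-dependent constants are omitted: only differences matter here.
    """
    return -gammaln(tables + 1.0).sum(axis=(-2, -1))


def _fisher_exact_2xc(table: np.ndarray) -> float:
    """Exact conditional p for a 2 x c table by enumeration over row 0."""
    col = table.sum(axis=0)
    r0 = int(table[0].sum())
    c = table.shape[1]

    obs_lp = float(_table_logprob(table))
    total_lp: list[float] = []
    extreme_lp: list[float] = []

    def rec(j: int, remaining: int, partial: list[int]):
        if j == c - 1:
            if remaining > col[-1]:
                return
            cells = partial + [remaining]
            t = np.array([cells, col - cells], dtype=float)
            if (t < 0).any():
                return
            lp = float(_table_logprob(t))
            total_lp.append(lp)
            if lp <= obs_lp + 1e-9:
                extreme_lp.append(lp)
            return
        lo = max(0, remaining - int(col[j + 1 :].sum()))
        hi = min(int(col[j]), remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a, partial + [a])

    rec(0, r0, [])
    total_lp_arr = np.array(total_lp)
    m = total_lp_arr.max()
    denom = np.exp(total_lp_arr - m).sum()
    num = np.exp(np.array(extreme_lp) - m).sum()
    return float(num / denom)


def fisher_exact(table, n_resamples: int = 100_000, seed: int | None = 0) -> float:
    """Two-sided Fisher's exact test for an r x c count table.

    2x2 tables use the exact hypergeometric test.  Larger tables with one
    dimension of size 2 and total count <= 200 are enumerated exactly;
    anything else falls back to a seeded Monte Carlo test (>= ``n_resamples``
    tables sampled with Patefield's algorithm), whose p-value definition
    (probability of a table at most as probable as the observed one)
    matches the exact test.  A zero margin yields p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2D array of nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in contingency table: test is degenerate, p = 1")
        return 1.0
    if t.shape == (2, 2):
        return float(sps.fisher_exact(t).pvalue)
    if t.shape[1] == 2 and t.shape[0] != 2:
        t = t.T
    if t.shape[0] == 2 and t.sum() <= 200:
        return _fisher_exact_2xc(t)
    rng = np.random.default_rng(seed)
    dist = sps.random_table(t.sum(axis=1), t.sum(axis=0))
    sampled = dist.rvs(n_resamples, method="patefield", random_state=rng)
    lp = _table_logprob(sampled)
    obs = float(_table_logprob(t.astype(float)))
    # +1 correction keeps the Monte Carlo p-value strictly positive.
    return float((np.sum(lp <= obs + 1e-9) + 1) / (n_resamples + 1))


def icc_agreement(ratings) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an n x 2 array of paired measurements (one column per
    observer).  Returns the ICC and its 95% F-based confidence interval.
    Zero total variance leaves the coefficient undefined (NaN, NaN CI).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 3:
        raise ValueError("ratings must be an n x 2 array with n >= 3")
    if np.ptp(x) == 0:
        warnings.warn("zero total variance: ICC is undefined")
        return float("nan"), (float("nan"), float("nan"))

    import pandas as pd
    import pingouin as pg

    n = x.shape[0]
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "rater": np.tile([0, 1], n),
            "score": x.ravel(),
        }
    )
    res = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    # two-way random, absolute agreement, single rater: labelled ICC2 or
    # ICC(A,1) depending on the pingouin release
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    ci_col = next(c for c in res.columns if c.startswith("CI95"))
    lo, hi = (float(v) for v in row[ci_col])
    return float(row["ICC"]), (lo, hi)
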