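"""ROC evaluation, cutoff selection, calibration and AUC comparison.

The AUC is the Mann-Whitney estimator (probability that a random positive
outscores a random negative, ties counting one half), its variance and the
paired comparison of two markers on the same subjects follow DeLong's
structural-components method, the operating point is chosen by Youden's
index with a strict ``score > cutoff`` positivity rule, sensitivity and
specificity carry Clopper-Pearson exact binomial intervals, and model
calibration is checked with the Hosmer-Lemeshow decile test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta, chi2, norm

__all__ = [
    "ModelEvaluation",
    "AUCComparison",
    "auc_mw",
    "delong_components",
    "delong_variance",
    "delong_test",
    "auc_ci",
    "youden_cutoff",
    "clopper_pearson",
    "hosmer_lemeshow",
    "evaluate_scores",
    "roc_curve_points",
]


@dataclass
class ModelEvaluation:
    """Discrimination, operating point and calibration of one marker."""

    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    hosmer_lemeshow_chi2: float | None = None
    hosmer_lemeshow_p: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class AUCComparison:
    """DeLong paired comparison of two AUCs."""

    auc_a: float
    auc_b: float
    z: float
    p: float


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D vectors of equal length")
    pos, neg = scores[labels == 1], scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def auc_mw(scores, labels) -> float:
    """Mann-Whitney AUC: mean of [pos > neg] + 0.5 [pos == neg] pairs."""
    pos, neg = _split(scores, labels)
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def delong_components(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC with its DeLong structural components (V10 per positive, V01 per negative)."""
    pos, neg = _split(scores, labels)
    psi = np.where(
        pos[:, None] > neg[None, :], 1.0, np.where(pos[:, None] == neg[None, :], 0.5, 0.0)
    )
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC estimate)."""
    auc, v10, v01 = delong_components(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def delong_test(scores_a, scores_b, labels) -> AUCComparison:
    """Paired DeLong test of two markers scored on the same subjects.

    Identical rankings give a zero-variance difference; that degenerate
    case is reported as z = 0, p = 1 by convention.
    """
    auc_a, v10_a, v01_a = delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    var = 0.0
    if m > 1:
        s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return AUCComparison(auc_a, auc_b, 0.0, 1.0)
    z = (auc_a - auc_b) / np.sqrt(var)
    return AUCComparison(auc_a, auc_b, float(z), float(min(2 * norm.sf(abs(z)), 1.0)))


def auc_ci(scores, labels, method: str = "delong", level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for the AUC.

    ``delong``
        Normal interval on the DeLong standard error, clipped to [0, 1].
    ``exact-binomial``
        Clopper-Pearson interval on the AUC with an effective number of
        Bernoulli trials chosen to match the DeLong variance
        (n_eff = auc (1 - auc) / var); a distribution-based exact-style
        interval that stays inside [0, 1] by construction.
    """
    auc, var = delong_variance(scores, labels)
    se = float(np.sqrt(var))
    z = norm.ppf(0.5 + level / 2)
    if method == "delong":
        return max(0.0, auc - z * se), min(1.0, auc + z * se)
    if method == "exact-binomial":
        if se == 0.0:
            return (1.0, 1.0) if auc == 1.0 else (auc, auc)
        n_eff = max(auc * (1.0 - auc) / var, 1.0)
        k = auc * n_eff
        alpha = 1.0 - level
        lo = 0.0 if k <= 0 else float(beta.ppf(alpha / 2, k, n_eff - k + 1))
        hi = 1.0 if k >= n_eff else float(beta.ppf(1 - alpha / 2, k + 1, n_eff - k))
        return lo, hi
    raise ValueError(f"unknown method {method!r}")


def _confusion_at(scores, labels, cutoff):
    pos, neg = _split(scores, labels)
    tp = int((pos > cutoff).sum())
    tn = int((neg <= cutoff).sum())
    return tp, pos.size, tn, neg.size


def youden_cutoff(scores, labels) -> tuple[float, float, float, bool]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Positivity rule: ``score > cutoff``.  J is scanned over all distinct
    observed scores; ties in J are broken toward higher specificity (the
    higher cutoff).  The reported cutoff is the midpoint between the lowest
    positive-classified score and the next lower distinct score, so the
    decision boundary sits between observed values.  Returns
    (cutoff, sensitivity, specificity, degenerate); ``degenerate`` is True
    when every cutoff gives J = 0 (e.g. all scores equal).
    """
    pos, neg = _split(scores, labels)
    distinct = np.unique(np.concatenate([pos, neg]))
    best = None
    for s in distinct:  # classify "score >= s" as positive
        sens = float((pos >= s).mean())
        spec = float((neg < s).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and s > best[1]):
            best = (j, s, sens, spec)
    j, s, sens, spec = best
    lower = distinct[distinct < s]
    if lower.size:
        cutoff = 0.5 * (s + lower.max())
    else:
        gap = distinct[1] - distinct[0] if distinct.size > 1 else 1.0
        cutoff = s - 0.5 * gap
    degenerate = bool(j <= 1e-12)
    if degenerate:
        warnings.warn("Youden's index is 0 at every cutoff: degenerate operating point")
    return float(cutoff), sens, spec, degenerate


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) interval from Beta quantiles."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def hosmer_lemeshow(probabilities, outcomes, g: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness-of-fit chi-square over probability deciles.

    Subjects are grouped into ``g`` equal-frequency bins of predicted
    probability; the statistic sums (observed - expected)^2 / expected over
    both outcome classes in every bin, with g - 2 degrees of freedom.
    Fewer distinct probabilities than bins merges bins (with a warning and
    adjusted df).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes).astype(int)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, g + 1)))
    if edges.size - 1 < g:
        warnings.warn(f"merged probability bins: {edges.size - 1} bins instead of {g}")
    bins = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, edges.size - 2)
    chi2_stat, used = 0.0, 0
    for b in range(edges.size - 1):
        sel = bins == b
        if not sel.any():
            continue
        used += 1
        obs1, exp1 = y[sel].sum(), p[sel].sum()
        obs0, exp0 = (~y[sel].astype(bool)).sum(), (1 - p[sel]).sum()
        chi2_stat += (obs1 - exp1) ** 2 / exp1 + (obs0 - exp0) ** 2 / exp0
    df = max(used - 2, 1)
    return float(chi2_stat), float(chi2.sf(chi2_stat, df))


def roc_curve_points(scores, labels) -> np.ndarray:
    """Empirical ROC coordinates (FPR, TPR), one row per distinct cutoff."""
    pos, neg = _split(scores, labels)
    cuts = np.concatenate([[-np.inf], np.unique(np.concatenate([pos, neg]))])
    pts = [(float((neg > c).mean()), float((pos > c).mean())) for c in cuts]
    return np.array(sorted(set(pts)))


def evaluate_scores(
    scores,
    labels,
    probabilities=None,
    ci_method: str = "delong",
) -> ModelEvaluation:
    """Full evaluation bundle for one score vector.

    When ``probabilities`` (predicted event probabilities on the same
    subjects) are supplied, the Hosmer-Lemeshow calibration test is added;
    raw markers that are not probabilities skip it.
    """
    pos, neg = _split(scores, labels)
    auc = auc_mw(scores, labels)
    lo, hi = auc_ci(scores, labels, method=ci_method)
    cutoff, sens, spec, degenerate = youden_cutoff(scores, labels)
    tp, n_pos, tn, n_neg = _confusion_at(scores, labels, cutoff)
    hl_chi2 = hl_p = None
    if probabilities is not None:
        hl_chi2, hl_p = hosmer_lemeshow(probabilities, labels)
    return ModelEvaluation(
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        cutoff=cutoff,
        sensitivity=tp / n_pos,
        sensitivity_ci=clopper_pearson(tp, n_pos),
        specificity=tn / n_neg,
        specificity_ci=clopper_pearson(tn, n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
        hosmer_lemeshow_chi2=hl_chi2,
        hosmer_lemeshow_p=hl_p,
        degenerate=degenerate,
    )
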