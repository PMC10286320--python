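"""Desk-scale reproduction of the headline cohort statistics.

The patient-level data behind the reference cohorts are not public, but the
per-grade and per-risk-group distribution parameters (mean, SD, group
sizes) are.  Drawing truncated-normal samples from those parameters and
recomputing the statistic of interest gives an unbiased desk-scale estimate
of what the cohort-level analysis produced: the Spearman correlation
between grade and a measure, or the AUC separating the risk groups.
Averaging over a few hundred seeded replicates removes most simulation
noise.

All functions draw through a numpy Generator so a single seed fixes the
whole reproduction.
"""

from __future__ import annotations

import numpy as np

from .evaluation import auc_mw
from .pipeline import select_threshold
from .stats import spearman
from .synthetic import _truncated_normal, default_training_spec, sample_cohort

__all__ = [
    "GRADE_SIZES",
    "CTRV250_BY_GRADE",
    "CTR_BY_GRADE",
    "RISK_GROUPS",
    "mean_grade_correlation",
    "mean_risk_group_auc",
    "sweep_winner_rate",
]

#: Training-cohort grade composition (MIA, IPA grade 1, 2, 3).
GRADE_SIZES = (15, 62, 151, 11)

#: Per-grade (mean, SD) of CTRV at -250 HU, percent.
CTRV250_BY_GRADE = ((3.4, 2.9), (7.5, 7.6), (26.5, 16.7), (40.6, 9.7))

#: Per-grade (mean, SD) of the 2D consolidation-to-tumor ratio, percent.
CTR_BY_GRADE = ((38.6, 10.6), (38.9, 13.1), (53.4, 15.8), (64.1, 14.1))

#: Risk-group (n, mean, SD) of CTRV at -250 HU per cohort:
#: (low-risk, high-risk) for the training and testing cohorts.
RISK_GROUPS = {
    "training": ((77, 6.7, 7.1), (162, 27.4, 16.7)),
    "testing": ((28, 8.7, 9.4), (59, 27.6, 17.3)),
}


def mean_grade_correlation(
    params_by_grade=CTRV250_BY_GRADE,
    sizes=GRADE_SIZES,
    n_reps: int = 200,
    seed: int = 0,
) -> float:
    """Mean Spearman correlation between grade and a simulated measure.

    Each replicate draws per-grade truncated-normal values (range [0, 100])
    with the stated (mean, SD) and group sizes, then correlates them with
    the ordinal grade.
    """
    rng = np.random.default_rng(seed)
    grade = np.concatenate([np.full(n, g) for g, n in enumerate(sizes)])
    rs = []
    for _ in range(n_reps):
        values = np.concatenate(
            [
                _truncated_normal(rng, mu, sd, 0.0, 100.0, n)
                for (mu, sd), n in zip(params_by_grade, sizes)
            ]
        )
        rs.append(spearman(grade, values).r)
    return float(np.mean(rs))


def mean_risk_group_auc(cohort: str = "training", n_reps: int = 200, seed: int = 0) -> float:
    """Mean AUC of CTRV at -250 HU separating the two risk groups.

    Replicates draw the low- and high-risk groups from truncated normals
    with the reported group parameters and compute the Mann-Whitney AUC
    with high risk as the positive class.
    """
    (n_lo, mu_lo, sd_lo), (n_hi, mu_hi, sd_hi) = RISK_GROUPS[cohort]
    rng = np.random.default_rng(seed)
    labels = np.r_[np.zeros(n_lo, int), np.ones(n_hi, int)]
    aucs = []
    for _ in range(n_reps):
        scores = np.concatenate(
            [
                _truncated_normal(rng, mu_lo, sd_lo, 0.0, 100.0, n_lo),
                _truncated_normal(rng, mu_hi, sd_hi, 0.0, 100.0, n_hi),
            ]
        )
        aucs.append(auc_mw(scores, labels))
    return float(np.mean(aucs))


def sweep_winner_rate(
    target_threshold: float = -250.0, n_reps: int = 40, seed: int = 0
) -> float:
    """Fraction of generated training cohorts whose threshold sweep selects
    ``target_threshold``.

    Each replicate generates a full training cohort from the calibrated
    mixture generator and runs the Spearman threshold sweep.
    """
    spec = default_training_spec()
    wins = 0
    for rep in range(n_reps):
        cohort = sample_cohort(spec, seed=seed + rep)
        if select_threshold(cohort).selected_threshold == target_threshold:
            wins += 1
    return wins / n_reps
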