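"""Univariable screening and multivariable logistic risk models.

The modelling strategy mirrors common radiology practice: candidate
predictors are screened by two-group tests (Mann-Whitney U for continuous,
Fisher's exact for binary features) at alpha = 0.05, the survivors enter a
plain maximum-likelihood logistic regression, and backward stepwise
elimination removes terms by likelihood-ratio test at alpha_remove = 0.10
(the backward-LR convention of mainstream statistical software).
Predictors enter untransformed, so odds ratios are per unit (per mm,
per percentage point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .stats import fisher_exact, mann_whitney_u

__all__ = [
    "LogisticModel",
    "ScreenResult",
    "univariable_screen",
    "fit_logistic",
    "backward_eliminate",
    "predict_prob",
    "odds_ratios",
]

_SEPARATION_COEF = 15.0  # |log-odds| beyond this flags quasi-separation


@dataclass
class LogisticModel:
    """A fitted (or externally specified) logistic regression.

    ``covariance`` is the (p+1) x (p+1) inverse observed information with
    the intercept first; it is None for models built directly from
    published coefficients.
    """

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    covariance: np.ndarray | None = None
    log_likelihood: float | None = None
    n_obs: int | None = None
    probability_cutoff: float | None = None
    flagged: bool = False
    notes: list[str] = field(default_factory=list)

    @classmethod
    def from_coefficients(cls, intercept: float, coefficients: dict[str, float],
                          probability_cutoff: float | None = None) -> "LogisticModel":
        """Build a model from externally reported intercept/coefficients."""
        return cls(
            feature_names=list(coefficients),
            coefficients=np.array(list(coefficients.values()), dtype=float),
            intercept=float(intercept),
            probability_cutoff=probability_cutoff,
        )

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.coefficients])


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of one univariable group-comparison test."""

    feature: str
    test: str  # "mann-whitney" or "fisher-exact"
    p: float
    selected: bool


def univariable_screen(
    cohort: pd.DataFrame,
    features: list[str],
    outcome: str = "high_risk",
    alpha: float = 0.05,
) -> list[ScreenResult]:
    """Screen candidate predictors by low-risk vs high-risk comparison.

    Binary features (values within {0, 1}) are tested by Fisher's exact
    test on the 2x2 table; all other features by Mann-Whitney U.  A feature
    is selected when p < alpha.
    """
    y = cohort[outcome].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must have both classes present")
    results = []
    for name in features:
        x = cohort[name].to_numpy(dtype=float)
        if set(np.unique(x)) <= {0.0, 1.0}:
            table = np.array(
                [
                    [np.sum((x == 0) & (y == 0)), np.sum((x == 0) & (y == 1))],
                    [np.sum((x == 1) & (y == 0)), np.sum((x == 1) & (y == 1))],
                ]
            )
            p = fisher_exact(table)
            test = "fisher-exact"
        else:
            _, p = mann_whitney_u(x[y == 1], x[y == 0])
            test = "mann-whitney"
        results.append(ScreenResult(name, test, float(p), bool(p < alpha)))
    return results


def fit_logistic(X: pd.DataFrame, y, feature_names: list[str] | None = None) -> LogisticModel:
    """Maximum-likelihood logistic fit (Newton iterations via statsmodels).

    Quasi-separation (non-convergence or any |coefficient| > 15) is
    detected and reported through the ``flagged`` attribute rather than by
    penalising the fit.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xmat = X.to_numpy(dtype=float)
    else:
        Xmat = np.asarray(X, dtype=float)
        names = feature_names or [f"x{i}" for i in range(Xmat.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xmat.shape
    if n <= p + 1:
        raise ValueError(f"need more observations ({n}) than parameters ({p + 1})")
    if any(np.ptp(Xmat[:, j]) == 0 for j in range(p)):
        raise ValueError("constant feature column; only the intercept may be constant")

    design = sm.add_constant(Xmat, has_constant="add")
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=False, maxiter=100, tol=1e-8)
            converged = bool(res.mle_retvals.get("converged", True))
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            # quasi-separation: Newton's Hessian became singular; fall back
            # to IRLS, which completes with (diverging) finite estimates
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
            converged = False
            fallback = True

    params = np.asarray(res.params)
    flagged = bool(fallback or not converged or np.any(np.abs(params) > _SEPARATION_COEF))
    model = LogisticModel(
        feature_names=names,
        coefficients=params[1:],
        intercept=float(params[0]),
        covariance=np.asarray(res.cov_params()),
        log_likelihood=float(res.llf),
        n_obs=n,
        flagged=flagged,
    )
    if flagged:
        model.notes.append("possible separation: fit did not converge or coefficients diverged")
    return model


def backward_eliminate(
    model: LogisticModel,
    X: pd.DataFrame,
    y,
    alpha_remove: float = 0.10,
) -> LogisticModel:
    """Backward stepwise elimination by likelihood-ratio removal tests.

    Each round refits the model without each remaining term; the term whose
    removal test has the largest p >= alpha_remove is dropped, until every
    retained term has removal p < alpha_remove.  Removing everything leaves
    an intercept-only model (returned with a warning).
    """
    X = pd.DataFrame(X).copy()
    y = np.asarray(y, dtype=float)
    current = model
    kept = list(current.feature_names)
    while kept:
        worst_p, worst_j = -1.0, None
        for j, name in enumerate(kept):
            reduced_names = [f for f in kept if f != name]
            if reduced_names:
                reduced = fit_logistic(X[reduced_names], y)
                ll0 = reduced.log_likelihood
            else:
                p_hat = y.mean()
                ll0 = float(np.sum(y * np.log(p_hat) + (1 - y) * np.log1p(-p_hat)))
            lr = 2.0 * (current.log_likelihood - ll0)
            p_val = float(chi2.sf(max(lr, 0.0), df=1))
            if p_val > worst_p:
                worst_p, worst_j = p_val, j
        if worst_p < alpha_remove:
            break
        kept.pop(worst_j)
        if not kept:
            break
        current = fit_logistic(X[kept], y)
    if not kept:
        warnings.warn("all terms eliminated: returning intercept-only model")
        p_hat = y.mean()
        return LogisticModel(
            feature_names=[],
            coefficients=np.empty(0),
            intercept=float(np.log(p_hat / (1 - p_hat))),
            log_likelihood=float(np.sum(y * np.log(p_hat) + (1 - y) * np.log1p(-p_hat))),
            n_obs=len(y),
            notes=["intercept-only model after elimination"],
        )
    return current


def predict_prob(model: LogisticModel, features) -> np.ndarray | float:
    """Predicted probability 1 / (1 + exp(-(intercept + sum coef * x))).

    ``features`` may be a mapping, a DataFrame, or an array in the model's
    feature order.  A missing feature raises a KeyError naming it.
    """
    if isinstance(features, dict):
        features = pd.DataFrame([features])
        scalar = True
    elif isinstance(features, pd.Series):
        features = features.to_frame().T
        scalar = True
    else:
        scalar = False
    if isinstance(features, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in features.columns]
        if missing:
            raise KeyError(f"missing feature(s): {', '.join(missing)}")
        Xmat = features[model.feature_names].to_numpy(dtype=float)
    else:
        Xmat = np.atleast_2d(np.asarray(features, dtype=float))
    eta = model.intercept + Xmat @ model.coefficients
    prob = 1.0 / (1.0 + np.exp(-eta))
    return float(prob[0]) if scalar else prob


def odds_ratios(model: LogisticModel, z: float = 1.959964) -> pd.DataFrame:
    """Per-feature odds ratios with Wald 95% confidence intervals.

    OR = exp(coef); CI = exp(coef +/- z * SE).  Models without a covariance
    matrix (built from published coefficients) report NaN intervals.
    """
    if model.covariance is not None:
        se = np.sqrt(np.diag(model.covariance))[1:]
    else:
        se = np.full(len(model.feature_names), np.nan)
    coef = model.coefficients
    from scipy.stats import norm

    with np.errstate(invalid="ignore", divide="ignore"):
        wald_p = 2 * norm.sf(np.abs(coef / se))
    return pd.DataFrame(
        {
            "feature": model.feature_names,
            "coefficient": coef,
            "odds_ratio": np.exp(coef),
            "or_ci_low": np.exp(coef - z * se),
            "or_ci_high": np.exp(coef + z * se),
            "wald_p": wald_p,
        }
    )
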