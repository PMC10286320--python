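"""End-to-end analysis: cohorts -> threshold selection -> models -> report.

The stages, in order:

1. cohort acquisition (synthetic generation, or a feature table quantified
   from real images);
2. per-grade summary of every characteristic with group tests and Spearman
   correlation against grade;
3. threshold sweep on the training cohort: Spearman correlation of CTRV
   with grade at every threshold, selection of the argmax threshold, and
   Z tests of the winner against every competing feature;
4. low-risk vs high-risk comparisons in both cohorts;
5. univariable screening and semantic / 2D / 3D logistic models with
   backward stepwise elimination;
6. ROC evaluation of the three models in both cohorts, with paired DeLong
   comparisons against the 3D model and Hosmer-Lemeshow calibration.

All randomness derives from a single global seed, so a rerun of
``run_analysis`` with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import delong_test, evaluate_scores
from .models import (
    LogisticModel,
    backward_eliminate,
    fit_logistic,
    odds_ratios,
    predict_prob,
    univariable_screen,
)
from .stats import (
    CorrelationComparison,
    CorrelationResult,
    compare_correlations,
    fisher_exact,
    kruskal_wallis,
    mann_whitney_u,
    spearman,
)
from .synthetic import (
    SEMANTIC_FEATURES,
    default_testing_spec,
    default_training_spec,
    sample_cohort,
)
from .types import DEFAULT_THRESHOLDS, threshold_column

__all__ = [
    "AnalysisConfig",
    "ThresholdSweepResult",
    "select_threshold",
    "grade_summary_table",
    "risk_group_table",
    "build_models",
    "evaluate_models",
    "run_analysis",
]

CONTINUOUS_MEASURES = ("diameter_mm", "ctr_percent", "volume_mm3", "mean_attenuation_hu")


@dataclass
class AnalysisConfig:
    """Everything a full run needs; loadable from YAML or JSON."""

    mode: str = "synthetic"  # "synthetic" or "real"
    seed: int = 0
    output_dir: str = "results"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    corr_test: str = "steiger"  # "steiger" (dependent) or "fisher" (independent)
    alpha_screen: float = 0.05
    alpha_remove: float = 0.10
    hl_groups: int = 10
    ci_method: str = "delong"
    solid_display_threshold: float = -160.0
    # synthetic mode
    synthetic: dict = field(default_factory=dict)  # optional CohortSpec overrides
    # real mode: feature tables (already quantified) or NIfTI manifests
    training_table: str | None = None
    testing_table: str | None = None
    training_manifest: str | None = None
    testing_manifest: str | None = None

    def __post_init__(self):
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("threshold grid must be strictly increasing")
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls(**data)


@dataclass
class ThresholdSweepResult:
    """Outcome of the attenuation-threshold selection stage."""

    correlations: dict[float, CorrelationResult]
    selected_threshold: float
    comparisons: dict[str, CorrelationComparison]
    tie: bool = False

    @property
    def selected_correlation(self) -> CorrelationResult:
        return self.correlations[self.selected_threshold]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, c in self.correlations.items():
            comp = self.comparisons.get(threshold_column(t))
            rows.append(
                {
                    "threshold_hu": t,
                    "spearman_r": c.r,
                    "spearman_p": c.p,
                    "selected": t == self.selected_threshold,
                    "z_vs_selected": comp.z if comp else np.nan,
                    "p_vs_selected": comp.p if comp else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _corr_method(corr_test: str) -> str:
    return {"steiger": "dependent-steiger", "fisher": "independent-fisher"}[corr_test]


def select_threshold(
    training: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    grade_col: str = "grade",
    corr_test: str = "steiger",
    extra_features: list[str] | None = None,
) -> ThresholdSweepResult:
    """Pick the attenuation threshold whose CTRV correlates best with grade.

    Spearman correlation is computed per threshold; the argmax wins, ties
    going to the lower (more inclusive) threshold with a warning.  The
    winner is then compared against every other threshold and every
    ``extra_features`` column with a correlation-difference Z test
    (dependent Steiger by default; naive independent Fisher via
    ``corr_test='fisher'``).
    """
    grade = training[grade_col]
    if grade.nunique() < 3:
        raise ValueError("threshold selection requires >= 3 grades represented")
    method = _corr_method(corr_test)
    correlations: dict[float, CorrelationResult] = {}
    for t in thresholds:
        col = threshold_column(t)
        res = spearman(grade, training[col])
        if not res.valid:
            warnings.warn(f"CTRV column {col} is constant; excluded from selection")
            continue
        correlations[t] = res
    if not correlations:
        raise ValueError("no usable CTRV column in the threshold grid")
    best_r = max(c.r for c in correlations.values())
    candidates = [t for t, c in correlations.items() if c.r >= best_r - 1e-12]
    tie = len(candidates) > 1
    if tie:
        warnings.warn(
            f"tie among thresholds {candidates}; selecting the lowest (most inclusive)"
        )
    selected = min(candidates)
    winner = correlations[selected]
    winner_col = threshold_column(selected)

    comparisons: dict[str, CorrelationComparison] = {}
    rivals = [threshold_column(t) for t in correlations if t != selected]
    rivals += list(extra_features or [])
    for col in rivals:
        rival = spearman(grade, training[col])
        if not rival.valid:
            warnings.warn(f"column {col} is constant; comparison skipped")
            continue
        r_ab = spearman(training[winner_col], training[col]).r
        comparisons[col] = compare_correlations(winner, rival, r_ab=r_ab, method=method)
    return ThresholdSweepResult(correlations, selected, comparisons, tie)


def _is_binary(series: pd.Series) -> bool:
    return set(pd.unique(series.dropna())) <= {0, 1, True, False}


def grade_summary_table(cohort: pd.DataFrame, thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Per-grade characteristic summary with group tests and grade correlation.

    Continuous measures are summarised as mean +/- SD per grade and tested
    with Kruskal-Wallis; binary features are summarised as yes-counts and
    tested with Fisher's exact test; every characteristic also gets a
    Spearman correlation against the ordinal grade.
    """
    grades = sorted(cohort["grade"].unique())
    characteristics = (
        list(SEMANTIC_FEATURES)
        + list(CONTINUOUS_MEASURES)
        + [threshold_column(t) for t in thresholds]
    )
    rows = []
    for name in characteristics:
        if name not in cohort.columns:
            continue
        x = cohort[name]
        row: dict = {"characteristic": name}
        if _is_binary(x):
            counts = [
                int(((cohort["grade"] == g) & (x == 1)).sum()) for g in grades
            ]
            totals = [int((cohort["grade"] == g).sum()) for g in grades]
            for g, c, t in zip(grades, counts, totals):
                row[f"grade{g}"] = f"{c}/{t}"
            table = np.array(
                [[t - c for c, t in zip(counts, totals)], counts]
            )
            row["p_group"] = fisher_exact(table)
            row["test"] = "fisher-exact"
        else:
            for g in grades:
                vals = x[cohort["grade"] == g]
                row[f"grade{g}"] = f"{vals.mean():.1f} +/- {vals.std(ddof=1):.1f}"
            _, row["p_group"] = kruskal_wallis(
                [x[cohort["grade"] == g].to_numpy() for g in grades]
            )
            row["test"] = "kruskal-wallis"
        corr = spearman(cohort["grade"], x.astype(float))
        row["spearman_r"], row["spearman_p"] = corr.r, corr.p
        rows.append(row)
    return pd.DataFrame(rows)


def risk_group_table(
    cohort: pd.DataFrame, ctrv_col: str, cohort_name: str = "training"
) -> pd.DataFrame:
    """Low-risk vs high-risk comparison of every candidate characteristic."""
    y = cohort["high_risk"].to_numpy(dtype=int)
    rows = []
    for name in list(SEMANTIC_FEATURES) + list(CONTINUOUS_MEASURES) + [ctrv_col]:
        x = cohort[name]
        row: dict = {"cohort": cohort_name, "characteristic": name}
        if _is_binary(x):
            xb = x.to_numpy(dtype=int)
            table = np.array(
                [
                    [np.sum((xb == 0) & (y == 0)), np.sum((xb == 0) & (y == 1))],
                    [np.sum((xb == 1) & (y == 0)), np.sum((xb == 1) & (y == 1))],
                ]
            )
            row["low_risk"] = f"{table[1, 0]}/{table[:, 0].sum()}"
            row["high_risk"] = f"{table[1, 1]}/{table[:, 1].sum()}"
            row["p"] = fisher_exact(table)
            row["test"] = "fisher-exact"
        else:
            lo, hi = x[y == 0], x[y == 1]
            row["low_risk"] = f"{lo.mean():.1f} +/- {lo.std(ddof=1):.1f}"
            row["high_risk"] = f"{hi.mean():.1f} +/- {hi.std(ddof=1):.1f}"
            _, row["p"] = mann_whitney_u(hi.to_numpy(), lo.to_numpy())
            row["test"] = "mann-whitney"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class FittedFamily:
    """One model family (semantic / 2D / 3D) after screening and elimination."""

    name: str
    screened: list
    model: LogisticModel
    score_column: str | None  # raw-marker scoring when a single term survives


def build_models(
    training: pd.DataFrame,
    ctrv_col: str,
    alpha_screen: float = 0.05,
    alpha_remove: float = 0.10,
) -> dict[str, FittedFamily]:
    """Screen, fit and prune the semantic, 2D and 3D model families.

    Within each family, features surviving the univariable screen enter a
    multivariable logistic fit followed by backward LR elimination.  A
    family reduced to a single predictor is additionally scored by the raw
    marker (rank-equivalent to the fitted probability), mirroring the use
    of CTRV itself as the 3D classifier.
    """
    families = {
        "semantic": list(SEMANTIC_FEATURES),
        "2d": ["diameter_mm", "ctr_percent"],
        "3d": ["volume_mm3", "mean_attenuation_hu", ctrv_col],
    }
    out: dict[str, FittedFamily] = {}
    y = training["high_risk"]
    for fam, candidates in families.items():
        screened = univariable_screen(training, candidates, alpha=alpha_screen)
        selected = [s.feature for s in screened if s.selected]
        if not selected:
            warnings.warn(f"{fam}: no feature passed the univariable screen")
            out[fam] = FittedFamily(fam, screened, None, None)
            continue
        full = fit_logistic(training[selected], y)
        final = backward_eliminate(full, training[selected], y, alpha_remove=alpha_remove)
        score_col = final.feature_names[0] if len(final.feature_names) == 1 else None
        out[fam] = FittedFamily(fam, screened, final, score_col)
    return out


def family_scores(family: FittedFamily, cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(scores, probabilities) of one family on one cohort.

    Single-predictor families score by the raw marker; the fitted
    probabilities (a monotone transform with identical ROC) are still used
    for calibration testing.
    """
    prob = predict_prob(family.model, cohort)
    if family.score_column is not None and family.model.coefficients[0] > 0:
        return cohort[family.score_column].to_numpy(dtype=float), prob
    return prob, prob


def evaluate_models(
    fitted: dict[str, FittedFamily],
    cohorts: dict[str, pd.DataFrame],
    reference: str = "3d",
    ci_method: str = "delong",
) -> pd.DataFrame:
    """Table of AUC / sensitivity / specificity per model and cohort.

    Each family's cutoff is set by Youden's index on its own scores in each
    cohort; AUCs are compared against the ``reference`` family with the
    paired DeLong test.
    """
    rows = []
    for cohort_name, cohort in cohorts.items():
        labels = cohort["high_risk"].to_numpy(dtype=int)
        ref_scores, _ = family_scores(fitted[reference], cohort)
        for fam, family in fitted.items():
            if family.model is None:
                continue
            scores, probs = family_scores(family, cohort)
            ev = evaluate_scores(scores, labels, probabilities=probs, ci_method=ci_method)
            if fam == reference:
                z = p = np.nan
            else:
                comp = delong_test(scores, ref_scores, labels)
                z, p = comp.z, comp.p
            rows.append(
                {
                    "cohort": cohort_name,
                    "model": fam,
                    "auc": ev.auc,
                    "auc_ci_low": ev.auc_ci_low,
                    "auc_ci_high": ev.auc_ci_high,
                    "cutoff": ev.cutoff,
                    "sensitivity": ev.sensitivity,
                    "sens_ci_low": ev.sensitivity_ci[0],
                    "sens_ci_high": ev.sensitivity_ci[1],
                    "specificity": ev.specificity,
                    "spec_ci_low": ev.specificity_ci[0],
                    "spec_ci_high": ev.specificity_ci[1],
                    "n_pos": ev.n_pos,
                    "n_neg": ev.n_neg,
                    "delong_z_vs_ref": z,
                    "delong_p_vs_ref": p,
                    "hl_chi2": ev.hosmer_lemeshow_chi2,
                    "hl_p": ev.hosmer_lemeshow_p,
                }
            )
    return pd.DataFrame(rows)


def _acquire_cohorts(config: AnalysisConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.mode == "synthetic":
        train_spec = default_training_spec()
        test_spec = default_testing_spec()
        overrides = dict(config.synthetic)
        if "n_per_grade_training" in overrides:
            train_spec = dataclasses.replace(
                train_spec, n_per_grade=tuple(overrides["n_per_grade_training"])
            )
        if "n_per_grade_testing" in overrides:
            test_spec = dataclasses.replace(
                test_spec, n_per_grade=tuple(overrides["n_per_grade_testing"])
            )
        train = sample_cohort(train_spec, seed=config.seed)
        test = sample_cohort(test_spec, seed=config.seed + 1_000_003)
        return train, test
    # real mode: feature tables directly, or NIfTI manifests to quantify
    from .io import quantify_manifest

    def load(table, manifest):
        if table is not None:
            path = Path(table)
            if not path.exists():
                raise FileNotFoundError(f"feature table not found: {path}")
            return pd.read_csv(path, float_precision="round_trip")
        if manifest is None:
            raise ValueError("real mode requires a feature table or a manifest per cohort")
        return quantify_manifest(manifest, thresholds=config.thresholds)

    return (
        load(config.training_table, config.training_manifest),
        load(config.testing_table, config.testing_manifest),
    )


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute the full pipeline and write the report bundle to disk.

    Returns a dict with the in-memory results; CSV/JSON artifacts are
    written under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        training, testing = _acquire_cohorts(config)
        for name, cohort in (("training", training), ("testing", testing)):
            if cohort["grade"].nunique() < 2:
                raise ValueError(f"{name} cohort is degenerate (single grade)")

        table1 = grade_summary_table(training, config.thresholds)
        sweep = select_threshold(
            training,
            thresholds=config.thresholds,
            corr_test=config.corr_test,
            extra_features=[
                f for f in (*SEMANTIC_FEATURES, *CONTINUOUS_MEASURES)
                if spearman(training["grade"], training[f].astype(float)).valid
            ],
        )
        ctrv_col = threshold_column(sweep.selected_threshold)
        # extra-study transparency output: the sweep re-run on the testing cohort
        testing_sweep = select_threshold(
            testing, thresholds=config.thresholds, corr_test=config.corr_test
        )
        table2 = pd.concat(
            [
                risk_group_table(training, ctrv_col, "training"),
                risk_group_table(testing, ctrv_col, "testing"),
            ],
            ignore_index=True,
        )
        fitted = build_models(
            training, ctrv_col, alpha_screen=config.alpha_screen,
            alpha_remove=config.alpha_remove,
        )
        table3 = pd.concat(
            [
                odds_ratios(f.model).assign(model=name)
                for name, f in fitted.items()
                if f.model is not None and f.model.feature_names
            ],
            ignore_index=True,
        )
        table4 = evaluate_models(
            fitted,
            {"training": training, "testing": testing},
            ci_method=config.ci_method,
        )
        captured = sorted({str(w.message) for w in caught})

    # %.17g keeps the cohort tables bit-exact under a CSV round trip, so
    # real mode re-fed with these files reproduces the report byte for byte
    training.to_csv(out / "training_cohort.csv", index=False, float_format="%.17g")
    testing.to_csv(out / "testing_cohort.csv", index=False, float_format="%.17g")
    table1.to_csv(out / "table1.csv", index=False)
    sweep.to_frame().to_csv(out / "sweep.csv", index=False)
    testing_sweep.to_frame().to_csv(out / "sweep_testing_extra.csv", index=False)
    table2.to_csv(out / "table2.csv", index=False)
    table3.to_csv(out / "table3.csv", index=False)
    table4.to_csv(out / "table4.csv", index=False)

    from .evaluation import roc_curve_points

    for cohort_name, cohort in (("training", training), ("testing", testing)):
        labels = cohort["high_risk"].to_numpy(dtype=int)
        for fam, family in fitted.items():
            if family.model is None:
                continue
            scores, _ = family_scores(family, cohort)
            pts = roc_curve_points(scores, labels)
            pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(
                out / f"roc_{cohort_name}_{fam}.csv", index=False
            )

    models_json = {
        name: {
            "features": f.model.feature_names,
            "intercept": f.model.intercept,
            "coefficients": dict(zip(f.model.feature_names, f.model.coefficients.tolist())),
            "score_column": f.score_column,
            "flagged": f.model.flagged,
        }
        for name, f in fitted.items()
        if f.model is not None
    }
    (out / "models.json").write_text(json.dumps(models_json, indent=2, sort_keys=True))

    import scipy

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "seed": config.seed,
        "selected_threshold_hu": sweep.selected_threshold,
        "warnings": captured,
        "versions": {
            "psnquant": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "training": training,
        "testing": testing,
        "table1": table1,
        "sweep": sweep,
        "testing_sweep": testing_sweep,
        "table2": table2,
        "fitted": fitted,
        "table3": table3,
        "table4": table4,
    }
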