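"""Cohort-level statistical validation of the scoring system.

Mirrors the original validation battery: Kruskal-Wallis (ordinal) and
Pearson chi-square (nominal) tests across the four Simpson-grade groups,
adjusted odds ratios from a proportional-odds ordinal logistic regression,
Spearman rank correlations against resection grade and against the 4-level
postoperative outcome, and linear-discriminant classification accuracy.

The battery is exposed both as free functions and as a
``CohortScoreModel`` / ``CohortScoreResults`` pair: build the model from a
:class:`~sphenoscore.cohorts.CohortTable`, call :meth:`CohortScoreModel.fit`,
and read estimates, intervals and diagnostics off the results object or its
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from sklearn.neighbors import NearestCentroid
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .config import PipelineConfig
from .cohorts import CohortTable

ORDINAL_VARS = ("volume_grade", "arterial_score", "total_score")
NOMINAL_VARS = ("cs_involved", "bone_invaded")
PREDICTOR_VARS = ("volume_grade", "arterial_score", "cs_involved", "bone_invaded")


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties.

    The p-value is the standard large-sample t approximation
    (``t = rs * sqrt((n-2)/(1-rs^2))`` on n-2 degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def descriptive_summary(cohort: CohortTable) -> dict:
    """Mean +/- sample SD of the total score and count/percent tables.

    SD uses the n-1 denominator; percentages are rounded to one decimal.
    """
    df = cohort.data
    out = {
        "n": len(df),
        "score_mean": float(df["total_score"].mean()),
        "score_sd": float(df["total_score"].std(ddof=1)),
        "counts": {},
    }
    for var in ("volume_grade", "arterial_score", "total_score", "cs_involved", "bone_invaded"):
        counts = df[var].value_counts().sort_index()
        out["counts"][var] = {
            level: (int(n), round(100.0 * n / len(df), 1)) for level, n in counts.items()
        }
    return out


def _simpson_groups(cohort: CohortTable, values: np.ndarray) -> list[np.ndarray]:
    grades = cohort.data["simpson_grade"].to_numpy()
    groups = []
    for g in (1, 2, 3, 4):
        sel = values[grades == g]
        if len(sel) == 0:
            warnings.warn(f"Simpson grade {g} group is empty; excluded from test", stacklevel=3)
        else:
            groups.append(sel)
    return groups


def univariate_tests(cohort: CohortTable) -> dict[str, float]:
    """Per-variable p-values across the Simpson-grade groups.

    Kruskal-Wallis (tie-corrected) for ordinal variables; Pearson
    chi-square without continuity correction for nominal variables.
    """
    if not cohort.has_simpson:
        raise ValueError("cohort lacks simpson_grade; univariate tests need it")
    df = cohort.data
    out: dict[str, float] = {}
    for var in ORDINAL_VARS:
        values = df[var].to_numpy(dtype=float)
        if np.ptp(values) == 0:
            out[var] = 1.0
            continue
        groups = _simpson_groups(cohort, values)
        stat, p = sps.kruskal(*groups)
        out[var] = float(p)
    for var in NOMINAL_VARS:
        table = pd.crosstab(df[var], df["simpson_grade"])
        if table.shape[0] < 2:
            out[var] = 1.0
            continue
        chi2, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
        out[var] = float(p)
    return out


def adjusted_odds_ratios(
    cohort: CohortTable,
    predictors: tuple[str, ...] = PREDICTOR_VARS,
    family: str = "ordinal",
) -> dict[str, dict]:
    """Adjusted ORs with Wald 95% CIs for the Simpson grade.

    ``family="ordinal"`` (default) fits a proportional-odds cumulative-logit
    regression of the grade on all predictors jointly, one common OR per
    predictor. ``family="binary"`` dichotomizes the outcome (grade I-II vs
    III-IV) and fits ordinary logistic regression. Non-convergence or
    quasi-separation is flagged per variable, never silent.
    """
    if not cohort.has_simpson:
        raise ValueError("cohort lacks simpson_grade; odds ratios need it")
    df = cohort.data
    grades = df["simpson_grade"].astype(int)
    if grades.nunique() < 2:
        raise ValueError("simpson_grade has a single level; odds ratios undefined")
    X = df[list(predictors)].astype(float)

    if family == "ordinal":
        endog = pd.Categorical(grades, categories=sorted(grades.unique()), ordered=True)
        model = OrderedModel(endog, X, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", maxiter=500, disp=False)
        converged = bool(res.mle_retvals.get("converged", True))
        params = res.params[: len(predictors)]
        bse = res.bse[: len(predictors)]
    elif family == "binary":
        endog = (grades >= 3).astype(int)
        if endog.nunique() < 2:
            raise ValueError("dichotomized outcome has a single level")
        model = sm.Logit(endog, sm.add_constant(X))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=False, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        params = res.params[list(predictors)]
        bse = res.bse[list(predictors)]
    else:
        raise ValueError("family must be 'ordinal' or 'binary'")

    z = sps.norm.ppf(0.975)
    out = {}
    for i, var in enumerate(predictors):
        coef = float(np.asarray(params)[i])
        se = float(np.asarray(bse)[i])
        flagged = (not converged) or not np.isfinite(se) or se > 10.0
        out[var] = {
            "or": float(np.exp(coef)),
            "ci_low": float(np.exp(coef - z * se)),
            "ci_high": float(np.exp(coef + z * se)),
            "flagged": bool(flagged),
        }
    return out


def discriminant_accuracy(
    cohort: CohortTable,
    predictors: tuple[str, ...] = ("total_score",),
    mode: str = "resubstitution",
) -> float:
    """Linear-discriminant classification accuracy for the Simpson grade, percent.

    Empirical class priors; resubstitution by default (accuracy on the
    records the classifier was fitted to), optional leave-one-out.
    """
    if not cohort.has_simpson:
        raise ValueError("cohort lacks simpson_grade; discriminant analysis needs it")
    df = cohort.data
    y = df["simpson_grade"].astype(int).to_numpy()
    X = df[list(predictors)].astype(float).to_numpy()
    n_classes = len(np.unique(y))
    if len(df) <= n_classes:
        raise ValueError("fewer records than classes (need more samples than grade levels)")
    lda = LinearDiscriminantAnalysis()
    try:
        if mode == "resubstitution":
            pred = lda.fit(X, y).predict(X)
        elif mode == "loo":
            pred = cross_val_predict(lda, X, y, cv=LeaveOneOut())
        else:
            raise ValueError("mode must be 'resubstitution' or 'loo'")
    except (np.linalg.LinAlgError, ValueError, IndexError) as exc:
        if mode not in ("resubstitution", "loo"):
            raise
        # zero within-class scatter (perfectly separated classes) breaks the
        # SVD solver; the corresponding LDA limit is the nearest class centroid
        warnings.warn(
            f"singular within-class covariance ({exc}); using nearest-centroid limit",
            stacklevel=2,
        )
        clf = NearestCentroid()
        if mode == "resubstitution":
            pred = clf.fit(X, y).predict(X)
        else:
            pred = cross_val_predict(clf, X, y, cv=LeaveOneOut())
    return round(100.0 * float(np.mean(pred == y)), 2)


def score_outcome_correlation(cohort: CohortTable) -> tuple[float, float]:
    """Spearman correlation between the total score and the 0-3 outcome grade."""
    if not cohort.has_outcome:
        raise ValueError("cohort lacks outcome_grade")
    return spearman_rho(
        cohort.data["total_score"].to_numpy(), cohort.data["outcome_grade"].to_numpy()
    )


@dataclass
class StatsReport:
    """Everything the validation battery computes for one cohort."""

    n: int
    score_mean: float
    score_sd: float
    univariate_p: dict[str, float] = field(default_factory=dict)
    adjusted_or: dict[str, dict] = field(default_factory=dict)
    spearman_vs_grade: dict[str, tuple[float, float]] = field(default_factory=dict)
    score_grade_rs: tuple[float, float] | None = None
    score_outcome_rs: tuple[float, float] | None = None
    discriminant_accuracy_pct: float | None = None


class CohortScoreModel:
    """Validation model for a scored cohort.

    Parameters
    ----------
    cohort : CohortTable
        Patient rows; the grade-dependent parts of the battery run only when
        ``simpson_grade`` is present, the outcome correlation only when
        ``outcome_grade`` is.
    config : PipelineConfig, optional
        Supplies the regression family and discriminant mode.

    Examples
    --------
    >>> from sphenoscore import CohortModel, simulate_cohort, CohortScoreModel
    >>> res = CohortScoreModel(simulate_cohort(CohortModel(n_patients=200, seed=7))).fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(self, cohort: CohortTable, config: PipelineConfig | None = None):
        self.cohort = cohort
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: PipelineConfig | None = None):
        return cls(CohortTable(data=df, provenance="user"), config)

    def fit(self) -> "CohortScoreResults":
        cohort = self.cohort
        desc = descriptive_summary(cohort)
        report = StatsReport(
            n=desc["n"], score_mean=desc["score_mean"], score_sd=desc["score_sd"]
        )
        if cohort.has_simpson:
            report.univariate_p = univariate_tests(cohort)
            report.adjusted_or = adjusted_odds_ratios(
                cohort, family=self.config.regression_family
            )
            grade = cohort.data["simpson_grade"].to_numpy()
            for var in PREDICTOR_VARS:
                report.spearman_vs_grade[var] = spearman_rho(
                    cohort.data[var].astype(float).to_numpy(), grade
                )
            report.score_grade_rs = spearman_rho(
                cohort.data["total_score"].to_numpy(), grade
            )
            report.discriminant_accuracy_pct = discriminant_accuracy(
                cohort, mode=self.config.discriminant_mode
            )
        if cohort.has_outcome:
            report.score_outcome_rs = score_outcome_correlation(cohort)
        return CohortScoreResults(self, report, desc)


class CohortScoreResults:
    """Fitted validation results; see :meth:`summary`."""

    def __init__(self, model: CohortScoreModel, report: StatsReport, descriptives: dict):
        self.model = model
        self.report = report
        self.descriptives = descriptives

    def summary(self) -> str:
        r = self.report
        lines = [
            "Cohort score validation",
            "=" * 68,
            f"n = {r.n}    score mean +/- SD = {r.score_mean:.1f} +/- {r.score_sd:.1f}",
        ]
        if r.univariate_p:
            lines.append("-" * 68)
            lines.append(f"{'parameter':<16}{'P (univar)':>12}{'adj OR (95% CI)':>24}{'Rs':>8}")
            for var in ("volume_grade", "arterial_score", "cs_involved", "bone_invaded"):
                p = r.univariate_p.get(var, float("nan"))
                orr = r.adjusted_or.get(var)
                rs = r.spearman_vs_grade.get(var, (float("nan"),))[0]
                or_txt = (
                    f"{orr['or']:.3f} ({orr['ci_low']:.3f}-{orr['ci_high']:.3f})"
                    + ("*" if orr["flagged"] else "")
                    if orr
                    else ""
                )
                lines.append(f"{var:<16}{p:>12.4f}{or_txt:>24}{rs:>8.3f}")
            lines.append("-" * 68)
            lines.append(
                f"score vs resection grade: Rs = {r.score_grade_rs[0]:.3f}"
                f" (P = {r.score_grade_rs[1]:.2g})"
            )
            lines.append(
                f"discriminant accuracy ({self.model.config.discriminant_mode}): "
                f"{r.discriminant_accuracy_pct:.2f}%"
            )
        if r.score_outcome_rs is not None:
            lines.append(
                f"score vs postoperative outcome: Rs = {r.score_outcome_rs[0]:.3f}"
                f" (P = {r.score_outcome_rs[1]:.2g})"
            )
        if any(v.get("flagged") for v in r.adjusted_or.values()):
            lines.append("* flagged: non-convergence or quasi-separation")
        return "\n".join(lines)
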