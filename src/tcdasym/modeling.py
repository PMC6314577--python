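"""Inferential stages: logistic outcome models, ROC/Youden cutoff
selection, and two-rater intraclass correlation.

Logistic models are maximum-likelihood (IRLS) with Wald 95% intervals
``exp(beta +/- 1.96*SE)``.  ROC candidate thresholds are the unique
observed scores under the strict rule ``score > threshold -> predicted
poor``; the Youden-optimal cutoff breaks ties toward the smallest
threshold (most sensitive).  The ICC is the two-way random-effects,
absolute-agreement, single-measures form, computed from the ANOVA mean
squares with an F test against zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from tcdasym.cohort import PatientRecord, dichotomize_outcome

__all__ = [
    "LogisticFit",
    "RocResult",
    "IccResult",
    "SeparationError",
    "fit_logistic",
    "univariable_screen",
    "roc_youden",
    "dichotomized_fit",
    "icc",
    "ADJUSTMENT_COVARIATES",
]

#: Fixed adjustment set for the covariate-adjusted outcome models.
ADJUSTMENT_COVARIATES = (
    "sex", "age", "nihss", "hemoglobin", "esr", "d_dimer", "time_to_tcd",
)


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist for a named predictor."""


@dataclass
class LogisticFit:
    """Logistic-regression estimates on both the log-odds and OR scales."""

    predictors: list[str]
    coefficients: np.ndarray
    std_errors: np.ndarray
    odds_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_used: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "coef": self.coefficients,
                "se": self.std_errors,
                "or": self.odds_ratios,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p_value": self.p_values,
            }
        )

    def __getitem__(self, predictor: str) -> dict[str, float]:
        i = self.predictors.index(predictor)
        return {
            "coef": float(self.coefficients[i]),
            "se": float(self.std_errors[i]),
            "or": float(self.odds_ratios[i]),
            "ci_lower": float(self.ci_lower[i]),
            "ci_upper": float(self.ci_upper[i]),
            "p_value": float(self.p_values[i]),
        }


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_value: float

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass
class IccResult:
    icc: float
    p_value: float
    model: str = "two-way random, absolute agreement, single measures"


def _design(predictors: pd.DataFrame) -> pd.DataFrame:
    x = predictors.copy()
    if "sex" in x.columns and x["sex"].dtype == object:
        x["sex"] = (x["sex"] == "male").astype(float)
    return x.astype(float)


def fit_logistic(
    outcome: Sequence[int], predictors: pd.DataFrame, maxiter: int = 200
) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome.

    An intercept is added automatically and excluded from the reported
    predictor table.  Raises :class:`SeparationError` on perfect
    separation (naming the separating predictor) and ``ValueError`` on a
    singular design (naming the collinear columns) or a constant
    predictor.
    """
    y = np.asarray(outcome, dtype=float)
    x = _design(predictors)
    if len(y) != len(x):
        raise ValueError("outcome and predictors have different lengths")
    if len(y) < 10:
        raise ValueError(f"need >= 10 observations, got {len(y)}")
    if not (set(np.unique(y)) <= {0.0, 1.0}) or len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes coded 0/1")
    constant = [c for c in x.columns if x[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant predictor(s): {constant}")
    design = sm.add_constant(x, prepend=True)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = x.corr().abs()
        collinear = sorted(
            {
                c
                for i, a in enumerate(x.columns)
                for c in (a,)
                if any(corr.iloc[i, j] > 0.999 for j in range(len(x.columns)) if j != i)
            }
        ) or list(x.columns)
        raise ValueError(f"singular design; collinear columns: {collinear}")

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=maxiter, method="newton")
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(
                f"perfect separation detected ({_separating_predictor(y, x)})"
            ) from exc
    params = np.asarray(res.params)[1:]
    se = np.asarray(res.bse)[1:]
    if not res.mle_retvals.get("converged", False) or np.any(np.abs(params) > 15):
        raise SeparationError(
            f"logistic fit did not converge ({_separating_predictor(y, x)})"
        )
    return LogisticFit(
        predictors=list(x.columns),
        coefficients=params,
        std_errors=se,
        odds_ratios=np.exp(params),
        ci_lower=np.exp(params - 1.96 * se),
        ci_upper=np.exp(params + 1.96 * se),
        p_values=np.asarray(res.pvalues)[1:],
        converged=True,
        n_used=len(y),
    )


def _separating_predictor(y: np.ndarray, x: pd.DataFrame) -> str:
    for c in x.columns:
        v = x[c].to_numpy(dtype=float)
        if v[y == 1].min() > v[y == 0].max() or v[y == 1].max() < v[y == 0].min():
            return f"separating predictor: {c}"
    return "separating predictor not identifiable from marginals"


@dataclass
class ScreenResult:
    fits: dict[str, LogisticFit] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)
    adjustment_set: list[str] = field(default_factory=list)


def univariable_screen(
    frame: pd.DataFrame,
    outcome: Sequence[int],
    variables: Sequence[str],
    alpha: float = 0.05,
    forced: Sequence[str] = ("sex", "age"),
) -> ScreenResult:
    """One single-predictor logistic fit per variable.

    Returns every fit plus the variables passing ``p < alpha``, and the
    downstream adjustment set (forced covariates first, then the
    selected ones).  Per-variable failures (zero variance, separation)
    are recorded, not raised.
    """
    result = ScreenResult()
    for var in variables:
        if var not in frame.columns:
            result.errors[var] = "variable not present"
            continue
        sub = frame[[var]].dropna()
        try:
            fit = fit_logistic(np.asarray(outcome)[sub.index], sub)
        except (ValueError, SeparationError) as exc:
            result.errors[var] = str(exc)
            continue
        result.fits[var] = fit
        if fit[var]["p_value"] < alpha:
            result.selected.append(var)
    result.adjustment_set = list(forced) + [
        v for v in result.selected if v not in forced
    ]
    return result


def roc_youden(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC over the unique observed scores with Youden-optimal cutoff.

    Classification rule: ``score > threshold`` predicts the positive
    (poor-outcome) class.  AUC by the trapezoidal rule over the implied
    ROC points; the cutoff maximizes J = sensitivity + specificity - 1,
    ties broken by the smallest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes")

    thresholds = np.unique(s)
    sens = np.array([(s[y == 1] > t).mean() for t in thresholds])
    spec = np.array([(s[y == 0] <= t).mean() for t in thresholds])

    # ROC points, including the predict-everything endpoint, sorted by FPR
    fpr = np.concatenate([[1.0], 1.0 - spec])
    tpr = np.concatenate([[1.0], sens])
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))

    j = sens + spec - 1.0
    # smallest threshold on ties (up to float noise in sens + spec)
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_cutoff=float(thresholds[best]),
        youden_value=float(j[best]),
    )


def dichotomized_fit(
    frame: pd.DataFrame,
    outcome: Sequence[int],
    cutoff: float,
    covariates: Sequence[str] = ADJUSTMENT_COVARIATES,
    asym_column: str = "overall_asym",
) -> LogisticFit:
    """Adjusted logistic fit of the indicator ``overall asymmetry > cutoff``.

    The continuous asymmetry column is replaced by a strict-inequality
    indicator named ``{asym_column}_gt_{cutoff:g}``; covariates default
    to the fixed adjustment set.
    """
    indicator_name = f"{asym_column}_gt_{cutoff:g}"
    x = frame[list(covariates)].copy()
    x[indicator_name] = (frame[asym_column] > cutoff).astype(float)
    keep = ~x.isna().any(axis=1) & frame[asym_column].notna()
    x = x.loc[keep]
    y = np.asarray(outcome)[keep.to_numpy()]
    if x[indicator_name].nunique() <= 1:
        raise ValueError(
            f"indicator {indicator_name!r} is constant after filtering"
        )
    return fit_logistic(y, x)


def icc(ratings: Sequence[Sequence[float]]) -> IccResult:
    """Two-way random, absolute-agreement, single-measures ICC for 2 raters.

    Computed from the ANOVA mean squares
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n)`` with the
    F test ``MSR/MSE`` against ICC = 0.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("ratings must be an (n_subjects, 2) matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError("need >= 3 subjects")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if msr == 0.0:
        raise ValueError("ICC undefined: zero between-subject variance")

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = (msr - mse) / denom
    if mse == 0.0:
        p = 0.0
    else:
        f = msr / mse
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return IccResult(icc=float(value), p_value=p)


def outcome_vector(records: Sequence[PatientRecord], threshold: int = 3) -> np.ndarray:
    """Binary poor-outcome vector for a cohort at the given mRS threshold."""
    return np.array(
        [int(dichotomize_outcome(r.mrs_3mo, threshold).poor) for r in records]
    )
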