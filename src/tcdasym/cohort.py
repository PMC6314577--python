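"""Patient-level data model, CSV I/O, outcome dichotomization, and the
descriptive two-group comparison machinery.

Conventions fixed here because they are part of the output contract:
medians/IQRs use the linear-interpolation quantile rule; the two-sided
Fisher p-value is the "small-p" sum over tables at least as improbable
as the observed one; chi-square is Pearson without continuity correction
unless requested; the ``auto`` continuous-test router runs a
Shapiro-Wilk screen at alpha = 0.05 in both groups and falls back to the
Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tcdasym.hemodynamics import McaIndexProfile, Side, VelocitySample, patient_profile

__all__ = [
    "PatientRecord",
    "OutcomeLabel",
    "GroupComparison",
    "dichotomize_outcome",
    "compare_continuous",
    "compare_categorical",
    "descriptive_table",
    "load_patients",
    "load_velocity_samples",
    "save_patients",
    "save_velocity_samples",
    "profiles_frame",
    "RISK_FLAGS",
    "PATIENT_COLUMNS",
    "VELOCITY_COLUMNS",
]

RISK_FLAGS = ("htn", "dm", "chol", "smoker", "cad", "pad")

PATIENT_COLUMNS = [
    "patient_id", "age", "sex", "nihss", "mrs_3mo", "hemoglobin", "esr",
    "d_dimer", "time_to_tcd", *RISK_FLAGS,
]
VELOCITY_COLUMNS = ["patient_id", "side", "depth_mm", "psv_cms", "edv_cms", "rater"]


@dataclass
class PatientRecord:
    """Covariates + 3-month outcome + raw velocity samples."""

    patient_id: str
    age: float
    sex: Literal["male", "female"]
    nihss: int
    mrs_3mo: int
    hemoglobin: float
    esr: float
    d_dimer: float
    time_to_tcd: float
    htn: bool = False
    dm: bool = False
    chol: bool = False
    smoker: bool = False
    cad: bool = False
    pad: bool = False
    samples: list[VelocitySample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.mrs_3mo <= 6:
            raise ValueError(f"mrs_3mo must be 0..6, got {self.mrs_3mo}")
        if self.nihss < 0:
            raise ValueError(f"nihss must be >= 0, got {self.nihss}")
        for lab in ("age", "hemoglobin", "esr", "d_dimer", "time_to_tcd"):
            if getattr(self, lab) < 0:
                raise ValueError(f"{lab} must be >= 0")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    def profile(self, **kwargs) -> McaIndexProfile:
        return patient_profile(self.samples, **kwargs)


@dataclass(frozen=True)
class OutcomeLabel:
    poor: bool
    threshold: int


@dataclass
class GroupComparison:
    """One descriptive-table row: per-group summaries plus a p-value."""

    variable: str
    kind: Literal["mann_whitney", "t_test", "chi2", "fisher"]
    statistic: float
    p_value: float
    summary_a: str
    summary_b: str

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


def dichotomize_outcome(mrs: int, threshold: int = 3) -> OutcomeLabel:
    """Label outcome poor iff ``mrs >= threshold`` (3 primary, 2 sensitivity)."""
    if not 0 <= mrs <= 6:
        raise ValueError(f"mRS must be within 0..6, got {mrs}")
    if threshold not in (2, 3):
        raise ValueError(f"threshold must be 2 or 3, got {threshold}")
    return OutcomeLabel(poor=mrs >= threshold, threshold=threshold)


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def _summary_continuous(values: np.ndarray, parametric: bool) -> str:
    if parametric:
        return f"{np.mean(values):.2f} ± {np.std(values, ddof=1):.2f}"
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return f"{med:.2f} [{q1:.2f}, {q3:.2f}]"


def compare_continuous(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: Literal["auto", "t_test", "mann_whitney"] = "auto",
    variable: str = "",
) -> GroupComparison:
    """Two-sided two-group comparison of a continuous variable.

    ``mann_whitney`` uses exact enumeration when the combined sample size
    is <= 20 and there are no ties, otherwise the normal approximation
    with tie correction.  ``auto`` selects the t test only when both
    groups pass a Shapiro-Wilk normality screen at alpha = 0.05.
    """
    a, b = _clean(values_a), _clean(values_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 non-missing values")

    if method == "auto":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = (
                np.ptp(a) > 0 and np.ptp(b) > 0
                and stats.shapiro(a).pvalue > 0.05
                and stats.shapiro(b).pvalue > 0.05
            )
        method = "t_test" if normal else "mann_whitney"

    if method == "t_test":
        res = stats.ttest_ind(a, b)
        return GroupComparison(
            variable=variable, kind="t_test",
            statistic=float(res.statistic), p_value=float(res.pvalue),
            summary_a=_summary_continuous(a, parametric=True),
            summary_b=_summary_continuous(b, parametric=True),
        )

    if method != "mann_whitney":
        raise ValueError(f"unknown method {method!r}")

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied; Mann-Whitney p set to 1", stacklevel=2)
        stat = len(a) * len(b) / 2.0
        p = 1.0
    else:
        ties = len(np.unique(pooled)) < len(pooled)
        mode = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=mode)
        stat, p = float(res.statistic), float(min(res.pvalue, 1.0))
    return GroupComparison(
        variable=variable, kind="mann_whitney", statistic=stat, p_value=p,
        summary_a=_summary_continuous(a, parametric=False),
        summary_b=_summary_continuous(b, parametric=False),
    )


def compare_categorical(
    table: Sequence[Sequence[int]],
    method: Literal["auto", "chi2", "fisher"] = "auto",
    variable: str = "",
    continuity_correction: bool = False,
) -> GroupComparison:
    """Chi-square or Fisher's exact test on a 2xk contingency table.

    ``auto`` routes to Fisher's exact (2x2 only) whenever any expected
    cell count is below 5, else Pearson chi-square (no continuity
    correction by default).  The two-sided Fisher p sums all tables with
    point probability <= the observed table's.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("table must be a 2-D array of non-negative integers")
    tab = tab.astype(int)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("all row and column margins must be positive")

    if method == "auto":
        expected = stats.contingency.expected_freq(tab)
        method = "fisher" if (expected < 5).any() and tab.shape == (2, 2) else "chi2"

    n_col = tab.sum(axis=0)
    pct = 100.0 * tab[0] / n_col
    summaries = [f"{tab[0, j]} ({pct[j]:.1f})" for j in range(tab.shape[1])]

    if method == "fisher":
        if tab.shape != (2, 2):
            raise ValueError("Fisher's exact test implemented for 2x2 tables only")
        res = stats.fisher_exact(tab, alternative="two-sided")
        stat, p = float(res[0]), float(res[1])
        kind = "fisher"
    elif method == "chi2":
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=continuity_correction)
        stat, p = float(chi2), float(p)
        kind = "chi2"
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        variable=variable, kind=kind, statistic=stat, p_value=p,
        summary_a=summaries[0], summary_b=summaries[1] if len(summaries) > 1 else "",
    )


#: variable -> ("continuous" | "binary"), used by descriptive_table
DEFAULT_TABLE_SPEC: dict[str, str] = {
    "age": "continuous",
    "male": "binary",
    "nihss": "continuous",
    "time_to_tcd": "continuous",
    "hemoglobin": "continuous",
    "esr": "continuous",
    "d_dimer": "continuous",
    **{flag: "binary" for flag in RISK_FLAGS},
}


def descriptive_table(
    frame: pd.DataFrame,
    poor: Sequence[bool],
    spec: dict[str, str] | None = None,
    continuous_method: str = "auto",
) -> pd.DataFrame:
    """Two-group descriptive comparison table (one row per variable).

    ``frame`` holds one row per patient; ``poor`` is the outcome label.
    ``spec`` maps variable name to ``continuous`` or ``binary``.
    Missing values are dropped per comparison (complete-case), with the
    missing count reported.
    """
    spec = dict(DEFAULT_TABLE_SPEC if spec is None else spec)
    unknown = [v for v in spec if v not in frame.columns]
    if unknown:
        raise ValueError(
            f"unknown variables {unknown}; available: {sorted(frame.columns)}"
        )
    poor = np.asarray(poor, dtype=bool)
    if len(poor) != len(frame):
        raise ValueError("grouping must be defined for every record")
    if poor.all() or not poor.any():
        raise ValueError("both outcome groups must be non-empty")

    rows = []
    for name, kind in spec.items():
        col = frame[name]
        missing = int(col.isna().sum())
        if kind == "continuous":
            cmp = compare_continuous(
                col[poor].dropna(), col[~poor].dropna(),
                method=continuous_method, variable=name,
            )
        elif kind == "binary":
            vals = col.astype(float)
            tab = [
                [int((vals[poor] == 1).sum()), int((vals[~poor] == 1).sum())],
                [int((vals[poor] == 0).sum()), int((vals[~poor] == 0).sum())],
            ]
            cmp = compare_categorical(tab, variable=name)
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {name!r}")
        rows.append(
            {
                "variable": name, "test": cmp.kind,
                "poor_summary": cmp.summary_a, "good_summary": cmp.summary_b,
                "statistic": cmp.statistic, "p_value": cmp.p_value,
                "n_missing": missing,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV I/O


def load_velocity_samples(path: str | Path) -> dict[str, list[VelocitySample]]:
    """Read the long-format velocity CSV into samples keyed by patient id.

    Expected header: ``patient_id,side,depth_mm,psv_cms,edv_cms,rater``
    with side in {R, L}.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "rater": str})
    missing = set(VELOCITY_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"velocity CSV missing columns: {sorted(missing)}")
    out: dict[str, list[VelocitySample]] = {}
    for row in df.itertuples(index=False):
        rater = getattr(row, "rater", None)
        if rater is not None and (pd.isna(rater) or rater == ""):
            rater = None
        out.setdefault(str(row.patient_id), []).append(
            VelocitySample(
                psv=float(row.psv_cms), edv=float(row.edv_cms),
                depth=float(row.depth_mm), side=Side(str(row.side)), rater=rater,
            )
        )
    return out


def load_patients(
    patients_path: str | Path, velocities_path: str | Path | None = None
) -> list[PatientRecord]:
    """Read the patient CSV (and optionally join the velocity CSV)."""
    df = pd.read_csv(patients_path, dtype={"patient_id": str})
    missing = set(PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"patient CSV missing columns: {sorted(missing)}")
    samples = (
        load_velocity_samples(velocities_path) if velocities_path is not None else {}
    )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                age=float(row.age), sex=str(row.sex),
                nihss=int(row.nihss), mrs_3mo=int(row.mrs_3mo),
                hemoglobin=float(row.hemoglobin), esr=float(row.esr),
                d_dimer=float(row.d_dimer), time_to_tcd=float(row.time_to_tcd),
                **{flag: bool(getattr(row, flag)) for flag in RISK_FLAGS},
                samples=samples.get(str(row.patient_id), []),
            )
        )
    return records


def save_patients(records: Iterable[PatientRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in PATIENT_COLUMNS if c not in RISK_FLAGS}
        row.update({flag: int(getattr(r, flag)) for flag in RISK_FLAGS})
        rows.append(row)
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)


def save_velocity_samples(records: Iterable[PatientRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id, "side": s.side.value, "depth_mm": s.depth,
            "psv_cms": s.psv, "edv_cms": s.edv, "rater": s.rater or "",
        }
        for r in records
        for s in r.samples
    ]
    pd.DataFrame(rows, columns=VELOCITY_COLUMNS).to_csv(path, index=False)


def profiles_frame(records: Sequence[PatientRecord], **kwargs) -> pd.DataFrame:
    """Per-patient index profiles as a flat table with validity columns."""
    rows = []
    for r in records:
        row: dict = {"patient_id": r.patient_id}
        row.update(r.profile(**kwargs).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
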