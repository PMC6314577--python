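"""End-to-end analysis pipeline: profiles -> descriptive tables ->
logistic models -> ROC cutoff, shared by the CLI and by tests."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from tcdasym.cohort import (
    DEFAULT_TABLE_SPEC,
    PatientRecord,
    descriptive_table,
    profiles_frame,
)
from tcdasym.modeling import (
    ADJUSTMENT_COVARIATES,
    SeparationError,
    dichotomized_fit,
    fit_logistic,
    outcome_vector,
    roc_youden,
    univariable_screen,
)

__all__ = ["covariate_frame", "analysis_frame", "run_analysis"]

SCREEN_VARIABLES = (
    "age", "male", "nihss", "time_to_tcd", "hemoglobin", "esr", "d_dimer",
    "htn", "dm", "chol", "smoker", "cad", "pad",
)

TCD_TABLE_VARIABLES = (
    "rt_proximal_index", "lt_proximal_index", "proximal_asym",
    "rt_distal_index", "lt_distal_index", "distal_asym",
    "rt_mean_index", "lt_mean_index", "overall_asym",
    "proximal_mv_asym", "distal_mv_asym", "overall_mv_asym",
    "proximal_pi_asym", "distal_pi_asym", "overall_pi_asym",
)


def covariate_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "age": r.age,
            "male": int(r.sex == "male"),
            "sex": int(r.sex == "male"),
            "nihss": r.nihss,
            "mrs_3mo": r.mrs_3mo,
            "hemoglobin": r.hemoglobin,
            "esr": r.esr,
            "d_dimer": r.d_dimer,
            "time_to_tcd": r.time_to_tcd,
            "htn": int(r.htn), "dm": int(r.dm), "chol": int(r.chol),
            "smoker": int(r.smoker), "cad": int(r.cad), "pad": int(r.pad),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def analysis_frame(records: Sequence[PatientRecord], **profile_kwargs) -> pd.DataFrame:
    """Covariates joined with the per-patient index profiles."""
    cov = covariate_frame(records)
    prof = profiles_frame(records, **profile_kwargs)
    return cov.merge(prof, on="patient_id")


def run_analysis(
    records: Sequence[PatientRecord],
    threshold: int = 3,
    cutoff: float | None = None,
) -> dict:
    """Run the full outcome analysis on a cohort.

    Returns a dict with the descriptive tables (DataFrames), the
    univariable screen, the covariate-adjusted continuous-asymmetry fit,
    the ROC result for overall asymmetry, and the adjusted fit of the
    dichotomized indicator at ``cutoff`` (Youden-optimal when None).
    """
    frame = analysis_frame(records)
    poor = outcome_vector(records, threshold).astype(bool)

    usable = frame["overall_asym"].notna().to_numpy()
    frame_u = frame.loc[usable].reset_index(drop=True)
    poor_u = poor[usable]

    table1 = descriptive_table(frame, poor, spec=DEFAULT_TABLE_SPEC)
    tcd_spec = {v: "continuous" for v in TCD_TABLE_VARIABLES}
    table2 = descriptive_table(
        frame_u, poor_u, spec=tcd_spec, continuous_method="mann_whitney"
    )

    screen = univariable_screen(frame_u, poor_u.astype(int), SCREEN_VARIABLES)

    out: dict = {
        "n_total": len(records),
        "n_usable": int(usable.sum()),
        "n_poor": int(poor.sum()),
        "threshold": threshold,
        "table1": table1,
        "table2": table2,
        "screen": screen,
    }

    covs = [c for c in ADJUSTMENT_COVARIATES if c != "sex"] + ["male"]
    try:
        adjusted = fit_logistic(
            poor_u.astype(int), frame_u[covs + ["overall_asym"]]
        )
    except (ValueError, SeparationError) as exc:
        adjusted = None
        out["adjusted_error"] = str(exc)
    out["adjusted"] = adjusted

    roc = roc_youden(frame_u["overall_asym"].to_numpy(), poor_u.astype(int))
    out["roc"] = roc

    chosen = roc.youden_cutoff if cutoff is None else cutoff
    out["cutoff"] = float(chosen)
    try:
        out["dichotomized"] = dichotomized_fit(
            frame_u, poor_u.astype(int), chosen, covariates=covs
        )
    except (ValueError, SeparationError) as exc:
        out["dichotomized"] = None
        out["dichotomized_error"] = str(exc)
    return out


def results_json(results: dict) -> dict:
    """JSON-serializable view of :func:`run_analysis` output."""

    def fit_obj(fit) -> list[dict] | None:
        if fit is None:
            return None
        df = fit.summary_frame()
        return [
            {k: (v if isinstance(v, str) else float(v)) for k, v in row.items()}
            for row in df.to_dict(orient="records")
        ]

    roc = results["roc"]
    obj = {
        "n_total": results["n_total"],
        "n_usable": results["n_usable"],
        "n_poor": results["n_poor"],
        "threshold": results["threshold"],
        "univariable": {
            name: fit_obj(fit) for name, fit in results["screen"].fits.items()
        },
        "univariable_errors": results["screen"].errors,
        "univariable_selected": results["screen"].selected,
        "adjusted": fit_obj(results["adjusted"]),
        "roc": {
            "auc": float(roc.auc),
            "youden_cutoff": float(roc.youden_cutoff),
            "youden_value": float(roc.youden_value),
        },
        "cutoff": results["cutoff"],
        "dichotomized": fit_obj(results["dichotomized"]),
    }
    for key in ("adjusted_error", "dichotomized_error"):
        if key in results:
            obj[key] = results[key]
    return obj
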