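"""Seeded synthetic cryptogenic-stroke cohort generator.

Bilateral MV and PI are log-normal per side x segment, with a
Kronecker-structured correlation (between-side correlation x
between-segment correlation) on the log scale.  Lower between-side
correlation in the poor-outcome group is the planted mechanism that
raises asymmetry indices there, rather than a systematic side shift.

Two outcome-generation modes are supported:

``group_first``
    draw the outcome label first, then group-specific TCD and covariate
    distributions — used for calibration checks against the configured
    marginal medians;
``logistic_link``
    draw TCD first from a single reference distribution, then the
    outcome through a logistic model with planted coefficients on the
    overall asymmetry index (continuous and/or a threshold indicator) —
    used for parameter-recovery studies.

Default calibration targets marginal medians/IQRs typical of a
cryptogenic-stroke registry cohort (n = 377, 13.8% poor outcome, MV
medians in the mid-50s cm/s, PI medians near 0.85-0.9).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.special import expit

from tcdasym.cohort import PatientRecord
from tcdasym.hemodynamics import (
    PI_MULTIPLIER,
    Side,
    VelocitySample,
    patient_profile,
)

__all__ = [
    "TcdGroupParams",
    "CovariateParams",
    "EffectParams",
    "CohortParams",
    "default_params",
    "generate_cohort",
    "invert_to_psv_edv",
    "PARAMS_SCHEMA_VERSION",
]

PARAMS_SCHEMA_VERSION = 1

# representative insonation depth used when emitting samples, mm
SEGMENT_DEPTH = {"M1": 60.0, "M2": 50.0}

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


def _lognorm_sigma(q1: float, q3: float) -> float:
    """Log-scale SD of a log-normal matching the given quartiles."""
    return float(np.log(q3 / q1) / (2.0 * _Z75))


def invert_to_psv_edv(mv: float, pi: float) -> tuple[float, float]:
    """Solve ``MV = EDV + (PSV-EDV)/3`` and ``PI = (PSV-EDV)/MV`` for
    (PSV, EDV).

    ``psv = mv*(1 + 2*pi/3)``, ``edv = mv*(1 - pi/3)``; the round trip
    through ``compute_mv``/``compute_pi`` reproduces (mv, pi) to machine
    precision.  Infeasible when ``pi >= 3`` (EDV would be negative).
    """
    if mv <= 0.0:
        raise ValueError(f"require mv > 0, got {mv}")
    if not 0.0 <= pi < 3.0:
        raise ValueError(f"infeasible inversion: require 0 <= pi < 3, got {pi}")
    return mv * (1.0 + 2.0 * pi / 3.0), mv * (1.0 - pi / 3.0)


@dataclass
class TcdGroupParams:
    """Log-normal MV/PI marginals and log-scale correlations for one group.

    ``mv_median``/``pi_median`` map side ("R"/"L") -> segment
    ("M1"/"M2") -> marginal median; sigmas are log-scale SDs with the
    same layout.
    """

    mv_median: dict[str, dict[str, float]]
    mv_sigma: dict[str, dict[str, float]]
    pi_median: dict[str, dict[str, float]]
    pi_sigma: dict[str, dict[str, float]]
    side_corr: float = 0.85
    segment_corr: float = 0.7

    def __post_init__(self) -> None:
        # side_corr = 1 is allowed as the degenerate perfectly-symmetric case
        for rho in (self.side_corr, self.segment_corr):
            if not -1.0 < rho <= 1.0:
                raise ValueError(f"correlation must lie in (-1, 1], got {rho}")
        for d in (self.mv_sigma, self.pi_sigma):
            for side in d.values():
                for s in side.values():
                    if s <= 0:
                        raise ValueError("scales must be > 0")


@dataclass
class CovariateParams:
    """Per-group covariate distributions (labs log-normal, age normal)."""

    age_mean: float
    age_sd: float
    male_fraction: float
    nihss_median: float
    nihss_sigma: float
    hemoglobin_median: float
    hemoglobin_sigma: float
    esr_median: float
    esr_sigma: float
    d_dimer_median: float
    d_dimer_sigma: float
    time_to_tcd_median: float
    time_to_tcd_sigma: float
    risk_fractions: dict[str, float] = field(default_factory=dict)
    mrs_weights: list[float] = field(default_factory=list)


@dataclass
class EffectParams:
    """Planted outcome effects for the ``logistic_link`` mode."""

    intercept: float = -2.2
    beta_asym: float = 0.0  # log-odds per percentage point of overall asymmetry
    indicator_log_or: float = 0.0
    indicator_threshold: float = 9.0


@dataclass
class CohortParams:
    """Full generator configuration; the seed fixes output bit-for-bit."""

    n_total: int
    poor_fraction: float
    good: TcdGroupParams
    poor: TcdGroupParams
    good_covariates: CovariateParams
    poor_covariates: CovariateParams
    mode: Literal["group_first", "logistic_link"] = "group_first"
    effects: EffectParams = field(default_factory=EffectParams)
    seed: int = 0
    schema_version: int = PARAMS_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if not 0.0 < self.poor_fraction < 1.0:
            raise ValueError("poor_fraction must lie in (0, 1)")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CohortParams":
        p = Path(source)
        data = json.loads(p.read_text() if p.exists() else str(source))
        version = data.pop("schema_version", PARAMS_SCHEMA_VERSION)
        if version != PARAMS_SCHEMA_VERSION:
            raise ValueError(f"unsupported params schema version {version}")
        return cls(
            n_total=data["n_total"],
            poor_fraction=data["poor_fraction"],
            good=TcdGroupParams(**data["good"]),
            poor=TcdGroupParams(**data["poor"]),
            good_covariates=CovariateParams(**data["good_covariates"]),
            poor_covariates=CovariateParams(**data["poor_covariates"]),
            mode=data.get("mode", "group_first"),
            effects=EffectParams(**data.get("effects", {})),
            seed=data.get("seed", 0),
        )


def _group_tcd(
    median_iqr_mv: dict[str, dict[str, tuple[float, float, float]]],
    median_iqr_pi: dict[str, dict[str, tuple[float, float, float]]],
    side_corr: float,
) -> TcdGroupParams:
    mv_median = {s: {g: v[0] for g, v in segs.items()} for s, segs in median_iqr_mv.items()}
    mv_sigma = {s: {g: _lognorm_sigma(v[1], v[2]) for g, v in segs.items()} for s, segs in median_iqr_mv.items()}
    pi_median = {s: {g: v[0] for g, v in segs.items()} for s, segs in median_iqr_pi.items()}
    pi_sigma = {s: {g: _lognorm_sigma(v[1], v[2]) for g, v in segs.items()} for s, segs in median_iqr_pi.items()}
    return TcdGroupParams(
        mv_median=mv_median, mv_sigma=mv_sigma,
        pi_median=pi_median, pi_sigma=pi_sigma,
        side_corr=side_corr,
    )


def default_params(seed: int = 0) -> CohortParams:
    """Documented default calibration for a 377-patient two-group cohort.

    Marginal medians and quartiles (median, q1, q3) below are the
    calibration targets the generator is checked against; the poor group
    gets a lower between-side correlation, which is what raises its
    asymmetry indices.
    """
    good = _group_tcd(
        median_iqr_mv={
            "R": {"M1": (56.0, 46.0, 69.0), "M2": (54.0, 43.0, 69.0)},
            "L": {"M1": (57.0, 47.0, 74.0), "M2": (56.0, 46.0, 70.0)},
        },
        median_iqr_pi={
            "R": {"M1": (0.87, 0.76, 1.00), "M2": (0.84, 0.73, 1.00)},
            "L": {"M1": (0.85, 0.73, 1.00), "M2": (0.84, 0.71, 1.00)},
        },
        side_corr=0.9,
    )
    poor = _group_tcd(
        median_iqr_mv={
            "R": {"M1": (52.5, 42.0, 63.3), "M2": (55.0, 40.3, 70.5)},
            "L": {"M1": (55.0, 41.0, 70.0), "M2": (57.0, 43.5, 69.0)},
        },
        median_iqr_pi={
            "R": {"M1": (0.91, 0.77, 1.00), "M2": (0.90, 0.78, 1.10)},
            "L": {"M1": (0.89, 0.76, 1.00), "M2": (0.88, 0.62, 1.08)},
        },
        side_corr=0.65,
    )
    good_cov = CovariateParams(
        age_mean=61.24, age_sd=12.19, male_fraction=0.748,
        nihss_median=2.0, nihss_sigma=_lognorm_sigma(1.0, 4.0),
        hemoglobin_median=14.5, hemoglobin_sigma=_lognorm_sigma(13.3, 15.5),
        esr_median=13.0, esr_sigma=_lognorm_sigma(7.0, 26.0),
        d_dimer_median=129.0, d_dimer_sigma=_lognorm_sigma(75.0, 271.3),
        time_to_tcd_median=3.0, time_to_tcd_sigma=_lognorm_sigma(2.0, 4.0),
        risk_fractions={
            "htn": 0.745, "dm": 0.292, "chol": 0.157,
            "smoker": 0.338, "cad": 0.175, "pad": 0.022,
        },
        mrs_weights=[0.45, 0.35, 0.20],
    )
    poor_cov = CovariateParams(
        age_mean=67.46, age_sd=11.83, male_fraction=0.615,
        nihss_median=8.0, nihss_sigma=_lognorm_sigma(4.0, 15.0),
        hemoglobin_median=13.6, hemoglobin_sigma=_lognorm_sigma(11.7, 14.9),
        esr_median=20.5, esr_sigma=_lognorm_sigma(8.0, 39.3),
        d_dimer_median=298.5, d_dimer_sigma=_lognorm_sigma(127.8, 1206.8),
        time_to_tcd_median=4.0, time_to_tcd_sigma=_lognorm_sigma(3.0, 6.0),
        risk_fractions={
            "htn": 0.654, "dm": 0.250, "chol": 0.212,
            "smoker": 0.250, "cad": 0.173, "pad": 0.019,
        },
        mrs_weights=[0.40, 0.30, 0.15, 0.15],
    )
    return CohortParams(
        n_total=377,
        poor_fraction=52.0 / 377.0,
        good=good, poor=poor,
        good_covariates=good_cov, poor_covariates=poor_cov,
        seed=seed,
    )


def _kron_corr(side_corr: float, segment_corr: float) -> np.ndarray:
    # variable order: (R,M1), (R,M2), (L,M1), (L,M2)
    side = np.array([[1.0, side_corr], [side_corr, 1.0]])
    seg = np.array([[1.0, segment_corr], [segment_corr, 1.0]])
    return np.kron(side, seg)


def _draw_lognormal_block(
    rng: np.random.Generator,
    n: int,
    medians: dict[str, dict[str, float]],
    sigmas: dict[str, dict[str, float]],
    corr: np.ndarray,
    upper: float | None = None,
    max_redraws: int = 100,
) -> tuple[np.ndarray, int]:
    """(n, 4) correlated log-normal draws; columns (R,M1),(R,M2),(L,M1),(L,M2).

    Rows with any value above ``upper`` are redrawn; returns the draw and
    the redraw count.
    """
    mu = np.log(
        [medians["R"]["M1"], medians["R"]["M2"], medians["L"]["M1"], medians["L"]["M2"]]
    )
    sd = np.array(
        [sigmas["R"]["M1"], sigmas["R"]["M2"], sigmas["L"]["M1"], sigmas["L"]["M2"]]
    )
    # eigen factor instead of Cholesky so singular (side_corr = 1) correlation
    # matrices are handled exactly
    w, v = np.linalg.eigh(corr)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    def draw(m: int) -> np.ndarray:
        z = rng.standard_normal((m, 4)) @ factor.T
        return np.exp(mu + sd * z)

    out = draw(n)
    redraws = 0
    if upper is not None:
        for _ in range(max_redraws):
            bad = (out >= upper).any(axis=1)
            if not bad.any():
                break
            redraws += int(bad.sum())
            out[bad] = draw(int(bad.sum()))
    return out, redraws


def _draw_covariates(
    rng: np.random.Generator, n: int, cov: CovariateParams
) -> dict[str, np.ndarray]:
    def lognorm(median: float, sigma: float) -> np.ndarray:
        return np.exp(np.log(median) + sigma * rng.standard_normal(n))

    return {
        "age": np.clip(rng.normal(cov.age_mean, cov.age_sd, n), 18.0, 100.0),
        "male": rng.random(n) < cov.male_fraction,
        "nihss": np.minimum(
            np.round(lognorm(cov.nihss_median, cov.nihss_sigma)).astype(int), 42
        ),
        "hemoglobin": lognorm(cov.hemoglobin_median, cov.hemoglobin_sigma),
        "esr": lognorm(cov.esr_median, cov.esr_sigma),
        "d_dimer": lognorm(cov.d_dimer_median, cov.d_dimer_sigma),
        "time_to_tcd": lognorm(cov.time_to_tcd_median, cov.time_to_tcd_sigma),
        **{
            flag: rng.random(n) < frac
            for flag, frac in cov.risk_fractions.items()
        },
    }


def _samples_from_block(mv_row: np.ndarray, pi_row: np.ndarray, rater: str = "A") -> list[VelocitySample]:
    samples = []
    for j, (side, segment) in enumerate(
        [(Side.RIGHT, "M1"), (Side.RIGHT, "M2"), (Side.LEFT, "M1"), (Side.LEFT, "M2")]
    ):
        psv, edv = invert_to_psv_edv(float(mv_row[j]), float(pi_row[j]))
        samples.append(
            VelocitySample(
                psv=psv, edv=edv, depth=SEGMENT_DEPTH[segment], side=side, rater=rater
            )
        )
    return samples


def overall_asym_from_blocks(mv: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Vectorized overall MCA asymmetry (percent) from (n, 4) MV/PI blocks.

    Columns are (R,M1), (R,M2), (L,M1), (L,M2).  Equivalent to running
    :func:`tcdasym.hemodynamics.patient_profile` per patient (asserted in
    the tests); nan where any contributing index is undefined.
    """
    denom = mv - PI_MULTIPLIER * pi
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(denom > 0, 100.0 * (mv + PI_MULTIPLIER * pi) / denom, np.nan)
    right = (idx[:, 0] + idx[:, 1]) / 2.0
    left = (idx[:, 2] + idx[:, 3]) / 2.0
    return 200.0 * np.abs(right - left) / (right + left)


def generate_cohort(
    params: CohortParams, seed: int | None = None
) -> list[PatientRecord]:
    """Generate a synthetic cohort; deterministic under (params, seed).

    See the module docstring for the two outcome-generation modes.
    Draws with PI >= 3 (infeasible PSV/EDV inversion) are redrawn with
    the count warned about; parameter sets making the MCA index
    undefined (``mv <= 10*pi``) for more than 10% of draws trigger a
    warning reporting the rate.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_total

    if params.mode == "group_first":
        poor = rng.random(n) < params.poor_fraction
    elif params.mode == "logistic_link":
        poor = np.zeros(n, dtype=bool)  # assigned after TCD draws
    else:
        raise ValueError(f"unknown mode {params.mode!r}")

    mv = np.empty((n, 4))
    pi = np.empty((n, 4))
    redraws = 0
    if params.mode == "group_first":
        for is_poor, group in ((False, params.good), (True, params.poor)):
            idx = np.flatnonzero(poor == is_poor)
            if len(idx) == 0:
                continue
            corr = _kron_corr(group.side_corr, group.segment_corr)
            mv_blk, r1 = _draw_lognormal_block(
                rng, len(idx), group.mv_median, group.mv_sigma, corr
            )
            pi_blk, r2 = _draw_lognormal_block(
                rng, len(idx), group.pi_median, group.pi_sigma, corr, upper=3.0
            )
            mv[idx], pi[idx] = mv_blk, pi_blk
            redraws += r1 + r2
    else:
        group = params.good  # reference TCD distribution
        corr = _kron_corr(group.side_corr, group.segment_corr)
        mv, r1 = _draw_lognormal_block(rng, n, group.mv_median, group.mv_sigma, corr)
        pi, r2 = _draw_lognormal_block(
            rng, n, group.pi_median, group.pi_sigma, corr, upper=3.0
        )
        redraws = r1 + r2
        asym = overall_asym_from_blocks(mv, pi)
        eff = params.effects
        logit = (
            eff.intercept
            + eff.beta_asym * asym
            + eff.indicator_log_or * (asym > eff.indicator_threshold)
        )
        poor = rng.random(n) < expit(logit)

    if redraws:
        warnings.warn(f"redrew {redraws} infeasible draws (PI >= 3)", stacklevel=2)
    undefined_rate = float((mv <= PI_MULTIPLIER * pi).mean())
    if undefined_rate > 0.10:
        warnings.warn(
            f"MCA index undefined for {undefined_rate:.1%} of draws", stacklevel=2
        )

    if params.mode == "logistic_link":
        # covariates must be outcome-independent here, otherwise the fitted
        # adjusted model is misspecified and planted effects are attenuated
        cov = _draw_covariates(rng, n, params.good_covariates)
    else:
        cov = {}
        for is_poor, cp in (
            (False, params.good_covariates),
            (True, params.poor_covariates),
        ):
            idx = np.flatnonzero(poor == is_poor)
            if len(idx) == 0:
                continue
            block = _draw_covariates(rng, len(idx), cp)
            for key, values in block.items():
                cov.setdefault(key, np.empty(n, dtype=values.dtype))[idx] = values

    mrs = np.empty(n, dtype=int)
    for is_poor, cp, base in (
        (False, params.good_covariates, 0),
        (True, params.poor_covariates, 3),
    ):
        idx = np.flatnonzero(poor == is_poor)
        if len(idx) == 0:
            continue
        w = np.asarray(cp.mrs_weights, dtype=float)
        w = w / w.sum()
        mrs[idx] = base + rng.choice(len(w), size=len(idx), p=w)

    records = []
    width = len(str(n))
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:0{width}d}",
                age=float(cov["age"][i]),
                sex="male" if cov["male"][i] else "female",
                nihss=int(cov["nihss"][i]),
                mrs_3mo=int(mrs[i]),
                hemoglobin=float(cov["hemoglobin"][i]),
                esr=float(cov["esr"][i]),
                d_dimer=float(cov["d_dimer"][i]),
                time_to_tcd=float(cov["time_to_tcd"][i]),
                **{flag: bool(cov[flag][i]) for flag in ("htn", "dm", "chol", "smoker", "cad", "pad")},
                samples=_samples_from_block(mv[i], pi[i]),
            )
        )
    return records
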