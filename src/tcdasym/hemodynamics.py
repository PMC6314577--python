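"""Core hemodynamic formulas for bilateral MCA transcranial Doppler.

All velocities are cm/s, insonation depths are mm, indices are percent.
The composite MCA index amplifies the pulsatility index by a fixed
multiplier (default 10) before forming the ratio
``100*(MV + k*PI)/(MV - k*PI)``; it is undefined when ``MV <= k*PI``.

Asymmetry between sides is expressed as the absolute right-left
difference as a percentage of the bilateral mean,
``200*|R - L|/(R + L)``.  A literal left-to-right reading of the source
formula string ("100 x |R-L| / (R+L) / 2", i.e. ``50*|R-L|/(R+L)``) is
available behind the ``convention`` switch for auditability; the default
is the standard convention, which is the only one consistent with the
magnitude of published MV asymmetry medians.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Side",
    "Segment",
    "InvalidSampleError",
    "InvalidIndexError",
    "VelocitySample",
    "SegmentHemodynamics",
    "McaIndexProfile",
    "compute_mv",
    "compute_pi",
    "segment_from_depth",
    "mca_index",
    "mean_mca_index",
    "asymmetry_index",
    "patient_profile",
    "index_sensitivity_grid",
    "PI_MULTIPLIER",
    "M1_WINDOW",
    "M2_WINDOW",
]

#: Default pulsatility-index multiplier inside the MCA index.
PI_MULTIPLIER = 10.0

#: Insonation-depth windows (mm, inclusive) defining the MCA segments.
M1_WINDOW = (58.0, 68.0)
M2_WINDOW = (44.0, 56.0)


class Side(str, enum.Enum):
    RIGHT = "R"
    LEFT = "L"


class Segment(str, enum.Enum):
    M1 = "M1"  # proximal stem
    M2 = "M2"  # distal branches
    OUT_OF_WINDOW = "out_of_window"


class InvalidSampleError(ValueError):
    """A velocity sample violates ``psv >= edv >= 0`` or ``depth > 0``."""


class InvalidIndexError(ValueError):
    """An index is undefined because its denominator is non-positive."""


@dataclass(frozen=True)
class VelocitySample:
    """One spectral-Doppler measurement at a single depth.

    Parameters
    ----------
    psv, edv
        Peak systolic and end-diastolic velocity, cm/s.
    depth
        Insonation depth, mm.
    side
        Insonated side.
    rater
        Optional rater identifier used by the reliability analysis.
    """

    psv: float
    edv: float
    depth: float
    side: Side
    rater: str | None = None

    def __post_init__(self) -> None:
        if not (self.psv >= self.edv >= 0.0):
            raise InvalidSampleError(
                f"require psv >= edv >= 0, got psv={self.psv}, edv={self.edv}"
            )
        if not self.depth > 0.0:
            raise InvalidSampleError(f"require depth > 0, got {self.depth}")
        if not isinstance(self.side, Side):
            object.__setattr__(self, "side", Side(self.side))

    @property
    def segment(self) -> Segment:
        return segment_from_depth(self.depth)

    @property
    def mv(self) -> float:
        return compute_mv(self.psv, self.edv)

    @property
    def pi(self) -> float:
        return compute_pi(self.psv, self.edv)


@dataclass(frozen=True)
class SegmentHemodynamics:
    """Aggregated mean velocity and pulsatility for one side x segment."""

    side: Side
    segment: Segment
    mv: float
    pi: float
    n_samples: int = 1

    def __post_init__(self) -> None:
        if self.mv <= 0.0:
            raise InvalidSampleError(f"require mv > 0, got {self.mv}")
        if self.pi < 0.0:
            raise InvalidSampleError(f"require pi >= 0, got {self.pi}")
        if self.segment not in (Segment.M1, Segment.M2):
            raise InvalidSampleError(
                "segment hemodynamics only defined inside the M1/M2 windows"
            )


def compute_mv(psv: float, edv: float) -> float:
    """Mean flow velocity ``EDV + (PSV - EDV)/3`` (cm/s).

    Raises
    ------
    InvalidSampleError
        If ``psv < edv`` or either velocity is negative (corrupted sample).
    """
    if not (psv >= edv >= 0.0):
        raise InvalidSampleError(
            f"require psv >= edv >= 0, got psv={psv}, edv={edv}"
        )
    return edv + (psv - edv) / 3.0


def compute_pi(psv: float, edv: float) -> float:
    """Pulsatility index ``(PSV - EDV)/MV`` (dimensionless).

    Raises
    ------
    InvalidIndexError
        If MV is zero (``psv == edv == 0``), where PI is undefined.
    """
    mv = compute_mv(psv, edv)
    if mv == 0.0:
        raise InvalidIndexError("PI undefined: MV = 0 (psv = edv = 0)")
    return (psv - edv) / mv


def segment_from_depth(depth: float) -> Segment:
    """Classify an insonation depth into M1 (58-68 mm) or M2 (44-56 mm).

    Depths outside both (disjoint, inclusive) windows — including the
    57 mm gap — return ``Segment.OUT_OF_WINDOW``; that is a value, not
    an error.
    """
    if not depth > 0.0:
        raise InvalidSampleError(f"require depth > 0, got {depth}")
    if M1_WINDOW[0] <= depth <= M1_WINDOW[1]:
        return Segment.M1
    if M2_WINDOW[0] <= depth <= M2_WINDOW[1]:
        return Segment.M2
    return Segment.OUT_OF_WINDOW


def mca_index(mv: float, pi: float, multiplier: float = PI_MULTIPLIER) -> float:
    """Composite MCA index ``100*(MV + k*PI)/(MV - k*PI)`` in percent.

    The index exceeds 100 whenever ``pi > 0`` and rises with low MV and
    high PI.

    Raises
    ------
    InvalidIndexError
        If ``mv <= multiplier*pi`` (non-positive denominator).  Callers
        must flag the affected side/segment invalid rather than drop it
        silently.
    """
    if mv <= 0.0:
        raise InvalidSampleError(f"require mv > 0, got {mv}")
    if pi < 0.0:
        raise InvalidSampleError(f"require pi >= 0, got {pi}")
    denom = mv - multiplier * pi
    if denom <= 0.0:
        raise InvalidIndexError(
            f"MCA index undefined: mv={mv} <= {multiplier}*pi={multiplier * pi}"
        )
    return 100.0 * (mv + multiplier * pi) / denom


def mean_mca_index(proximal_index: float, distal_index: float) -> float:
    """Arithmetic mean of the proximal (M1) and distal (M2) MCA indices."""
    return (proximal_index + distal_index) / 2.0


def asymmetry_index(
    right: float, left: float, convention: str = "standard"
) -> float:
    """Bilateral asymmetry of a positive quantity, in percent.

    ``standard`` (default): ``200*|R - L|/(R + L)``, i.e. the absolute
    difference as a percentage of the bilateral mean; bounded in
    [0, 200) and zero iff the sides are equal.  ``literal``: the
    left-to-right parse ``50*|R - L|/(R + L)`` of the printed formula,
    exposed for auditability only.
    """
    if right <= 0.0 or left <= 0.0:
        raise InvalidSampleError(
            f"require positive bilateral values, got right={right}, left={left}"
        )
    if convention == "standard":
        scale = 200.0
    elif convention == "literal":
        scale = 50.0
    else:
        raise ValueError(f"unknown asymmetry convention: {convention!r}")
    return scale * abs(right - left) / (right + left)


@dataclass
class McaIndexProfile:
    """Per-patient derived MCA indices and asymmetries (percent).

    Any quantity whose defining denominator is non-positive is ``nan``
    and recorded in ``invalid``; a profile missing a side x segment is
    ``complete = False`` with the reasons listed.
    """

    right: SegmentHemodynamics | None = None
    left: SegmentHemodynamics | None = None
    right_distal: SegmentHemodynamics | None = None
    left_distal: SegmentHemodynamics | None = None

    rt_proximal_index: float = math.nan
    rt_distal_index: float = math.nan
    rt_mean_index: float = math.nan
    lt_proximal_index: float = math.nan
    lt_distal_index: float = math.nan
    lt_mean_index: float = math.nan

    proximal_asym: float = math.nan
    distal_asym: float = math.nan
    overall_asym: float = math.nan

    proximal_mv_asym: float = math.nan
    distal_mv_asym: float = math.nan
    overall_mv_asym: float = math.nan
    proximal_pi_asym: float = math.nan
    distal_pi_asym: float = math.nan
    overall_pi_asym: float = math.nan

    complete: bool = True
    incomplete_reasons: list[str] = field(default_factory=list)
    invalid: list[str] = field(default_factory=list)

    FIELDS = (
        "rt_proximal_index",
        "rt_distal_index",
        "rt_mean_index",
        "lt_proximal_index",
        "lt_distal_index",
        "lt_mean_index",
        "proximal_asym",
        "distal_asym",
        "overall_asym",
        "proximal_mv_asym",
        "distal_mv_asym",
        "overall_mv_asym",
        "proximal_pi_asym",
        "distal_pi_asym",
        "overall_pi_asym",
    )

    def is_valid(self, name: str) -> bool:
        return self.complete and name not in self.invalid and not math.isnan(
            getattr(self, name)
        )

    def as_dict(self) -> dict[str, float | bool | str]:
        out: dict[str, float | bool | str] = {f: getattr(self, f) for f in self.FIELDS}
        out["complete"] = self.complete
        out["incomplete_reasons"] = ";".join(self.incomplete_reasons)
        out["invalid"] = ";".join(self.invalid)
        return out


_SEGMENT_LABEL = {Segment.M1: "proximal", Segment.M2: "distal"}
_SIDE_LABEL = {Side.RIGHT: "right", Side.LEFT: "left"}


def _aggregate(
    samples: Sequence[VelocitySample], side: Side, segment: Segment
) -> SegmentHemodynamics | None:
    # Means of per-depth MV and PI (PI averaged directly, not recomputed
    # from averaged PSV/EDV).
    sub = [s for s in samples if s.side == side and s.segment == segment]
    if not sub:
        return None
    mv = float(np.mean([s.mv for s in sub]))
    pi = float(np.mean([s.pi for s in sub]))
    return SegmentHemodynamics(side=side, segment=segment, mv=mv, pi=pi, n_samples=len(sub))


def patient_profile(
    samples: Iterable[VelocitySample],
    multiplier: float = PI_MULTIPLIER,
    convention: str = "standard",
) -> McaIndexProfile:
    """Assemble the full per-patient index profile from raw samples.

    Per side and segment, MV and PI are arithmetic means over that
    segment's in-window samples.  Side/segment MCA indices, their mean,
    and all asymmetries follow; overall MV/PI asymmetries use the
    per-side mean of the proximal and distal MV/PI.  A missing side or
    segment marks the profile incomplete (mirroring poor-temporal-window
    exclusions); an undefined index flags only the derived quantities
    that depend on it.
    """
    samples = list(samples)
    profile = McaIndexProfile()
    hemo: dict[tuple[Side, Segment], SegmentHemodynamics | None] = {}
    for side in (Side.RIGHT, Side.LEFT):
        for segment in (Segment.M1, Segment.M2):
            agg = _aggregate(samples, side, segment)
            hemo[(side, segment)] = agg
            if agg is None:
                profile.complete = False
                profile.incomplete_reasons.append(
                    f"no {_SIDE_LABEL[side]} {_SEGMENT_LABEL[segment]} window"
                )
    profile.right = hemo[(Side.RIGHT, Segment.M1)]
    profile.right_distal = hemo[(Side.RIGHT, Segment.M2)]
    profile.left = hemo[(Side.LEFT, Segment.M1)]
    profile.left_distal = hemo[(Side.LEFT, Segment.M2)]
    if not profile.complete:
        return profile

    idx: dict[tuple[Side, Segment], float] = {}
    for (side, segment), agg in hemo.items():
        assert agg is not None
        name = f"{'rt' if side is Side.RIGHT else 'lt'}_{_SEGMENT_LABEL[segment]}_index"
        try:
            value = mca_index(agg.mv, agg.pi, multiplier)
        except InvalidIndexError:
            profile.invalid.append(name)
            value = math.nan
        idx[(side, segment)] = value
        setattr(profile, name, value)

    for side, prefix in ((Side.RIGHT, "rt"), (Side.LEFT, "lt")):
        p, d = idx[(side, Segment.M1)], idx[(side, Segment.M2)]
        name = f"{prefix}_mean_index"
        if math.isnan(p) or math.isnan(d):
            profile.invalid.append(name)
        else:
            setattr(profile, name, mean_mca_index(p, d))

    def _asym(name: str, r: float, l: float) -> None:
        if math.isnan(r) or math.isnan(l):
            profile.invalid.append(name)
            return
        setattr(profile, name, asymmetry_index(r, l, convention))

    _asym("proximal_asym", idx[(Side.RIGHT, Segment.M1)], idx[(Side.LEFT, Segment.M1)])
    _asym("distal_asym", idx[(Side.RIGHT, Segment.M2)], idx[(Side.LEFT, Segment.M2)])
    # overall asymmetry is defined from the two mean indices only
    _asym("overall_asym", profile.rt_mean_index, profile.lt_mean_index)

    for attr in ("mv", "pi"):
        vals = {k: getattr(v, attr) for k, v in hemo.items() if v is not None}
        _asym(
            f"proximal_{attr}_asym",
            vals[(Side.RIGHT, Segment.M1)],
            vals[(Side.LEFT, Segment.M1)],
        )
        _asym(
            f"distal_{attr}_asym",
            vals[(Side.RIGHT, Segment.M2)],
            vals[(Side.LEFT, Segment.M2)],
        )
        _asym(
            f"overall_{attr}_asym",
            (vals[(Side.RIGHT, Segment.M1)] + vals[(Side.RIGHT, Segment.M2)]) / 2.0,
            (vals[(Side.LEFT, Segment.M1)] + vals[(Side.LEFT, Segment.M2)]) / 2.0,
        )
    return profile


def index_sensitivity_grid(
    mv_values: Sequence[float],
    pi_values: Sequence[float],
    multipliers: Sequence[float],
) -> "np.ndarray":
    """Index values over a (mv, pi, multiplier) grid; nan where undefined.

    Used to compare how PI multipliers spread differences between
    hemodynamic states; undefined cells (``mv <= k*pi``) are flagged as
    nan, never raised.

    Returns a structured array with fields ``mv, pi, multiplier, index,
    defined`` of shape ``(len(mv_values), len(pi_values),
    len(multipliers))``.
    """
    mv_arr = np.asarray(mv_values, dtype=float)
    pi_arr = np.asarray(pi_values, dtype=float)
    k_arr = np.asarray(multipliers, dtype=float)
    if (mv_arr <= 0).any() or (pi_arr < 0).any() or (k_arr <= 0).any():
        raise InvalidSampleError("require mv > 0, pi >= 0, multipliers > 0")
    mv, pi, k = np.meshgrid(mv_arr, pi_arr, k_arr, indexing="ij")
    denom = mv - k * pi
    defined = denom > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        index = np.where(defined, 100.0 * (mv + k * pi) / denom, np.nan)
    out = np.empty(mv.shape, dtype=[("mv", float), ("pi", float), ("multiplier", float), ("index", float), ("defined", bool)])
    out["mv"], out["pi"], out["multiplier"] = mv, pi, k
    out["index"], out["defined"] = index, defined
    return out
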