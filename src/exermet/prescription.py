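"""Exercise sessions and conversions between work rate, oxygen cost and intensity.

Five modalities are supported. For leg and arm cycling, linear relations link
the external work rate (W) to oxygen uptake during moderate-intensity
exercise. For walking, running and stepping, the ACSM metabolic equations give
the oxygen cost from gait kinematics, and the session's work-rate surrogate is
obtained through the ~5 kcal per litre O2 caloric equivalent.

An exercise session is a time-ordered list of piecewise-constant intensity
segments (each a target %VO2max over [t_start, t_end]); a single segment is
the classic step protocol, multiple segments encode incremental tests.
"""

from __future__ import annotations

import enum
from typing import List

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import DomainError

__all__ = [
    "Modality",
    "CyclingMode",
    "GaitMode",
    "GaitParameters",
    "ExerciseSegment",
    "ExerciseProtocol",
    "VO2_REST_DEFAULT",
    "wr_from_vo2_cycling",
    "vo2_from_gait",
    "wr_energy_equivalent",
    "tv_from_gait",
]

#: Resting oxygen uptake, ml·kg⁻¹·min⁻¹ (1 MET, the ACSM convention).
VO2_REST_DEFAULT = 3.5


class Modality(str, enum.Enum):
    leg_cycling = "leg_cycling"
    arm_cycling = "arm_cycling"
    walking = "walking"
    running = "running"
    stepping = "stepping"


class CyclingMode(str, enum.Enum):
    leg = "leg"
    arm = "arm"


class GaitMode(str, enum.Enum):
    walking = "walking"
    running = "running"
    stepping = "stepping"


class GaitParameters(BaseModel):
    """Kinematic description of a gait-type exercise.

    ``speed`` (v, m·min⁻¹) and ``grade`` (G, fractional slope) apply to
    walking/running; ``step_frequency`` (F, steps·min⁻¹) and ``step_height``
    (H, m) to stepping. Only the modality-relevant fields may be non-zero.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    speed: float = Field(default=0.0, ge=0)
    grade: float = Field(default=0.0, ge=0)
    step_frequency: float = Field(default=0.0, ge=0)
    step_height: float = Field(default=0.0, ge=0)


class ExerciseSegment(BaseModel):
    """One piecewise-constant intensity interval: Tv %VO2max over [t_start, t_end] min."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    t_start: float = Field(ge=0)
    t_end: float
    tv: float = Field(gt=0, le=100)
    above_lt: bool = False

    @model_validator(mode="after")
    def _ordered(self) -> "ExerciseSegment":
        if not self.t_end > self.t_start:
            raise ValueError("segment requires t_end > t_start")
        return self


class ExerciseProtocol(BaseModel):
    """An exercise session: modality plus ordered, non-overlapping segments."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    modality: Modality = Modality.leg_cycling
    segments: List[ExerciseSegment] = Field(default_factory=list)
    vo2_rest: float = Field(default=VO2_REST_DEFAULT, gt=0)

    @model_validator(mode="after")
    def _non_overlapping(self) -> "ExerciseProtocol":
        prev_end = None
        for seg in self.segments:
            if prev_end is not None and seg.t_start < prev_end:
                raise ValueError("segments must be time-ordered and non-overlapping")
            prev_end = seg.t_end
        return self

    @property
    def t_start(self) -> float | None:
        return self.segments[0].t_start if self.segments else None

    @property
    def t_end(self) -> float | None:
        return self.segments[-1].t_end if self.segments else None

    @classmethod
    def single_bout(
        cls,
        tv: float,
        t_start: float,
        t_end: float,
        modality: Modality = Modality.leg_cycling,
        vo2_rest: float = VO2_REST_DEFAULT,
    ) -> "ExerciseProtocol":
        """The step protocol: one segment at Tv from t_start to t_end."""
        return cls(
            modality=modality,
            segments=[ExerciseSegment(t_start=t_start, t_end=t_end, tv=tv)],
            vo2_rest=vo2_rest,
        )


def wr_from_vo2_cycling(
    vo2: float,
    bw: float,
    vo2_rest: float = VO2_REST_DEFAULT,
    mode: CyclingMode | str = CyclingMode.leg,
) -> float:
    """External work rate (W) for cycling at oxygen uptake ``vo2``.

    Leg cycling: WR = BW·(VO2 − 2·VO2rest)/10.8;
    arm cycling: WR = BW·(VO2 − VO2rest)/18. Valid for moderate-intensity
    exercise; intensities yielding negative work rates are rejected.
    """
    mode = CyclingMode(mode)
    if mode is CyclingMode.leg:
        wr = bw * (vo2 - 2.0 * vo2_rest) / 10.8
    else:
        wr = bw * (vo2 - vo2_rest) / 18.0
    if wr < 0:
        raise DomainError(
            f"{mode.value} cycling at VO2={vo2} ml/kg/min is below the relation's "
            "validity range (negative work rate)"
        )
    return wr


def vo2_from_gait(
    params: GaitParameters,
    vo2_rest: float = VO2_REST_DEFAULT,
    mode: GaitMode | str = GaitMode.walking,
) -> float:
    """Oxygen cost (ml·kg⁻¹·min⁻¹) of walking, running or stepping (ACSM equations)."""
    mode = GaitMode(mode)
    if mode in (GaitMode.walking, GaitMode.running):
        if params.step_frequency or params.step_height:
            raise DomainError(f"stepping parameters set for {mode.value} gait")
        v, g = params.speed, params.grade
        if mode is GaitMode.walking:
            return vo2_rest + 0.1 * v + 1.8 * v * g
        return vo2_rest + 0.2 * v + 0.9 * v * g
    if params.speed or params.grade:
        raise DomainError("walking/running parameters set for stepping gait")
    f, h = params.step_frequency, params.step_height
    return vo2_rest + 0.2 * f + 1.33 * 1.8 * h * f


def wr_energy_equivalent(vo2: float, bw: float, t_start: float, t_end: float) -> float:
    """Session work-rate surrogate for walking/running/stepping.

    Computed as VO2 · BW · (t_end − t_start) · 5·10⁻³ · 1.163, converting the
    oxygen consumed over the session to Watt through the 5 kcal·l⁻¹ O2 caloric
    equivalent. The duration factor makes the quantity energy-like despite its
    Watt label; it is provided exactly in this conventional form (see the
    methods note).
    """
    if not t_end > t_start:
        if t_end == t_start:
            return 0.0
        raise DomainError("t_end must be >= t_start")
    return vo2 * bw * (t_end - t_start) * 5e-3 * 1.163


def tv_from_gait(
    params: GaitParameters,
    vo2_rest: float = VO2_REST_DEFAULT,
    mode: GaitMode | str = GaitMode.walking,
    vo2max: float = 0.0,
) -> float:
    """Relative intensity (%VO2max) implied by gait kinematics.

    Composes the ACSM oxygen-cost equation with the inverted intensity
    relation: Tv = 100·VO2/VO2max. Raises if the implied intensity exceeds
    maximal capacity.
    """
    if not vo2max > 0:
        raise DomainError("vo2max must be positive")
    vo2 = vo2_from_gait(params, vo2_rest, mode)
    tv = 100.0 * vo2 / vo2max
    if tv > 100.0:
        raise DomainError(
            f"gait implies Tv={tv:.1f} %VO2max, exceeding maximal aerobic capacity"
        )
    return tv
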