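"""Fixtures for the six published validation-study protocols.

Every other module is testable without downloads: this module encodes the
studies' subject ranges and exercise prescriptions, builds runnable
:class:`~exermet.prescription.ExerciseProtocol` objects from them, constructs
the extremal ("corner") subjects whose simulated envelope brackets the group
response, and generates synthetic noisy hormone observations under the
4%-CV Gaussian measurement-error model used for parameter estimation.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .estimation import ObservationSet
from .prescription import ExerciseProtocol, ExerciseSegment, Modality
from .simulate import Trajectory
from .subject import Gender, SubjectProfile

__all__ = [
    "StudyGroup",
    "StudyVariant",
    "StudyProtocol",
    "get_study_protocol",
    "list_studies",
    "build_protocol",
    "extremal_subjects",
    "reference_subject",
    "generate_observations",
    "STUDY3_SAMPLE_TIMES",
]

#: Estimation sampling design for the 60-min bout with 30-min baseline:
#: every 10 min from -30 to +180 min around exercise onset (onset at t=30).
STUDY3_SAMPLE_TIMES = np.arange(0.0, 211.0, 10.0)


class StudyGroup(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    label: str
    n_male: int = Field(ge=0)
    n_female: int = Field(ge=0)
    age: Tuple[int, int]
    body_weight: Tuple[float, float]
    height: Tuple[float, float]
    vo2max: float = Field(gt=0)

    @model_validator(mode="after")
    def _ranges(self) -> "StudyGroup":
        for name in ("age", "body_weight", "height"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range must satisfy lo <= hi")
        if self.n_male + self.n_female == 0:
            raise ValueError("group must contain at least one subject")
        return self

    @property
    def gender(self) -> Gender:
        return Gender.male if self.n_male >= self.n_female else Gender.female


class StudyVariant(BaseModel):
    """One exercise prescription of a study (some studies ran several)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    label: str
    baseline_min: float = Field(ge=0)
    recovery_min: float = Field(ge=0)
    segments: List[dict]

    @model_validator(mode="after")
    def _segments(self) -> "StudyVariant":
        if not self.segments:
            raise ValueError("variant needs at least one segment")
        for seg in self.segments:
            if seg["duration_min"] <= 0 or not 0 < seg["tv"] <= 100:
                raise ValueError("segment needs duration > 0 and 0 < tv <= 100")
        return self


class StudyProtocol(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    study_id: int = Field(ge=1, le=6)
    label: str
    groups: List[StudyGroup]
    protocols: List[StudyVariant]
    observables: dict
    unsupported_observables: List[str] = Field(default_factory=list)
    notes: Optional[str] = None


@lru_cache(maxsize=1)
def _load_studies() -> dict[int, StudyProtocol]:
    res = resources.files("exermet.data") / "studies.json"
    raw = json.loads(res.read_text())
    out = {}
    for entry in raw["studies"]:
        sp = StudyProtocol(**entry)
        out[sp.study_id] = sp
    return out


def list_studies() -> List[StudyProtocol]:
    return [s for _, s in sorted(_load_studies().items())]


def get_study_protocol(study_id: int) -> StudyProtocol:
    """The encoded protocol of one validation study (ids 1-6)."""
    studies = _load_studies()
    if study_id not in studies:
        raise KeyError(
            f"unknown study id {study_id}; valid ids: {sorted(studies)}"
        )
    return studies[study_id]


def build_protocol(
    study: StudyProtocol | int,
    variant: int | str = 0,
    seven_minute_variant: bool = False,
) -> ExerciseProtocol:
    """Runnable exercise protocol for a study variant.

    Time zero is simulation start; exercise begins after the variant's
    baseline period, and contiguous incremental stages are chained.
    ``seven_minute_variant`` shortens every stage of the incremental study
    to 7 min (the narrative description) instead of the tabulated 8 min.
    """
    if isinstance(study, int):
        study = get_study_protocol(study)
    if isinstance(variant, str):
        matches = [v for v in study.protocols if v.label == variant]
        if not matches:
            raise KeyError(
                f"study {study.study_id} has no variant {variant!r}; "
                f"available: {[v.label for v in study.protocols]}"
            )
        var = matches[0]
    else:
        var = study.protocols[variant]
    t = var.baseline_min
    segments = []
    for seg in var.segments:
        dur = 7.0 if seven_minute_variant else float(seg["duration_min"])
        segments.append(
            ExerciseSegment(
                t_start=t, t_end=t + dur, tv=float(seg["tv"]),
                above_lt=bool(seg.get("above_lt", False)),
            )
        )
        t += dur
    return ExerciseProtocol(modality=Modality.leg_cycling, segments=segments)


def extremal_subjects(study: StudyProtocol | int) -> List[SubjectProfile]:
    """Corner subjects spanning each group's (age, body weight) ranges.

    All min/max combinations per sex group — the envelope construction: the
    simulated responses of interior subjects lie within the pointwise band of
    these corners for outputs monotone in the swept characteristics.
    Degenerate ranges (lo == hi) collapse their corners.
    """
    if isinstance(study, int):
        study = get_study_protocol(study)
    subjects: List[SubjectProfile] = []
    for group in study.groups:
        seen = set()
        for age in sorted(set(group.age)):
            for bw in sorted(set(group.body_weight)):
                key = (group.gender, age, bw)
                if key in seen:
                    continue
                seen.add(key)
                subjects.append(
                    SubjectProfile(
                        gender=group.gender,
                        age=int(age),
                        body_weight=float(bw),
                        vo2max_override=group.vo2max,
                    )
                )
    return subjects


def reference_subject(study_id: int = 3) -> SubjectProfile:
    """The canonical fitting subject: 25-y, 70-kg male at the study's VO2max.

    70 kg is the classical reference body weight and lies inside the
    estimation study's 66-85 kg range.
    """
    study = get_study_protocol(study_id)
    return SubjectProfile(
        gender=Gender.male, age=25, body_weight=70.0,
        vo2max_override=study.groups[0].vo2max,
    )


def generate_observations(
    traj: Trajectory,
    times: Sequence[float],
    cv: float = 0.04,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ObservationSet:
    """Noisy insulin/glucagon observations from a simulated trajectory.

    observed = simulated·(1 + cv·z) with z standard normal per point,
    independently for the two hormones; non-positive draws are re-sampled so
    concentrations stay physical. ``cv = 0`` returns the noise-free series.
    Reproducible for a fixed ``seed``.
    """
    t = np.asarray(times, dtype=float)
    if t.min() < traj.times[0] or t.max() > traj.times[-1]:
        raise ValueError("observation times outside the trajectory span")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    sampled = traj.interp(t)
    if rng is None:
        rng = np.random.default_rng(seed)

    def noisy(clean: np.ndarray) -> np.ndarray:
        if cv == 0:
            return clean.copy()
        out = clean * (1.0 + cv * rng.standard_normal(clean.size))
        bad = out <= 0
        while np.any(bad):  # redraw non-positive values
            out[bad] = clean[bad] * (1.0 + cv * rng.standard_normal(int(bad.sum())))
            bad = out <= 0
        return out

    return ObservationSet(
        times=t,
        insulin_obs=noisy(sampled.ci),
        glucagon_obs=noisy(sampled.cg),
        cv=cv if cv > 0 else 0.04,
        meta={"seed": seed, "generating_cv": cv},
    )
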