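"""Subject description and resolution of maximal oxygen uptake.

The simulator personalizes exercise by *relative* intensity, expressed as a
percentage of the subject's maximal oxygen uptake (VO2max, ml·kg⁻¹·min⁻¹).
VO2max is either supplied directly (measured in the laboratory or imposed by a
validation protocol) or resolved from a normative table keyed by gender,
decadal age bracket and cardiorespiratory fitness category.
"""

from __future__ import annotations

import enum
import warnings
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import DomainError, TableLookupError

__all__ = [
    "Gender",
    "FitnessStatus",
    "SubjectProfile",
    "NormativeVo2maxTable",
    "default_norms_table",
    "resolve_vo2max",
    "target_vo2",
]


class Gender(str, enum.Enum):
    male = "male"
    female = "female"


class FitnessStatus(str, enum.Enum):
    """Ordinal cardiorespiratory fitness classification, poor → superior."""

    poor = "poor"
    fair = "fair"
    good = "good"
    excellent = "excellent"
    superior = "superior"

    @property
    def rank(self) -> int:
        return list(FitnessStatus).index(self)


class SubjectProfile(BaseModel):
    """The person performing exercise.

    Parameters
    ----------
    gender : {"male", "female"}
    age : int
        Years. Accepted range 10–100; a warning is issued outside 20–40, the
        range in which the hormonal model has been validated.
    body_weight : float
        kg, strictly positive.
    fitness_status : FitnessStatus, optional
        Required only when ``vo2max_override`` is absent.
    vo2max_override : float, optional
        Measured or imposed VO2max in ml·kg⁻¹·min⁻¹; takes precedence over any
        normative-table lookup.
    """

    model_config = ConfigDict(extra="forbid", frozen=True, use_enum_values=False)

    gender: Gender
    age: int = Field(ge=10, le=100)
    body_weight: float = Field(gt=0)
    fitness_status: Optional[FitnessStatus] = None
    vo2max_override: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "SubjectProfile":
        if not (20 <= self.age <= 40):
            warnings.warn(
                f"subject age {self.age} is outside the validated 20-40 y range; "
                "hormonal responses are extrapolated",
                stacklevel=2,
            )
        if self.fitness_status is None and self.vo2max_override is None:
            raise ValueError(
                "either fitness_status (for normative lookup) or vo2max_override "
                "must be provided"
            )
        return self


class NormativeVo2maxTable:
    """Normative VO2max values keyed by (gender, age bracket, fitness category).

    Brackets are decadal and clamped at the extremes: an age below the lowest
    bracket resolves to the lowest, above the highest to the highest.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"gender", "age_lo", "age_hi", "category", "vo2max_ml_kg_min"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"normative table missing columns: {sorted(missing)}")
        self._frame = frame.reset_index(drop=True)
        self._validate()

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormativeVo2maxTable":
        return cls(pd.read_csv(path, comment="#"))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def _validate(self) -> None:
        df = self._frame
        if (df["vo2max_ml_kg_min"] <= 0).any():
            raise ValueError("normative table contains non-positive VO2max values")
        brackets = df[["age_lo", "age_hi"]].drop_duplicates()
        for gender in Gender:
            for _, (lo, hi) in brackets.iterrows():
                sub = df[
                    (df["gender"] == gender.value)
                    & (df["age_lo"] == lo)
                    & (df["age_hi"] == hi)
                ]
                cats = {c.value for c in FitnessStatus}
                present = set(sub["category"])
                if present != cats:
                    raise ValueError(
                        f"incomplete coverage for ({gender.value}, {lo}-{hi}): "
                        f"missing {sorted(cats - present)}"
                    )
                ordered = sub.set_index("category").loc[
                    [c.value for c in FitnessStatus], "vo2max_ml_kg_min"
                ]
                if not ordered.is_monotonic_increasing or ordered.duplicated().any():
                    raise ValueError(
                        f"VO2max must increase strictly with fitness category for "
                        f"({gender.value}, {lo}-{hi})"
                    )

    def _bracket(self, age: int) -> tuple[int, int]:
        brackets = (
            self._frame[["age_lo", "age_hi"]]
            .drop_duplicates()
            .sort_values("age_lo")
            .to_numpy()
        )
        for lo, hi in brackets:
            if lo <= age <= hi:
                return int(lo), int(hi)
        # clamp to nearest bracket at the extremes
        if age < brackets[0][0]:
            return int(brackets[0][0]), int(brackets[0][1])
        return int(brackets[-1][0]), int(brackets[-1][1])

    def lookup(self, gender: Gender, age: int, category: FitnessStatus) -> float:
        lo, hi = self._bracket(age)
        df = self._frame
        row = df[
            (df["gender"] == Gender(gender).value)
            & (df["age_lo"] == lo)
            & (df["age_hi"] == hi)
            & (df["category"] == FitnessStatus(category).value)
        ]
        if row.empty:
            raise TableLookupError(
                f"no normative VO2max entry for ({Gender(gender).value}, "
                f"age {age} [{lo}-{hi}], {FitnessStatus(category).value})"
            )
        return float(row["vo2max_ml_kg_min"].iloc[0])


@lru_cache(maxsize=1)
def default_norms_table() -> NormativeVo2maxTable:
    """The packaged normative table (external reference data, see file header)."""
    path = resources.files("exermet.data") / "vo2max_norms.csv"
    with resources.as_file(path) as p:
        return NormativeVo2maxTable.from_csv(p)


def resolve_vo2max(
    subject: SubjectProfile, table: NormativeVo2maxTable | None = None
) -> float:
    """Resolve the subject's VO2max in ml·kg⁻¹·min⁻¹.

    An explicit ``vo2max_override`` always wins; otherwise the normative table
    is consulted with the subject's gender, age bracket and fitness category.
    """
    if subject.vo2max_override is not None:
        return float(subject.vo2max_override)
    if subject.fitness_status is None:  # pragma: no cover - blocked by validator
        raise TableLookupError("subject has neither vo2max_override nor fitness_status")
    table = table if table is not None else default_norms_table()
    value = table.lookup(subject.gender, subject.age, subject.fitness_status)
    if not value > 0:  # pragma: no cover - blocked by table validation
        raise TableLookupError("normative table returned a non-positive VO2max")
    return value


def target_vo2(tv: float, vo2max: float) -> float:
    """Steady-state oxygen consumption at relative intensity ``tv`` (%VO2max).

    VO2 = Tv · VO2max / 100, in ml·kg⁻¹·min⁻¹. The model is restricted to
    sub-maximal exercise, so ``tv`` must lie in [0, 100].
    """
    if not 0 <= tv <= 100:
        raise DomainError(
            f"relative intensity Tv={tv} outside [0, 100] %VO2max "
            "(model valid for sub-maximal exercise only)"
        )
    if not vo2max > 0:
        raise DomainError("vo2max must be positive")
    return tv * vo2max / 100.0
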