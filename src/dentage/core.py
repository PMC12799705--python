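"""Domain model: teeth, developmental stages, charts and subjects.

The package works on the seven left mandibular teeth in FDI notation
(31 central incisor .. 37 second molar), each staged on the eight-stage
A-H mineralization scale (A = initial crown calcification, H = apical
closure).  Sexes are coded ``"F"``/``"M"``; every reference table in the
method is sex-specific.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import InvalidStage, MissingTooth

#: FDI codes of the seven left mandibular teeth, incisor to second molar.
FDI_TEETH: tuple[int, ...] = (31, 32, 33, 34, 35, 36, 37)

#: Conventional short labels for the seven teeth.
TOOTH_LABELS: dict[int, str] = {
    31: "CI", 32: "LI", 33: "C", 34: "PM1", 35: "PM2", 36: "M1", 37: "M2",
}
LABEL_TO_FDI: dict[str, int] = {v: k for k, v in TOOTH_LABELS.items()}

#: The eight ordered mineralization stages.
STAGES: str = "ABCDEFGH"

#: Valid sex codes.
SEXES: tuple[str, str] = ("F", "M")

#: Days per year used when deriving a decimal age from calendar dates.
DAYS_PER_YEAR: float = 365.25


def stage_index(stage: str) -> int:
    """Position of ``stage`` in the A-H order (A -> 0, H -> 7)."""
    stage = validate_stage(stage)
    return STAGES.index(stage)


def validate_stage(stage: str) -> str:
    """Return the canonical (uppercase) stage letter or raise :class:`InvalidStage`."""
    if not isinstance(stage, str) or stage.upper() not in STAGES:
        raise InvalidStage(f"stage must be one of {'/'.join(STAGES)}, got {stage!r}")
    return stage.upper()


def validate_sex(sex: str) -> str:
    if not isinstance(sex, str) or sex.upper() not in SEXES:
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    return sex.upper()


def validate_tooth(fdi: int) -> int:
    fdi = int(fdi)
    if fdi not in FDI_TEETH:
        raise ValueError(f"tooth must be an FDI code in {FDI_TEETH}, got {fdi}")
    return fdi


@dataclass(frozen=True)
class DentalChart:
    """One A-H stage for each of the seven left mandibular teeth.

    ``stages`` maps FDI code -> stage letter.  Charts are only usable for
    scoring once complete; :func:`validate_chart` enforces that.
    """

    stages: Mapping[int, str]

    @classmethod
    def from_sequence(cls, stages: Sequence[str]) -> "DentalChart":
        """Build a chart from seven stage letters ordered 31..37."""
        if len(stages) != len(FDI_TEETH):
            raise MissingTooth([t for t in FDI_TEETH[len(stages):]])
        return cls(dict(zip(FDI_TEETH, stages)))

    def stage(self, fdi: int) -> str:
        return self.stages[validate_tooth(fdi)]

    def as_tuple(self) -> tuple[str, ...]:
        """Stages in FDI order 31..37."""
        return tuple(self.stages[t] for t in FDI_TEETH)


def validate_chart(chart: DentalChart | Mapping[int, str]) -> DentalChart:
    """Check completeness (all seven teeth) and stage alphabet; return the chart.

    Raises :class:`MissingTooth` listing absent FDI codes, or
    :class:`InvalidStage` for a label outside A-H.  Stage letters are
    canonicalized to uppercase.
    """
    stages = chart.stages if isinstance(chart, DentalChart) else chart
    cleaned: dict[int, str] = {}
    for fdi, stage in stages.items():
        cleaned[validate_tooth(fdi)] = validate_stage(stage)
    missing = [t for t in FDI_TEETH if t not in cleaned]
    if missing:
        raise MissingTooth(missing)
    return DentalChart(cleaned)


def age_from_dates(birth_date: _dt.date, exam_date: _dt.date) -> float:
    """Chronological age in decimal years: (exam - birth) / 365.25, 2 dp."""
    days = (exam_date - birth_date).days
    return round(days / DAYS_PER_YEAR, 2)


@dataclass(frozen=True)
class Subject:
    """A staged individual: id, sex, chronological age and dental chart."""

    id: str
    sex: str
    chronological_age: float
    chart: DentalChart
    birth_date: Optional[_dt.date] = field(default=None, compare=False)
    exam_date: Optional[_dt.date] = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "sex", validate_sex(self.sex))
        object.__setattr__(self, "chart", validate_chart(self.chart))
        if not 0 < self.chronological_age < 25:
            raise ValueError(
                f"chronological age must be in (0, 25) years, got {self.chronological_age}"
            )
        if self.birth_date is not None and self.exam_date is not None:
            derived = age_from_dates(self.birth_date, self.exam_date)
            if abs(derived - self.chronological_age) > 0.02:
                raise ValueError(
                    f"subject {self.id}: age {self.chronological_age} disagrees with "
                    f"dates ({derived} from birth/exam)"
                )

    @classmethod
    def from_dates(
        cls,
        id: str,
        sex: str,
        birth_date: _dt.date,
        exam_date: _dt.date,
        chart: DentalChart,
    ) -> "Subject":
        return cls(
            id=id,
            sex=sex,
            chronological_age=age_from_dates(birth_date, exam_date),
            chart=chart,
            birth_date=birth_date,
            exam_date=exam_date,
        )
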