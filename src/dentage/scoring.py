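"""Maturity scoring: look up per-tooth scores and sum them per subject.

This is the second step of the staging method: each staged tooth receives
the population table's score for its (sex, tooth, stage) cell and the seven
contributions are summed into the subject's maturity score.  Scores are
categorical lookups — never interpolated between stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .core import FDI_TEETH, DentalChart, Subject, validate_chart
from .tables import MaturityScoreTable

__all__ = ["MaturityScore", "lookup_score", "score_chart", "total_maturity_score"]


@dataclass(frozen=True)
class MaturityScore:
    """A subject's summed maturity score with its per-tooth breakdown."""

    total: float
    per_tooth: Mapping[int, float]

    def __post_init__(self):
        assert abs(self.total - round(sum(self.per_tooth.values()), 10)) < 1e-9


def lookup_score(table: MaturityScoreTable, sex: str, tooth: int, stage: str) -> float:
    """Score for one (sex, tooth, stage) cell.

    Raises :class:`~dentage.errors.StageBelowCoverage` when the stage precedes
    the table's first scored stage for that tooth.
    """
    return table.score(sex, tooth, stage)


def score_chart(table: MaturityScoreTable, sex: str, chart: DentalChart) -> MaturityScore:
    """Sum the seven per-tooth scores for a validated chart."""
    chart = validate_chart(chart)
    per_tooth = {fdi: table.score(sex, fdi, chart.stage(fdi)) for fdi in FDI_TEETH}
    return MaturityScore(total=round(sum(per_tooth.values()), 10), per_tooth=per_tooth)


def total_maturity_score(table: MaturityScoreTable, subject: Subject) -> MaturityScore:
    """Summed maturity score for a subject under ``table``."""
    return score_chart(table, subject.sex, subject.chart)
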