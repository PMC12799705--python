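"""Population-specific calibration of maturity scores and conversion grids.

Given a staged cohort with known chronological ages, calibration re-derives
both reference tables for that population:

1. **Stage scores.**  For every (sex, tooth, stage) cell with at least
   ``min_n`` subjects, the central (default: median) chronological age of the
   subjects whose tooth is in that stage becomes the cell's maturity score
   (rounded to 0.1 yr).  This makes the seven-tooth summed score a
   years-equivalents maturity index for the population.
2. **Conversion grid.**  Each subject is re-scored under the new table, the
   per-integer-age-bin median summed scores become (age, score) anchors
   (pool-adjacent-violators repair if small-sample medians invert), a
   monotone 4PL logistic curve is fitted through the anchors, and the curve
   is discretized onto the 6.0-16.0 / 0.1-yr grid.

The public surface follows the statsmodels convention: build a
:class:`DentalMaturityModel` from a cohort (or DataFrame), call ``fit()``,
and read tables, anchors, curves and diagnostics off the returned
:class:`DentalMaturityResults`.  The module-level functions expose each step
individually.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .core import FDI_TEETH, STAGES, DentalChart, Subject
from .errors import (
    EmptyCohort,
    InvariantViolation,
    NoStageHCoverage,
    SparseBin,
    StageBelowCoverage,
)
from .scoring import total_maturity_score
from .tables import ConversionGrid, MaturityScoreTable, ReferenceTables, dump_reference_tables
from .conversion import LogisticCurve, curve_to_grid, fit_logistic

__all__ = [
    "CohortDataset",
    "DentalMaturityModel",
    "DentalMaturityResults",
    "CalibrationResult",
    "stage_median_ages",
    "derive_score_table",
    "summed_score_anchors",
    "calibrate_population",
    "percentile_curves",
    "filter_scoreable",
    "split_cohort",
]

#: Default minimum cell / bin occupancy.  Ten subjects per age and sex group
#: is the accepted lower bound for building dental maturity references while
#: limiting age-mimicry risk.
DEFAULT_MIN_N = 10


@dataclass(frozen=True)
class CohortDataset:
    """A list of staged subjects with a provenance note."""

    subjects: Tuple[Subject, ...]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "subjects", tuple(self.subjects))

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(sorted({s.sex for s in self.subjects}))

    def filter(self, predicate) -> "CohortDataset":
        return CohortDataset(
            subjects=tuple(s for s in self.subjects if predicate(s)),
            provenance=self.provenance,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Standard staging frame: subject_id, sex, age, t31..t37."""
        rows = [
            {
                "subject_id": s.id,
                "sex": s.sex,
                "age": s.chronological_age,
                **{f"t{fdi}": s.chart.stage(fdi) for fdi in FDI_TEETH},
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "CohortDataset":
        subjects = [
            Subject(
                id=str(row["subject_id"]),
                sex=row["sex"],
                chronological_age=float(row["age"]),
                chart=DentalChart({fdi: row[f"t{fdi}"] for fdi in FDI_TEETH}),
            )
            for _, row in df.iterrows()
        ]
        return cls(subjects=tuple(subjects), provenance=provenance)


def _cohort_frame(cohort: CohortDataset) -> pd.DataFrame:
    if len(cohort) == 0:
        raise EmptyCohort("cohort has no subjects")
    return cohort.to_dataframe()


def stage_median_ages(
    cohort: CohortDataset,
    estimator: str = "median",
    min_n: int = DEFAULT_MIN_N,
) -> Tuple[Dict[Tuple[str, int, str], float], pd.DataFrame]:
    """Central chronological age for every observed (sex, tooth, stage) cell.

    Returns ``(cells, diagnostics)``: ``cells`` maps each cell with
    ``n >= min_n`` to its central age; ``diagnostics`` lists every observed
    cell with n, center, quartiles and whether it met ``min_n``.
    """
    if estimator not in ("median", "mean"):
        raise ValueError(f"estimator must be 'median' or 'mean', got {estimator!r}")
    df = _cohort_frame(cohort)
    records = []
    cells: Dict[Tuple[str, int, str], float] = {}
    for fdi in FDI_TEETH:
        grouped = df.groupby(["sex", f"t{fdi}"], sort=True)["age"]
        stats = grouped.agg(
            n="count",
            center=estimator,
            q25=lambda a: float(np.quantile(a, 0.25)),
            q75=lambda a: float(np.quantile(a, 0.75)),
        )
        for (sex, stage), row in stats.iterrows():
            included = row["n"] >= min_n
            records.append(
                {
                    "sex": sex, "fdi": fdi, "stage": stage, "n": int(row["n"]),
                    "center": float(row["center"]), "q25": row["q25"], "q75": row["q75"],
                    "included": bool(included),
                }
            )
            if included:
                cells[(sex, fdi, stage)] = float(row["center"])
    diagnostics = pd.DataFrame.from_records(records).sort_values(
        ["sex", "fdi", "stage"], ignore_index=True
    )
    return cells, diagnostics


def derive_score_table(
    cell_ages: Mapping[Tuple[str, int, str], float],
    population: str = "custom",
    fallback_centers: Optional[Mapping[Tuple[str, int, str], float]] = None,
) -> MaturityScoreTable:
    """Turn per-cell central ages into a maturity-score table (0.1-yr precision).

    A tooth's scored stages must form a contiguous run ending at stage H
    (the structure every published table has).  The occupancy threshold
    trims *leading* low-coverage stages — the table simply starts later —
    but an interior hole cannot be dropped without making every subject
    observed in that stage unscoreable, so holes are filled: from
    ``fallback_centers`` (low-n observed centers) when available, otherwise
    by the midpoint of the adjacent stages' scores.  Raises
    :class:`NoStageHCoverage` when a tooth has no stage-H cell — such a
    table could not score mature subjects.
    """
    if not cell_ages:
        raise EmptyCohort("no cells survived the occupancy threshold")
    fallback_centers = fallback_centers or {}
    scores: Dict[Tuple[str, int, str], float] = {}
    keys = {(sex, fdi) for sex, fdi, _ in cell_ages}
    for sex, fdi in sorted(keys):
        covered = [s for s in STAGES if (sex, fdi, s) in cell_ages]
        if "H" not in covered:
            raise NoStageHCoverage(
                f"tooth {fdi} ({sex}) has no stage-H data; the derived table "
                "would be unusable for mature subjects"
            )
        run = STAGES[STAGES.index(covered[0]):]  # first well-supported stage .. H
        for i, s in enumerate(run):
            key = (sex, fdi, s)
            if key in cell_ages:
                value = cell_ages[key]
            elif key in fallback_centers:
                value = fallback_centers[key]
            else:
                prev = next(v for v in (scores.get((sex, fdi, t)) for t in reversed(run[:i])) if v is not None)
                nxt = next(
                    cell_ages.get((sex, fdi, t), fallback_centers.get((sex, fdi, t)))
                    for t in run[i + 1:]
                    if (sex, fdi, t) in cell_ages or (sex, fdi, t) in fallback_centers
                )
                value = (prev + nxt) / 2.0
            scores[key] = round(value, 1)
    return MaturityScoreTable(population=population, scores=scores)


def _age_bin(age: float) -> int:
    # completed years: bin k covers [k, k+1)
    return int(math.floor(age))


@dataclass(frozen=True)
class AnchorSet:
    """Per-sex (age, summed-score) anchors with repair bookkeeping."""

    anchors: Mapping[str, Tuple[Tuple[float, float], ...]]
    repaired: Mapping[str, bool]
    bin_counts: Mapping[str, Mapping[int, int]]


def summed_score_anchors(
    cohort: CohortDataset,
    score_table: MaturityScoreTable,
    min_n: int = DEFAULT_MIN_N,
) -> AnchorSet:
    """Median summed maturity score per (sex, integer-age bin).

    Subjects are binned by completed years (bin k = [k, k+1)); each bin
    contributes one anchor at (median age in bin, median summed score).
    Bins with fewer than ``min_n`` subjects raise :class:`SparseBin`.
    Non-monotone score sequences are repaired by pool-adjacent-violators
    (weighted by bin size) and flagged.
    """
    if len(cohort) == 0:
        raise EmptyCohort("cohort has no subjects")
    totals = {
        s.id: total_maturity_score(score_table, s).total for s in cohort.subjects
    }
    anchors: Dict[str, Tuple[Tuple[float, float], ...]] = {}
    repaired: Dict[str, bool] = {}
    bin_counts: Dict[str, Dict[int, int]] = {}
    for sex in cohort.sexes:
        subs = [s for s in cohort.subjects if s.sex == sex]
        bins: Dict[int, list] = {}
        for s in subs:
            bins.setdefault(_age_bin(s.chronological_age), []).append(s)
        sparse = {k: len(v) for k, v in bins.items() if len(v) < min_n}
        if sparse:
            raise SparseBin(
                f"sex {sex}: age bins below min_n={min_n}: "
                + ", ".join(f"{k} (n={n})" for k, n in sorted(sparse.items()))
            )
        ages, scores, weights = [], [], []
        for k in sorted(bins):
            members = bins[k]
            ages.append(float(np.median([s.chronological_age for s in members])))
            scores.append(float(np.median([totals[s.id] for s in members])))
            weights.append(len(members))
        raw = np.asarray(scores)
        fixed = isotonic_regression(raw, weights=np.asarray(weights, dtype=float)).x
        repaired[sex] = bool(np.any(np.abs(fixed - raw) > 1e-12))
        anchors[sex] = tuple(zip(ages, (float(v) for v in fixed)))
        bin_counts[sex] = {k: len(bins[k]) for k in sorted(bins)}
    return AnchorSet(anchors=anchors, repaired=repaired, bin_counts=bin_counts)


def percentile_curves(
    cohort: CohortDataset,
    score_table: MaturityScoreTable,
    q: Sequence[float] = (0.10, 0.50, 0.90),
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """Empirical summed-score quantiles per (sex, integer-age bin).

    Quantiles use the type-7 (linear-interpolation) definition, numpy's
    default.  Returns a long-format frame: sex, age_bin, n, q, score.
    """
    if len(cohort) == 0:
        raise EmptyCohort("cohort has no subjects")
    rows = []
    for sex in cohort.sexes:
        subs = [s for s in cohort.subjects if s.sex == sex]
        bins: Dict[int, list] = {}
        for s in subs:
            bins.setdefault(_age_bin(s.chronological_age), []).append(s)
        sparse = {k: len(v) for k, v in bins.items() if len(v) < min_n}
        if sparse:
            raise SparseBin(
                f"sex {sex}: age bins below min_n={min_n}: "
                + ", ".join(f"{k} (n={n})" for k, n in sorted(sparse.items()))
            )
        for k in sorted(bins):
            totals = [total_maturity_score(score_table, s).total for s in bins[k]]
            for qq in q:
                rows.append(
                    {
                        "sex": sex, "age_bin": k, "n": len(totals), "q": float(qq),
                        "score": float(np.quantile(totals, qq)),
                    }
                )
    return pd.DataFrame(rows)


def _strictify(anchors: Sequence[Tuple[float, float]], eps: float = 0.01):
    """Break PAV ties so the logistic fitter sees strictly increasing scores."""
    out, nudged = [], False
    prev = -np.inf
    for age, score in anchors:
        if score <= prev:
            score = prev + eps
            nudged = True
        out.append((age, score))
        prev = score
    return out, nudged


class DentalMaturityModel:
    """Calibration model for population-specific dental maturity references.

    Parameters
    ----------
    cohort : CohortDataset
        Staged subjects with chronological ages.  All ages must fall inside
        ``age_window`` and each sex present must span at least five integer
        age bins.
    population : str
        Identifier stamped into the derived tables.
    estimator : {"median", "mean"}
        Central-age estimator per stage cell.  The median is the default;
        the mean is offered because both conventions exist in practice.
    min_n : int
        Minimum subjects per stage cell and per age bin (default 10).
    age_window : (float, float)
        Half-open admissible chronological-age window, default [6, 17).

    Examples
    --------
    >>> model = DentalMaturityModel(cohort, population="mypop")
    >>> res = model.fit()
    >>> res.score_table.score("F", 37, "H")
    >>> print(res.summary())
    """

    def __init__(
        self,
        cohort: CohortDataset,
        *,
        population: str = "custom",
        estimator: str = "median",
        min_n: int = DEFAULT_MIN_N,
        age_window: Tuple[float, float] = (6.0, 17.0),
    ):
        if len(cohort) == 0:
            raise EmptyCohort("cohort has no subjects")
        lo, hi = age_window
        out = [s for s in cohort.subjects if not lo <= s.chronological_age < hi]
        if out:
            raise InvariantViolation(
                f"{len(out)} subject(s) outside the declared age window [{lo}, {hi}): "
                + ", ".join(s.id for s in out[:5])
                + ("..." if len(out) > 5 else "")
            )
        for sex in cohort.sexes:
            bins = {_age_bin(s.chronological_age) for s in cohort.subjects if s.sex == sex}
            if len(bins) < 5:
                raise InvariantViolation(
                    f"sex {sex} spans only {len(bins)} integer-age bins; at least 5 "
                    "are needed to anchor a conversion curve"
                )
        self.cohort = cohort
        self.population = population
        self.estimator = estimator
        self.min_n = min_n
        self.age_window = age_window

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "", **kwargs) -> "DentalMaturityModel":
        """Build the model from a standard staging frame (subject_id, sex, age, t31..t37)."""
        return cls(CohortDataset.from_dataframe(df, provenance=provenance), **kwargs)

    def fit(self) -> "DentalMaturityResults":
        """Run the full calibration pipeline and return the results object."""
        cells, diagnostics = stage_median_ages(
            self.cohort, estimator=self.estimator, min_n=self.min_n
        )
        fallback = {
            (r.sex, r.fdi, r.stage): r.center
            for r in diagnostics.itertuples()
            if not r.included
        }
        score_table = derive_score_table(
            cells, population=self.population, fallback_centers=fallback
        )
        filled = sorted(key for key in score_table.scores if key not in cells)
        # subjects staged below the derived table's coverage (their cell fell
        # under min_n) cannot be scored; they are excluded from the anchor
        # step and reported, rather than silently scored as zero
        anchor_cohort, excluded = filter_scoreable(self.cohort, score_table)
        anchor_set = summed_score_anchors(anchor_cohort, score_table, min_n=self.min_n)
        curves: Dict[str, LogisticCurve] = {}
        grids: Dict[str, ConversionGrid] = {}
        tie_nudged: Dict[str, bool] = {}
        for sex, anchors in anchor_set.anchors.items():
            strict, nudged = _strictify(anchors)
            tie_nudged[sex] = nudged
            curves[sex] = fit_logistic(strict)
            grids[sex] = curve_to_grid(curves[sex], sex)
        return DentalMaturityResults(
            model=self,
            score_table=score_table,
            grids=grids,
            curves=curves,
            anchor_set=anchor_set,
            anchor_tie_nudged=tie_nudged,
            diagnostics=diagnostics,
            filled_cells=tuple(filled),
            unscoreable_ids=tuple(excluded),
        )


@dataclass(frozen=True)
class DentalMaturityResults:
    """Fitted calibration: derived tables, curves, anchors and diagnostics."""

    model: DentalMaturityModel = field(repr=False)
    score_table: MaturityScoreTable
    grids: Mapping[str, ConversionGrid]
    curves: Mapping[str, LogisticCurve]
    anchor_set: AnchorSet
    anchor_tie_nudged: Mapping[str, bool]
    diagnostics: pd.DataFrame = field(repr=False)
    filled_cells: Tuple[Tuple[str, int, str], ...] = ()
    unscoreable_ids: Tuple[str, ...] = ()

    @property
    def population(self) -> str:
        return self.score_table.population

    @property
    def anchors(self) -> Mapping[str, Tuple[Tuple[float, float], ...]]:
        return self.anchor_set.anchors

    def to_reference_tables(self) -> ReferenceTables:
        return ReferenceTables(score_table=self.score_table, grids=dict(self.grids))

    def save(self, path, include_diagnostics: bool = True) -> None:
        """Write the derived tables as a reference JSON file."""
        diag = None
        if include_diagnostics:
            diag = {
                "estimator": self.model.estimator,
                "min_n": self.model.min_n,
                "n_subjects": len(self.model.cohort),
                "omitted_cells": [
                    f"{r.sex}/{r.fdi}/{r.stage} (n={r.n})"
                    for r in self.diagnostics.itertuples()
                    if not r.included
                ],
                "filled_cells": [f"{s}/{f}/{st}" for s, f, st in self.filled_cells],
                "anchor_repaired": {k: bool(v) for k, v in self.anchor_set.repaired.items()},
            }
        dump_reference_tables(self.to_reference_tables(), path, diagnostics=diag)

    def summary(self) -> str:
        """Human-readable calibration report."""
        lines = [
            "Dental maturity calibration",
            "=" * 60,
            f"population:        {self.population}",
            f"subjects:          {len(self.model.cohort)}"
            + "".join(
                f"  ({sex}: {sum(1 for s in self.model.cohort.subjects if s.sex == sex)})"
                for sex in self.model.cohort.sexes
            ),
            f"estimator:         {self.model.estimator}   min_n: {self.model.min_n}",
            f"cells included:    {int(self.diagnostics['included'].sum())}"
            f" / {len(self.diagnostics)} observed",
        ]
        if self.filled_cells:
            lines.append(f"interior cells filled below min_n: {len(self.filled_cells)}")
        if self.unscoreable_ids:
            lines.append(
                f"subjects excluded from anchors (below coverage): {len(self.unscoreable_ids)}"
            )
        for sex in sorted(self.grids):
            c = self.curves[sex]
            lines += [
                "-" * 60,
                f"sex {sex}: logistic curve  A={c.lower:.2f}  K={c.upper:.2f}  "
                f"r={c.rate:.3f}/yr  m={c.midpoint:.2f} yr"
                + ("  [anchors repaired]" if self.anchor_set.repaired[sex] else ""),
                "  age bin anchors (median age, median score):",
            ]
            lines += [
                f"    {age:6.2f}  {score:7.2f}" for age, score in self.anchors[sex]
            ]
        return "\n".join(lines)


#: Alias matching the field's "calibration result" vocabulary.
CalibrationResult = DentalMaturityResults


def calibrate_population(cohort: CohortDataset, **kwargs) -> DentalMaturityResults:
    """One-call calibration: ``DentalMaturityModel(cohort, **kwargs).fit()``."""
    return DentalMaturityModel(cohort, **kwargs).fit()


def filter_scoreable(
    cohort: CohortDataset, score_table: MaturityScoreTable
) -> Tuple[CohortDataset, Tuple[str, ...]]:
    """Split off subjects whose every (tooth, stage) the table can score.

    Returns (scoreable cohort, ids of excluded subjects).  Subjects staged
    below a tooth's first scored stage cannot receive a summed score.
    """
    keep, excluded = [], []
    for subject in cohort.subjects:
        try:
            total_maturity_score(score_table, subject)
        except StageBelowCoverage:
            excluded.append(subject.id)
        else:
            keep.append(subject)
    return (
        CohortDataset(tuple(keep), provenance=cohort.provenance),
        tuple(excluded),
    )


def split_cohort(
    cohort: CohortDataset, test_fraction: float = 0.25, seed: Optional[int] = None
) -> Tuple[CohortDataset, CohortDataset]:
    """Simple seeded train/test split (no stratification guarantees)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(cohort))
    n_test = int(round(test_fraction * len(cohort)))
    test = {int(i) for i in idx[:n_test]}
    train_subjects = tuple(s for i, s in enumerate(cohort.subjects) if i not in test)
    test_subjects = tuple(s for i, s in enumerate(cohort.subjects) if i in test)
    return (
        CohortDataset(train_subjects, provenance=f"{cohort.provenance} [train]"),
        CohortDataset(test_subjects, provenance=f"{cohort.provenance} [test]"),
    )
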