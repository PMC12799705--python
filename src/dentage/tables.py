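"""Reference-table containers and their JSON serialization.

Two tables drive the method:

* :class:`MaturityScoreTable` — per (sex, tooth, stage) maturity score.  In
  the bundled Kosovar table the scores are median chronological ages in
  years, so the seven-tooth sum is on a years-equivalents scale.  Teeth
  assessed over a 6-16 year window lack early-stage observations, so scored
  stages form a contiguous run ending at stage H (right-aligned): e.g. the
  first molar carries scores only for stages E-H.
* :class:`ConversionGrid` — per sex, the summed score expected at each age
  on the 6.0-16.0 grid in 0.1-year steps (101 rows, strictly increasing).

A reference-table file stores one score table plus one grid per sex:

.. code-block:: json

    {"population": "kosovo",
     "score_table": {"F": {"31": {"D": 5.20, ...}, ...}, "M": {...}},
     "conversion": {"F": [[6.00, 48.06], ...], "M": [...]}}

Numbers are written with two decimals so that the bundled files round-trip
byte-identically through :func:`load_reference_tables` /
:func:`dump_reference_tables`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping, Tuple

import numpy as np

from .core import FDI_TEETH, SEXES, STAGES, validate_sex, validate_stage, validate_tooth
from .errors import InvariantViolation, SchemaError, StageBelowCoverage

GRID_START, GRID_STOP, GRID_STEP = 6.0, 16.0, 0.1
GRID_ROWS = 101

#: id -> resource file of tables shipped with the package.
BUILTIN_POPULATIONS = {"kosovo": "kosovo.json"}


@dataclass(frozen=True)
class MaturityScoreTable:
    """Per-(sex, tooth, stage) maturity scores for one population.

    ``scores`` maps ``(sex, fdi, stage)`` to a positive score.  The published
    table is stored verbatim: within-tooth score sequences are *not*
    guaranteed monotone (the printed Kosovar table has non-monotone runs) and
    no smoothing is ever applied to a reference.
    """

    population: str
    scores: Mapping[Tuple[str, int, str], float]

    def __post_init__(self):
        if not self.scores:
            raise InvariantViolation("empty score table")
        for (sex, fdi, stage), value in self.scores.items():
            if not (np.isfinite(value) and value > 0):
                raise InvariantViolation(
                    f"score for ({sex}, {fdi}, {stage}) must be finite and > 0, got {value}"
                )
        for sex in self.sexes:
            for fdi in self.teeth(sex):
                covered = [s for s in STAGES if (sex, fdi, s) in self.scores]
                # scored stages must be a contiguous suffix of A..H ending at H
                if STAGES[8 - len(covered):] != "".join(covered):
                    raise InvariantViolation(
                        f"stages for ({sex}, {fdi}) must be a contiguous run ending "
                        f"at H, got {''.join(covered)}"
                    )

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(s for s in SEXES if any(k[0] == s for k in self.scores))

    def teeth(self, sex: str) -> tuple[int, ...]:
        return tuple(t for t in FDI_TEETH if any(k[:2] == (sex, t) for k in self.scores))

    def stages(self, sex: str, fdi: int) -> str:
        """Scored stages for a tooth, in A-H order (a suffix ending at H)."""
        return "".join(s for s in STAGES if (sex, fdi, s) in self.scores)

    def first_stage(self, sex: str, fdi: int) -> str:
        return self.stages(sex, fdi)[0]

    def score(self, sex: str, fdi: int, stage: str) -> float:
        """The printed score, or :class:`StageBelowCoverage` for earlier stages."""
        sex, fdi, stage = validate_sex(sex), validate_tooth(fdi), validate_stage(stage)
        try:
            return self.scores[(sex, fdi, stage)]
        except KeyError:
            raise StageBelowCoverage(sex, fdi, stage, self.first_stage(sex, fdi)) from None

    def max_total(self, sex: str) -> float:
        """Summed score of a fully mature (all stage H) chart."""
        return round(sum(self.scores[(sex, t, "H")] for t in self.teeth(sex)), 10)


@dataclass(frozen=True)
class ConversionGrid:
    """Score expected at each age 6.0-16.0 in 0.1-yr steps, for one sex."""

    sex: str
    ages: np.ndarray
    scores: np.ndarray
    nudged: bool = field(default=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "sex", validate_sex(self.sex))
        ages = np.asarray(self.ages, dtype=float)
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "scores", scores)
        if ages.shape != scores.shape or ages.ndim != 1:
            raise InvariantViolation("grid ages and scores must be equal-length 1-d arrays")
        if len(ages) != GRID_ROWS:
            raise InvariantViolation(f"grid must have {GRID_ROWS} rows, got {len(ages)}")
        expected = grid_ages()
        if not np.allclose(ages, expected, atol=1e-9):
            raise InvariantViolation("grid ages must be 6.0..16.0 in steps of 0.1")
        if not np.all(np.diff(scores) > 0):
            raise InvariantViolation(f"grid scores for sex {self.sex} are not strictly increasing")

    def __eq__(self, other):
        if not isinstance(other, ConversionGrid):
            return NotImplemented
        return (
            self.sex == other.sex
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.scores, other.scores)
        )

    def rows(self) -> list[tuple[float, float]]:
        return [(float(a), float(s)) for a, s in zip(self.ages, self.scores)]


def grid_ages() -> np.ndarray:
    """The canonical 101-point age grid 6.0, 6.1, ..., 16.0."""
    return np.round(GRID_START + GRID_STEP * np.arange(GRID_ROWS), 1)


@dataclass(frozen=True)
class ReferenceTables:
    """A score table plus one conversion grid per sex, as loaded from file."""

    score_table: MaturityScoreTable
    grids: Mapping[str, ConversionGrid]

    @property
    def population(self) -> str:
        return self.score_table.population

    def grid(self, sex: str) -> ConversionGrid:
        return self.grids[validate_sex(sex)]


def _parse_score_table(population, raw) -> MaturityScoreTable:
    scores: Dict[Tuple[str, int, str], float] = {}
    for sex, teeth in raw.items():
        sex = validate_sex(sex)
        for fdi, cells in teeth.items():
            fdi = validate_tooth(int(fdi))
            for stage, value in cells.items():
                scores[(sex, fdi, validate_stage(stage))] = float(value)
    return MaturityScoreTable(population=population, scores=scores)


def parse_reference_tables(doc: dict) -> ReferenceTables:
    """Build typed tables from a decoded JSON document, checking every invariant."""
    try:
        population = doc["population"]
        raw_scores = doc["score_table"]
        raw_conv = doc["conversion"]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"reference-table document missing key: {exc}") from exc
    if not isinstance(raw_scores, dict) or not raw_scores:
        raise SchemaError("score_table must be a non-empty mapping sex -> tooth -> stage -> score")
    table = _parse_score_table(population, raw_scores)
    if set(raw_conv) != set(raw_scores):
        raise SchemaError(
            f"conversion sexes {sorted(raw_conv)} do not match score_table sexes "
            f"{sorted(raw_scores)}"
        )
    grids = {}
    for sex, rows in raw_conv.items():
        sex = validate_sex(sex)
        try:
            ages = np.array([r[0] for r in rows], dtype=float)
            scores = np.array([r[1] for r in rows], dtype=float)
        except (TypeError, IndexError) as exc:
            raise SchemaError(f"conversion rows for sex {sex} must be [age, score] pairs") from exc
        grids[sex] = ConversionGrid(sex=sex, ages=ages, scores=scores)
    return ReferenceTables(score_table=table, grids=grids)


def load_reference_tables(path) -> ReferenceTables:
    """Load and validate a reference-table JSON file.

    Unknown top-level keys (e.g. ``diagnostics`` written by calibration) are
    ignored, so calibration outputs reload cleanly.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    return parse_reference_tables(doc)


def _fmt(obj) -> str:
    # fixed 2-dp floats so bundled files round-trip byte-identically
    if isinstance(obj, float):
        return format(obj, ".2f")
    if isinstance(obj, (list, tuple)):
        return "[" + ", ".join(_fmt(x) for x in obj) + "]"
    if isinstance(obj, dict):
        return "{" + ", ".join(json.dumps(k) + ": " + _fmt(v) for k, v in obj.items()) + "}"
    return json.dumps(obj)


def reference_tables_to_doc(tables: ReferenceTables, diagnostics: dict | None = None) -> dict:
    score_table: dict = {}
    for sex in tables.score_table.sexes:
        score_table[sex] = {
            str(fdi): {
                s: tables.score_table.scores[(sex, fdi, s)]
                for s in tables.score_table.stages(sex, fdi)
            }
            for fdi in tables.score_table.teeth(sex)
        }
    doc = {
        "population": tables.population,
        "score_table": score_table,
        "conversion": {sex: [list(r) for r in g.rows()] for sex, g in sorted(tables.grids.items())},
    }
    if diagnostics is not None:
        doc["diagnostics"] = diagnostics
    return doc


def dump_reference_tables(tables: ReferenceTables, path, diagnostics: dict | None = None) -> None:
    """Write a reference-table JSON file (floats at 2 dp; reload-identity)."""
    doc = reference_tables_to_doc(tables, diagnostics=diagnostics)
    with open(path, "w") as fh:
        fh.write(_fmt(doc) + "\n")


def load_builtin(population: str = "kosovo") -> ReferenceTables:
    """Load a population's tables shipped with the package."""
    try:
        name = BUILTIN_POPULATIONS[population]
    except KeyError:
        raise SchemaError(
            f"unknown built-in population {population!r}; available: "
            f"{sorted(BUILTIN_POPULATIONS)}"
        ) from None
    ref = resources.files("dentage") / "data" / name
    return parse_reference_tables(json.loads(ref.read_text()))


def kosovo_tables() -> ReferenceTables:
    """The bundled Kosovar reference tables (ages 6-16, both sexes)."""
    return load_builtin("kosovo")
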