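"""Reading and writing the package's file formats.

* Staging CSV: ``subject_id,sex,age,t31,...,t37`` — one subject per row;
  ``age`` may be replaced (or accompanied) by ISO-8601 ``birth_date`` /
  ``exam_date`` columns, from which age is derived with a 365.25-day year.
  Lines starting with ``#`` are comments (used for provenance stamps).
* Estimates CSV: per-subject score, dental age and per-tooth contributions.
* Reference JSON: see :mod:`dentage.tables`.
"""

from __future__ import annotations

import csv
import datetime as _dt
import hashlib
from typing import Optional, Union

import pandas as pd

from .core import FDI_TEETH, DentalChart, Subject, age_from_dates
from .calibration import CohortDataset, DentalMaturityResults
from .conversion import score_to_age
from .errors import ContradictoryAge, DentageError, ParseError
from .scoring import total_maturity_score
from .tables import ReferenceTables, dump_reference_tables

__all__ = [
    "read_staging_csv",
    "write_staging_csv",
    "estimate_cohort",
    "write_estimates_csv",
    "write_reference_json",
]

STAGE_COLUMNS = tuple(f"t{fdi}" for fdi in FDI_TEETH)


def _parse_date(text: str, what: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(text.strip())
    except ValueError as exc:
        raise ValueError(f"{what} must be ISO-8601 (YYYY-MM-DD), got {text!r}") from exc


def read_staging_csv(path) -> CohortDataset:
    """Parse a staging CSV into a typed cohort.

    All malformed rows are collected and reported together with their
    physical line numbers; age/date contradictions (> 0.02 yr) raise
    :class:`ContradictoryAge`, any other defect :class:`ParseError`.
    """
    subjects = []
    errors: list[tuple[int, str, bool]] = []  # (line, message, is_contradiction)
    with open(path, newline="") as fh:
        numbered = ((i, line) for i, line in enumerate(fh, start=1))
        data = [(i, line) for i, line in numbered if line.strip() and not line.lstrip().startswith("#")]
        if not data:
            raise ParseError(f"{path}: no data rows")
        header_line, *rows = data
        header = [h.strip() for h in next(csv.reader([header_line[1]]))]
        required = {"subject_id", "sex", *STAGE_COLUMNS}
        missing = required - set(header)
        if missing:
            raise ParseError(f"{path}: header missing columns: {sorted(missing)}")
        has_age = "age" in header
        has_dates = {"birth_date", "exam_date"} <= set(header)
        if not (has_age or has_dates):
            raise ParseError(f"{path}: need an 'age' column or 'birth_date'+'exam_date'")
        for lineno, raw in rows:
            try:
                fields = next(csv.reader([raw]))
                if len(fields) != len(header):
                    raise ValueError(f"expected {len(header)} fields, got {len(fields)}")
                rec = dict(zip(header, (f.strip() for f in fields)))
                birth = exam = None
                if has_dates and rec.get("birth_date") and rec.get("exam_date"):
                    birth = _parse_date(rec["birth_date"], "birth_date")
                    exam = _parse_date(rec["exam_date"], "exam_date")
                if has_age and rec.get("age"):
                    age = round(float(rec["age"]), 2)
                    if birth is not None:
                        derived = age_from_dates(birth, exam)
                        if abs(derived - age) > 0.02:
                            errors.append(
                                (lineno, f"age {age} contradicts dates (derived {derived})", True)
                            )
                            continue
                elif birth is not None:
                    age = age_from_dates(birth, exam)
                else:
                    raise ValueError("row has neither an age nor both dates")
                chart = DentalChart({fdi: rec[f"t{fdi}"] for fdi in FDI_TEETH})
                subjects.append(
                    Subject(
                        id=rec["subject_id"], sex=rec["sex"], chronological_age=age,
                        chart=chart, birth_date=birth, exam_date=exam,
                    )
                )
            except (DentageError, ValueError, KeyError) as exc:
                errors.append((lineno, str(exc), False))
    if errors:
        msg = f"{path}: {len(errors)} bad row(s): " + "; ".join(
            f"line {ln}: {m}" for ln, m, _ in errors[:10]
        ) + ("..." if len(errors) > 10 else "")
        if all(contradiction for _, _, contradiction in errors):
            raise ContradictoryAge(msg)
        raise ParseError(msg)
    return CohortDataset(subjects=tuple(subjects), provenance=str(path))


def write_staging_csv(cohort: CohortDataset, path, provenance: Optional[str] = None) -> None:
    with open(path, "w", newline="") as fh:
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "sex", "age", *STAGE_COLUMNS])
        for s in cohort.subjects:
            writer.writerow([s.id, s.sex, f"{s.chronological_age:.2f}", *s.chart.as_tuple()])


def estimate_cohort(cohort: CohortDataset, tables: ReferenceTables) -> pd.DataFrame:
    """Per-subject score, dental age and per-tooth contributions."""
    rows = []
    for s in cohort.subjects:
        ms = total_maturity_score(tables.score_table, s)
        est = score_to_age(tables.grid(s.sex), ms.total)
        rows.append(
            {
                "subject_id": s.id,
                "sex": s.sex,
                "ca": s.chronological_age,
                "score": round(ms.total, 2),
                "da": est.dental_age,
                "da_minus_ca": round(est.dental_age - s.chronological_age, 2),
                "clamped": est.clamped,
                **{f"c{fdi}": ms.per_tooth[fdi] for fdi in FDI_TEETH},
            }
        )
    return pd.DataFrame(rows)


def write_estimates_csv(df: pd.DataFrame, path, provenance: Optional[str] = None) -> None:
    with open(path, "w", newline="") as fh:
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        df.to_csv(fh, index=False)


def write_reference_json(
    result: Union[DentalMaturityResults, ReferenceTables], path, include_diagnostics: bool = True
) -> None:
    """Write calibration results or plain tables as a reference JSON file."""
    if isinstance(result, DentalMaturityResults):
        result.save(path, include_diagnostics=include_diagnostics)
    else:
        dump_reference_tables(result, path)


def file_sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()
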