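"""Cohort data model and delimited-text I/O.

The analysis consumes one row per subject-visit carrying demographics,
age, disease duration (PD only) and regional specific binding ratios
(SBRs) for the left/right putamen and caudate.  This module defines the
in-memory containers (:class:`VisitRecord`, :class:`SubjectSeries`,
:class:`Cohort`), the SBR formula, reading/writing with a configurable
column mapping, and the more-affected-side rule used throughout the
trajectory estimation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("control", "sPD", "LRRK2", "GBA")
PD_GROUPS = ("sPD", "LRRK2", "GBA")


class CohortValidationError(ValueError):
    """Raised when cohort rows violate the data-model invariants.

    Carries ``problems``: a list of ``(row_number, message)`` pairs so
    callers can report every offending row at once.
    """

    def __init__(self, problems: Sequence[tuple[int | None, str]]):
        self.problems = list(problems)
        lines = "; ".join(
            f"row {r}: {m}" if r is not None else m for r, m in self.problems
        )
        super().__init__(f"cohort validation failed: {lines}")


def compute_sbr(target_uptake, reference_uptake):
    """Specific binding ratio: (target − reference) / reference.

    Accepts scalars or arrays.  The reference-region uptake must be
    strictly positive.
    """
    target = np.asarray(target_uptake, dtype=float)
    reference = np.asarray(reference_uptake, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference uptake must be strictly positive")
    out = (target - reference) / reference
    return float(out) if out.ndim == 0 else out


@dataclass
class VisitRecord:
    """One imaging visit: age, disease duration and the four regional SBRs."""

    age_at_visit: float
    sbr_putamen_left: float
    sbr_putamen_right: float
    sbr_caudate_left: float | None = None
    sbr_caudate_right: float | None = None
    disease_duration: float | None = None  # None for controls

    def averaged_putamen(self) -> float:
        """Mean of left and right putaminal SBR (the control-side summary)."""
        return 0.5 * (self.sbr_putamen_left + self.sbr_putamen_right)

    def putamen(self, side: str) -> float:
        if side == "left":
            return self.sbr_putamen_left
        if side == "right":
            return self.sbr_putamen_right
        raise ValueError(f"unknown side {side!r}")


@dataclass
class SubjectSeries:
    """A subject's ordered scan history with demographic metadata.

    ``aao`` (age at motor onset, years) is required for PD subjects and
    absent for controls.  ``more_affected_side`` is assigned once from
    the baseline scan by :func:`assign_affected_side`.
    """

    subject_id: str
    group: str
    visits: list[VisitRecord] = field(default_factory=list)
    sex: str | None = None
    aao: float | None = None
    more_affected_side: str | None = None

    @property
    def is_pd(self) -> bool:
        return self.group in PD_GROUPS

    @property
    def baseline(self) -> VisitRecord:
        return self.visits[0]

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def sorted_by_age(self) -> "SubjectSeries":
        return dataclasses.replace(
            self, visits=sorted(self.visits, key=lambda v: v.age_at_visit)
        )


@dataclass
class Cohort:
    subjects: list[SubjectSeries]
    metadata: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)

    def by_group(self, *groups: str) -> list[SubjectSeries]:
        return [s for s in self.subjects if s.group in groups]

    @property
    def controls(self) -> list[SubjectSeries]:
        return self.by_group("control")


@dataclass(frozen=True)
class SchemaConfig:
    """Column-name mapping for delimited cohort files.

    Defaults match the synthetic generator's output; override the fields
    to load PPMI-export-shaped tables.
    """

    subject_id: str = "subject_id"
    group: str = "group"
    age_at_visit: str = "age_at_visit"
    disease_duration: str = "disease_duration"
    sex: str = "sex"
    sbr_putamen_left: str = "sbr_putamen_left"
    sbr_putamen_right: str = "sbr_putamen_right"
    sbr_caudate_left: str = "sbr_caudate_left"
    sbr_caudate_right: str = "sbr_caudate_right"
    delimiter: str = ","

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (
            self.subject_id,
            self.group,
            self.age_at_visit,
            self.sbr_putamen_left,
            self.sbr_putamen_right,
        )


DEFAULT_SCHEMA = SchemaConfig()

# age-at-onset vs (age − duration) consistency tolerance, years
_AAO_RTOL = 0.51


def _validate_series(series: SubjectSeries, problems, row_of):
    for v in series.visits:
        r = row_of.get(id(v))
        if not v.age_at_visit > 0:
            problems.append((r, f"{series.subject_id}: age_at_visit must be > 0"))
        sbrs = [v.sbr_putamen_left, v.sbr_putamen_right]
        if any(s is not None and (not np.isfinite(s) or s < -1) for s in sbrs):
            problems.append((r, f"{series.subject_id}: putaminal SBR not finite or < -1"))
        if series.is_pd:
            if v.disease_duration is None:
                problems.append((r, f"{series.subject_id}: PD visit missing disease_duration"))
            elif v.disease_duration < 0:
                problems.append((r, f"{series.subject_id}: negative disease_duration"))
        else:
            if v.disease_duration is not None:
                problems.append((r, f"{series.subject_id}: control carries disease_duration"))
    if series.is_pd and series.aao is None:
        problems.append((None, f"{series.subject_id}: PD subject without age at onset"))
    if series.is_pd and series.aao is not None:
        for v in series.visits:
            if v.disease_duration is None:
                continue
            if abs((v.age_at_visit - v.disease_duration) - series.aao) > _AAO_RTOL:
                problems.append(
                    (row_of.get(id(v)),
                     f"{series.subject_id}: age − duration inconsistent with AAO")
                )


def read_cohort(path, schema: SchemaConfig = DEFAULT_SCHEMA,
                metadata: Mapping | None = None) -> Cohort:
    """Load a delimited subject-visit table and validate the data model.

    Rows are grouped by subject id, visits sorted by age, and every
    invariant checked; all violations are reported together in a
    :class:`CohortValidationError` with source row numbers (1-based,
    excluding the header).
    """
    df = pd.read_csv(path, sep=schema.delimiter)
    missing = [c for c in schema.mandatory if c not in df.columns]
    if missing:
        raise CohortValidationError(
            [(None, f"missing mandatory column(s): {', '.join(missing)}")]
        )
    problems: list[tuple[int | None, str]] = []
    subjects: dict[str, SubjectSeries] = {}
    row_of: dict[int, int] = {}
    has_sex = schema.sex in df.columns
    has_dur = schema.disease_duration in df.columns
    has_cn = (schema.sbr_caudate_left in df.columns
              and schema.sbr_caudate_right in df.columns)

    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        sid = str(rec[schema.subject_id])
        group = str(rec[schema.group])
        if group not in GROUPS:
            problems.append((i, f"unknown group label {group!r}"))
            continue
        dur = rec.get(schema.disease_duration) if has_dur else None
        if dur is not None and (isinstance(dur, float) and np.isnan(dur)):
            dur = None
        visit = VisitRecord(
            age_at_visit=float(rec[schema.age_at_visit]),
            sbr_putamen_left=float(rec[schema.sbr_putamen_left]),
            sbr_putamen_right=float(rec[schema.sbr_putamen_right]),
            sbr_caudate_left=float(rec[schema.sbr_caudate_left]) if has_cn else None,
            sbr_caudate_right=float(rec[schema.sbr_caudate_right]) if has_cn else None,
            disease_duration=float(dur) if dur is not None else None,
        )
        row_of[id(visit)] = i
        if sid not in subjects:
            subjects[sid] = SubjectSeries(
                subject_id=sid,
                group=group,
                sex=str(rec[schema.sex]) if has_sex and rec.get(schema.sex) is not None else None,
            )
        elif subjects[sid].group != group:
            problems.append((i, f"{sid}: inconsistent group labels across visits"))
        subjects[sid].visits.append(visit)

    out = []
    for series in subjects.values():
        series = series.sorted_by_age()
        if series.is_pd:
            durs = [v for v in series.visits if v.disease_duration is not None]
            if durs:
                v0 = durs[0]
                series.aao = v0.age_at_visit - v0.disease_duration
        _validate_series(series, problems, row_of)
        out.append(series)
    if problems:
        raise CohortValidationError(problems)
    return Cohort(subjects=out, metadata=dict(metadata or {}))


def write_cohort(cohort: Cohort, path, schema: SchemaConfig = DEFAULT_SCHEMA) -> None:
    """Write a cohort back to the documented delimited-text schema."""
    rows = []
    for s in cohort.subjects:
        for v in s.visits:
            rows.append({
                schema.subject_id: s.subject_id,
                schema.group: s.group,
                schema.sex: s.sex if s.sex is not None else "",
                schema.age_at_visit: v.age_at_visit,
                schema.disease_duration: (
                    v.disease_duration if v.disease_duration is not None else ""
                ),
                schema.sbr_putamen_left: v.sbr_putamen_left,
                schema.sbr_putamen_right: v.sbr_putamen_right,
                schema.sbr_caudate_left: (
                    v.sbr_caudate_left if v.sbr_caudate_left is not None else ""
                ),
                schema.sbr_caudate_right: (
                    v.sbr_caudate_right if v.sbr_caudate_right is not None else ""
                ),
            })
    pd.DataFrame(rows).to_csv(path, sep=schema.delimiter, index=False)


def assign_affected_side(series: SubjectSeries) -> SubjectSeries:
    """Label the more-affected putamen from the baseline (earliest) scan.

    The side with the lower baseline putaminal SBR is taken as more
    affected; an exact tie is broken toward the left.  Returns a copy
    with ``more_affected_side`` set.
    """
    series = series.sorted_by_age()
    b = series.baseline
    if b.sbr_putamen_left is None or b.sbr_putamen_right is None:
        raise ValueError(f"{series.subject_id}: baseline missing a putaminal SBR")
    side = "left" if b.sbr_putamen_left <= b.sbr_putamen_right else "right"
    return dataclasses.replace(series, more_affected_side=side)


def control_baseline_sbrs(cohort: Cohort | Iterable[SubjectSeries]) -> np.ndarray:
    """Averaged putaminal SBR at each control subject's baseline scan."""
    subjects = cohort.subjects if isinstance(cohort, Cohort) else list(cohort)
    vals = [s.baseline.averaged_putamen() for s in subjects if s.group == "control"]
    return np.asarray(vals, dtype=float)
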