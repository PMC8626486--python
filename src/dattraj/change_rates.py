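"""Stage 1: per-putamen annual change rates and the subject exclusion rule.

Each subject with ≥2 scans contributes two (baseline SBR, annual change
rate) pairs — one per putamen — obtained by ordinary least squares of
SBR on time since the first scan.  PD subjects whose more-affected
putamen sits near the control mean *and* shows a positive slope are
excluded as probable diagnostic or processing errors.  Extreme annual
changes are flagged by a 3×IQR quartile rule for display only; flagged
samples always stay in the model fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_cohort import Cohort, SubjectSeries, control_baseline_sbrs

SIDES = ("left", "right")


@dataclass
class RateSample:
    """One putamen's (baseline SBR, annual change rate) pair."""

    subject_id: str
    side: str
    baseline_sbr: float
    annual_change: float
    n_visits: int
    group: str | None = None
    baseline_duration: float | None = None  # disease duration at first scan
    intercept: float = float("nan")  # fitted value at the first scan
    excluded: bool = False
    exclusion_reason: str | None = None
    outlier_flag: bool = False  # display only, never removes from fitting


@dataclass(frozen=True)
class ControlStats:
    """Mean/SD of averaged putaminal SBR at control baselines."""

    mean_putaminal_sbr: float
    sd_putaminal_sbr: float
    n: int

    def __post_init__(self):
        if not self.sd_putaminal_sbr > 0:
            raise ValueError("control SBR standard deviation must be positive")

    @property
    def exclusion_threshold(self) -> float:
        """Baseline SBR above which condition (i) of the exclusion rule holds."""
        return self.mean_putaminal_sbr - 1.0 * self.sd_putaminal_sbr


@dataclass
class ExclusionReport:
    """Subjects removed by the baseline-near-control + positive-slope rule."""

    threshold: float
    control_mean: float
    control_sd: float
    excluded: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "rule": "baseline_sbr > control_mean - 1.0*SD and annual_change > 0",
            "control_mean": round(self.control_mean, 6),
            "control_sd": round(self.control_sd, 6),
            "threshold": round(self.threshold, 6),
            "n_excluded": len(self.excluded),
            "excluded": sorted(
                (
                    {k: (round(v, 6) if isinstance(v, float) else v)
                     for k, v in e.items()}
                    for e in self.excluded
                ),
                key=lambda e: e["subject_id"],
            ),
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def compute_control_stats(cohort: Cohort) -> ControlStats:
    vals = control_baseline_sbrs(cohort)
    if vals.size < 2:
        raise ValueError("need at least 2 control subjects for control statistics")
    return ControlStats(
        mean_putaminal_sbr=float(vals.mean()),
        sd_putaminal_sbr=float(vals.std(ddof=1)),
        n=int(vals.size),
    )


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares (intercept, slope) of y on t."""
    slope, intercept = np.polyfit(t, y, 1)
    return float(intercept), float(slope)


def fit_subject_slopes(series: SubjectSeries,
                       baseline_mode: str = "observed") -> list[RateSample]:
    """OLS slope of each putaminal SBR against years since the first scan.

    ``baseline_mode`` selects what is reported as the baseline SBR:
    ``"observed"`` (the first-visit measurement, default) or
    ``"fitted"`` (the regression line evaluated at the first scan).
    """
    if baseline_mode not in ("observed", "fitted"):
        raise ValueError("baseline_mode must be 'observed' or 'fitted'")
    series = series.sorted_by_age()
    if series.n_visits < 2:
        raise ValueError(f"{series.subject_id}: need >= 2 visits for a slope")
    t = np.array([v.age_at_visit for v in series.visits], float)
    t = t - t[0]
    dur0 = series.baseline.disease_duration
    out = []
    for side in SIDES:
        y = np.array([v.putamen(side) for v in series.visits], float)
        intercept, slope = _ols_line(t, y)
        out.append(RateSample(
            subject_id=series.subject_id,
            side=side,
            baseline_sbr=float(y[0]) if baseline_mode == "observed" else intercept,
            annual_change=slope,
            n_visits=series.n_visits,
            group=series.group,
            baseline_duration=dur0,
            intercept=intercept,
        ))
    return out


def apply_exclusion_rule(samples: Sequence[RateSample], control_stats: ControlStats,
                         affected_sides: Mapping[str, str]
                         ) -> tuple[list[RateSample], ExclusionReport]:
    """Drop PD subjects with near-normal baseline yet rising putaminal SBR.

    A subject is excluded when their *more-affected* putamen shows both
    (i) baseline SBR above the control mean − 1.0 SD and (ii) a positive
    annual change rate.  The rule acts at subject level: both putamina
    of a triggering subject are removed.  Returns the kept samples and a
    deterministic report.
    """
    if control_stats is None:
        raise ValueError("control statistics are required for the exclusion rule")
    thr = control_stats.exclusion_threshold
    report = ExclusionReport(
        threshold=thr,
        control_mean=control_stats.mean_putaminal_sbr,
        control_sd=control_stats.sd_putaminal_sbr,
    )
    triggering: set[str] = set()
    for s in samples:
        side = affected_sides.get(s.subject_id)
        if side is None:
            raise ValueError(f"{s.subject_id}: more-affected side not assigned")
        if s.side != side:
            continue
        if s.baseline_sbr > thr and s.annual_change > 0:
            triggering.add(s.subject_id)
            report.excluded.append({
                "subject_id": s.subject_id,
                "side": s.side,
                "baseline_sbr": float(s.baseline_sbr),
                "annual_change": float(s.annual_change),
            })
    kept, dropped = [], []
    for s in samples:
        if s.subject_id in triggering:
            dropped.append(replace(
                s, excluded=True,
                exclusion_reason="baseline near control mean with positive slope",
            ))
        else:
            kept.append(s)
    return kept, report


def flag_outliers(samples: Sequence[RateSample]) -> list[RateSample]:
    """Flag annual changes outside [Q1 − 3·IQR, Q3 + 3·IQR] (display only).

    Quartiles use linear interpolation between closest ranks (the
    numpy/R type-7 convention).  With degenerate IQR = 0 the interval
    collapses to the common value and equal values are not flagged.
    """
    vals = np.array([s.annual_change for s in samples], float)
    if vals.size < 4:
        return [replace(s, outlier_flag=False) for s in samples]
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 3 * iqr, q3 + 3 * iqr
    return [replace(s, outlier_flag=bool(v < lo or v > hi))
            for s, v in zip(samples, vals)]


def sbr_at_motor_onset(series: SubjectSeries) -> float:
    """More-affected putaminal SBR extrapolated to disease duration 0.

    Fits the subject's per-side line of SBR on disease duration and
    evaluates it at duration 0, i.e. the moment of motor onset.
    """
    series = series.sorted_by_age()
    if series.more_affected_side is None:
        raise ValueError(f"{series.subject_id}: more-affected side not assigned")
    if any(v.disease_duration is None for v in series.visits):
        raise ValueError(f"{series.subject_id}: visit missing disease duration")
    if series.n_visits < 2:
        raise ValueError(f"{series.subject_id}: need >= 2 visits")
    d = np.array([v.disease_duration for v in series.visits], float)
    y = np.array([v.putamen(series.more_affected_side) for v in series.visits], float)
    intercept, _ = _ols_line(d, y)
    return intercept


def cohort_rate_samples(cohort: Cohort, groups: Iterable[str],
                        baseline_mode: str = "observed"
                        ) -> tuple[list[RateSample], dict[str, str]]:
    """Slopes for every PD subject in ``groups`` with ≥2 visits.

    Also returns the subject → more-affected-side mapping (assigned at
    baseline) needed by the exclusion rule and the anchoring stage.
    """
    from .io_cohort import assign_affected_side

    samples: list[RateSample] = []
    sides: dict[str, str] = {}
    for series in cohort.by_group(*groups):
        if series.n_visits < 2:
            continue
        series = assign_affected_side(series)
        sides[series.subject_id] = series.more_affected_side
        samples.extend(fit_subject_slopes(series, baseline_mode=baseline_mode))
    return samples, sides
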