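"""Stage 3: integrate dS/dt = f(S), anchor at motor onset, find degeneration onset.

The fitted rate function f(S) is treated as the right-hand side of a
first-order ODE and integrated with the modified Euler (Heun
predictor–corrector) method.  The curve is anchored at disease duration
0 with the mean of the per-subject estimated SBRs at motor onset,
converted to an age axis by adding the group's median age at motor
onset, and run backward until it meets the control aging line
SBR = c1·age + c2.  That intersection is taken as the onset of striatal
dopaminergic degeneration; the premotor phase is the interval from that
onset to motor onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .change_rates import (
    apply_exclusion_rule,
    cohort_rate_samples,
    compute_control_stats,
    sbr_at_motor_onset,
)
from .io_cohort import Cohort, assign_affected_side
from .rate_function import KnotSet, fit_rate_function, place_knots


class IntegrationDivergedError(RuntimeError):
    pass


class NoIntersectionError(RuntimeError):
    """Backward trajectory never meets the control aging line."""


@dataclass
class ControlAgingModel:
    """Linear non-PD model: averaged putaminal SBR = c1·age + c2."""

    c1: float  # slope, SBR / year
    c2: float  # intercept, SBR
    n: int
    residual_sd: float

    def __call__(self, age):
        return self.c1 * np.asarray(age, float) + self.c2


def fit_control_aging_model(cohort: Cohort) -> ControlAgingModel:
    """OLS of averaged putaminal SBR on age over all pooled control visits."""
    ages, sbrs = [], []
    for s in cohort.controls:
        for v in s.visits:
            ages.append(v.age_at_visit)
            sbrs.append(v.averaged_putamen())
    if len(set(s.subject_id for s in cohort.controls)) < 10:
        raise ValueError("need >= 10 control subjects for the aging model")
    ages = np.asarray(ages, float)
    sbrs = np.asarray(sbrs, float)
    c1, c2 = np.polyfit(ages, sbrs, 1)
    resid = sbrs - (c1 * ages + c2)
    if c1 >= 0:
        warnings.warn(
            f"control aging slope is non-negative ({c1:.4g}); SBR is expected "
            "to decline with age", RuntimeWarning, stacklevel=2,
        )
    return ControlAgingModel(
        c1=float(c1), c2=float(c2), n=ages.size,
        residual_sd=float(np.sqrt(np.mean(resid ** 2))),
    )


@dataclass
class Trajectory:
    """Integrated SBR-vs-time curve on a disease-duration grid.

    ``times`` are years of disease duration (0 at motor onset, negative
    premotor); ``ages`` = times + median AAO.
    """

    times: np.ndarray
    values: np.ndarray
    anchor_sbr: float
    median_aao: float
    step: float
    onset_age: float | None = None
    premotor_duration: float | None = None
    n_clipped: int = 0

    @property
    def ages(self) -> np.ndarray:
        return self.times + self.median_aao

    @property
    def motor_onset_age(self) -> float:
        return self.median_aao

    def value_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))


def integrate_trajectory(f: Callable[[float], float], s0: float, t0: float,
                         horizon: float, step: float, direction: str = "forward",
                         floor: float = 0.0, bound: float = 50.0,
                         stop_when: Callable[[float, float], bool] | None = None
                         ) -> tuple[np.ndarray, np.ndarray, int]:
    """Heun (modified Euler) integration of dS/dt = f(S).

    Per signed step h: predictor s* = s + h·f(s), corrector
    s_next = s + (h/2)(f(s) + f(s*)).  Values are clipped at ``floor``
    (clip count returned); |s| exceeding ``bound`` aborts with
    :class:`IntegrationDivergedError`.  ``stop_when(t, s)`` optionally
    truncates the grid once a condition is reached (e.g. the backward
    curve has passed well above the control line).  Returns (times,
    values, n_clipped) with times ordered along the integration
    direction.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    h = step if direction == "forward" else -step
    n = int(round(horizon / step))
    times = t0 + h * np.arange(n + 1)
    values = np.empty(n + 1)
    values[0] = s0
    n_clipped = 0
    s = float(s0)
    for i in range(n):
        fs = float(f(s))
        s_star = s + h * fs
        s_next = s + 0.5 * h * (fs + float(f(s_star)))
        if abs(s_next) > bound:
            raise IntegrationDivergedError(
                f"integration diverged at step {i + 1} (t={times[i + 1]:.3f}, "
                f"s={s_next:.3g})"
            )
        if s_next < floor:
            s_next = floor
            n_clipped += 1
        values[i + 1] = s_next
        s = s_next
        if stop_when is not None and stop_when(float(times[i + 1]), s):
            return times[: i + 2], values[: i + 2], n_clipped
    return times, values, n_clipped


def anchor_and_localize(f, pd_subjects: Sequence, control_model: ControlAgingModel,
                        step: float = 0.01, forward_horizon: float = 15.0,
                        backward_horizon: float = 30.0, floor: float = 0.0
                        ) -> Trajectory:
    """Anchor the integrated curve at motor onset and convert to age.

    The anchor is the mean over PD subjects of the more-affected-side
    SBR extrapolated to disease duration 0; the age axis adds the
    group's median age at motor onset.  The curve is integrated forward
    over the motor phase and backward over the premotor search horizon.
    """
    if not pd_subjects:
        raise ValueError("empty PD group")
    onset_sbrs = []
    aaos = []
    for series in pd_subjects:
        if series.more_affected_side is None:
            series = assign_affected_side(series)
        onset_sbrs.append(sbr_at_motor_onset(series))
        aaos.append(series.aao)
    anchor = float(np.mean(onset_sbrs))
    median_aao = float(np.median(aaos))

    # the backward segment only needs to bracket the control-line crossing;
    # stop once the curve sits 25% above the line to keep the exponential
    # growth of reversed-time integration bounded
    def past_line(t, s):
        return s > 1.25 * float(control_model(t + median_aao))

    t_b, v_b, nc_b = integrate_trajectory(
        f, anchor, 0.0, backward_horizon, step, "backward", floor=floor,
        stop_when=past_line)
    t_f, v_f, nc_f = integrate_trajectory(
        f, anchor, 0.0, forward_horizon, step, "forward", floor=floor)
    times = np.concatenate([t_b[::-1], t_f[1:]])
    values = np.concatenate([v_b[::-1], v_f[1:]])
    if nc_b + nc_f:
        warnings.warn(
            f"{nc_b + nc_f} integration step(s) clipped at floor {floor}",
            RuntimeWarning, stacklevel=2,
        )
    return Trajectory(
        times=times, values=values, anchor_sbr=anchor, median_aao=median_aao,
        step=step, n_clipped=nc_b + nc_f,
    )


def find_degeneration_onset(traj: Trajectory, control_model: ControlAgingModel
                            ) -> tuple[float, float]:
    """Intersection of the backward trajectory with the control aging line.

    Scans the premotor (t < 0) part of the grid for sign changes of
    trajectory − control line in age coordinates, takes the crossing
    nearest motor onset, and interpolates linearly inside the bracketing
    step.  Returns (onset age, premotor duration).
    """
    mask = traj.times <= 0
    ages = traj.ages[mask]
    diff = traj.values[mask] - control_model(ages)
    sign = np.sign(diff)
    idx = np.nonzero(sign[:-1] * sign[1:] <= 0)[0]
    idx = idx[(sign[idx] != 0) | (sign[idx + 1] != 0)]
    exact = np.nonzero(sign == 0)[0]
    candidates = []
    for i in idx:
        a0, a1 = ages[i], ages[i + 1]
        d0, d1 = diff[i], diff[i + 1]
        candidates.append(a0 + (a1 - a0) * (0.0 - d0) / (d1 - d0))
    candidates.extend(ages[exact])
    if not candidates:
        raise NoIntersectionError(
            "backward trajectory does not cross the control aging line within "
            f"the search horizon (min age {ages[0]:.1f}, trajectory "
            f"[{traj.values[mask].min():.3g}, {traj.values[mask].max():.3g}], "
            f"control line [{control_model(ages).min():.3g}, "
            f"{control_model(ages).max():.3g}])"
        )
    onset_age = float(max(candidates))  # nearest to motor onset
    premotor = traj.motor_onset_age - onset_age
    return onset_age, premotor


@dataclass
class PipelineConfig:
    """Numerical settings of the end-to-end premotor estimation."""

    step: float = 0.01  # years
    forward_horizon: float = 15.0
    backward_horizon: float = 30.0
    floor: float = 0.0
    baseline_mode: str = "observed"
    reml: bool = False
    collapse_two_step: bool = False
    knot_rule: str | None = None  # None = auto by putamen count


@dataclass
class PremotorEstimate:
    """End-to-end result: trajectory plus the headline premotor statistics."""

    trajectory: Trajectory
    onset_age: float
    motor_onset_age: float
    premotor_duration: float
    anchor_sbr: float
    anchor_pct_of_control: float  # anchor as % of age-matched control mean
    reduction_per_year: float  # mean premotor SBR loss per year
    knots: KnotSet
    control_model: ControlAgingModel
    n_subjects: int
    n_excluded: int
    n_rate_samples: int
    frac_outside_domain: float  # premotor grid outside the training range
    exclusion_report: object = field(repr=False, default=None)
    rate_function: object = field(repr=False, default=None)


def estimate_premotor_phase(cohort: Cohort, group: str,
                            config: PipelineConfig | None = None
                            ) -> PremotorEstimate:
    """Full estimator: slopes → exclusion → mixed RCS → integrate → onset.

    ``group`` selects the PD group whose trajectory is reconstructed;
    controls come from the same cohort.
    """
    config = config or PipelineConfig()
    control_stats = compute_control_stats(cohort)
    control_model = fit_control_aging_model(cohort)

    samples, sides = cohort_rate_samples(
        cohort, [group], baseline_mode=config.baseline_mode)
    if not samples:
        raise ValueError(f"no usable PD subjects in group {group!r}")
    kept, report = apply_exclusion_rule(samples, control_stats, sides)
    if not kept:
        raise ValueError(f"exclusion rule removed every subject in {group!r}")

    baselines = np.array([s.baseline_sbr for s in kept], float)
    knots = place_knots(baselines, rule_auto=config.knot_rule is None,
                        rule=config.knot_rule)
    f, _mixed = fit_rate_function(
        kept, knots, reml=config.reml, collapse_two_step=config.collapse_two_step)

    kept_ids = {s.subject_id for s in kept}
    pd_subjects = [
        assign_affected_side(s) for s in cohort.by_group(group)
        if s.subject_id in kept_ids
    ]
    traj = anchor_and_localize(
        f, pd_subjects, control_model, step=config.step,
        forward_horizon=config.forward_horizon,
        backward_horizon=config.backward_horizon, floor=config.floor,
    )
    onset_age, premotor = find_degeneration_onset(traj, control_model)
    traj.onset_age = onset_age
    traj.premotor_duration = premotor

    sbr_at_onset = float(control_model(onset_age))
    reduction = (sbr_at_onset - traj.anchor_sbr) / premotor
    anchor_pct = 100.0 * traj.anchor_sbr / float(control_model(traj.motor_onset_age))

    premotor_mask = (traj.times < 0) & (traj.ages >= onset_age)
    vals = traj.values[premotor_mask]
    lo, hi = f.domain
    frac_outside = float(np.mean((vals < lo) | (vals > hi))) if vals.size else 0.0
    if frac_outside > 0.10:
        warnings.warn(
            f"{frac_outside:.0%} of the premotor segment lies outside the "
            "rate function's training domain; the curve there relies on "
            "linear extrapolation", RuntimeWarning, stacklevel=2,
        )

    n_subjects = len({s.subject_id for s in samples})
    return PremotorEstimate(
        trajectory=traj,
        onset_age=onset_age,
        motor_onset_age=traj.motor_onset_age,
        premotor_duration=premotor,
        anchor_sbr=traj.anchor_sbr,
        anchor_pct_of_control=anchor_pct,
        reduction_per_year=float(reduction),
        knots=knots,
        control_model=control_model,
        n_subjects=n_subjects,
        n_excluded=n_subjects - len(kept_ids),
        n_rate_samples=len(kept),
        frac_outside_domain=frac_outside,
        exclusion_report=report,
        rate_function=f,
    )
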