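import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dattraj.change_rates import (
    ControlStats,
    RateSample,
    apply_exclusion_rule,
    fit_subject_slopes,
    flag_outliers,
    sbr_at_motor_onset,
)
from dattraj.io_cohort import SubjectSeries, VisitRecord, assign_affected_side


def make_series(times, left, right=None, group="sPD", base_age=60.0):
    right = right if right is not None else [v + 0.3 for v in left]
    visits = [
        VisitRecord(age_at_visit=base_age + t, disease_duration=1.0 + t,
                    sbr_putamen_left=l, sbr_putamen_right=r)
        for t, l, r in zip(times, left, right)
    ]
    return SubjectSeries(subject_id="P1", group=group, visits=visits,
                         aao=base_age - 1.0)


class TestSubjectSlopes:
    def test_two_point_slope(self):
        s = make_series([0, 2], [1.0, 0.8])
        left = {r.side: r for r in fit_subject_slopes(s)}["left"]
        assert left.annual_change == pytest.approx(-0.1)
        assert left.baseline_sbr == pytest.approx(1.0)

    def test_constant_series_has_zero_slope(self):
        s = make_series([0, 1, 3], [0.9, 0.9, 0.9])
        assert fit_subject_slopes(s)[0].annual_change == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        t = np.array([0.0, 1.1, 2.4, 3.9])
        y = 1.2 - 0.07 * t + rng.normal(0, 0.05, size=4)
        s = make_series(t, y)
        # brute-force normal equations
        X = np.column_stack([np.ones(4), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fit = {r.side: r for r in fit_subject_slopes(s)}["left"]
        assert fit.annual_change == pytest.approx(beta[1], abs=1e-12)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-12)

    def test_single_visit_is_an_error(self):
        s = make_series([0], [1.0])
        with pytest.raises(ValueError):
            fit_subject_slopes(s)

    @settings(derandomize=True, max_examples=30)
    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_time_shift_and_sbr_scale_equivariance(self, shift, scale):
        t = np.array([0.0, 1.0, 2.5, 4.0])
        y = np.array([1.1, 1.0, 0.85, 0.7])
        base = fit_subject_slopes(make_series(t, y))[0].annual_change
        shifted = fit_subject_slopes(
            make_series(t, y, base_age=60.0 + shift))[0].annual_change
        scaled = fit_subject_slopes(make_series(t, scale * y))[0].annual_change
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert scaled == pytest.approx(scale * base, rel=1e-9, abs=1e-12)


def _sample(sid, baseline, slope, side="left"):
    return RateSample(sid, side, baseline, slope, 2)


class TestExclusionRule:
    stats = ControlStats(mean_putaminal_sbr=2.13, sd_putaminal_sbr=0.55, n=213)

    def test_threshold_value(self):
        assert self.stats.exclusion_threshold == pytest.approx(1.58)

    @pytest.mark.parametrize(
        "baseline, slope, excluded",
        [(1.70, 0.02, True), (1.70, -0.05, False), (1.40, 0.02, False)],
    )
    def test_both_conditions_required(self, baseline, slope, excluded):
        samples = [_sample("P1", baseline, slope)]
        kept, report = apply_exclusion_rule(samples, self.stats, {"P1": "left"})
        assert (len(kept) == 0) == excluded
        assert (len(report.excluded) == 1) == excluded

    def test_subject_level_exclusion_drops_both_putamina(self):
        samples = [_sample("P1", 1.70, 0.02, "left"),
                   _sample("P1", 1.90, -0.01, "right")]
        kept, _ = apply_exclusion_rule(samples, self.stats, {"P1": "left"})
        assert kept == []

    def test_less_affected_side_never_triggers(self):
        samples = [_sample("P1", 1.40, -0.02, "left"),
                   _sample("P1", 1.90, 0.03, "right")]
        kept, _ = apply_exclusion_rule(samples, self.stats, {"P1": "left"})
        assert len(kept) == 2

    @settings(derandomize=True, max_examples=40)
    @given(b=st.floats(0.2, 3.0), d=st.floats(0.0, 1.0))
    def test_exclusion_monotone_in_baseline_and_slope(self, b, d):
        # lowering baseline or slope never converts kept -> excluded
        slope = 0.02
        hi, _ = apply_exclusion_rule([_sample("P", b, slope)], self.stats, {"P": "left"})
        lo, _ = apply_exclusion_rule([_sample("P", b - d, slope)], self.stats, {"P": "left"})
        lo2, _ = apply_exclusion_rule([_sample("P", b, slope - d)], self.stats, {"P": "left"})
        if len(hi) == 1:  # kept at the higher values
            assert len(lo) == 1 and len(lo2) == 1


class TestOutlierFlags:
    @staticmethod
    def brute_force_flags(values):
        v = np.sort(np.asarray(values, float))
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        return [bool(x < q1 - 3 * iqr or x > q3 + 3 * iqr) for x in values]

    def test_single_gross_outlier_flagged(self):
        vals = [-0.1, -0.12, -0.08, -0.11, -0.09, -5.0]
        samples = [_sample(f"P{i}", 1.0, v) for i, v in enumerate(vals)]
        flagged = [s.outlier_flag for s in flag_outliers(samples)]
        assert flagged == [False] * 5 + [True]

    def test_degenerate_iqr_flags_nothing(self):
        samples = [_sample(f"P{i}", 1.0, -0.1) for i in range(6)]
        assert not any(s.outlier_flag for s in flag_outliers(samples))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=4, max_size=40))
    def test_matches_brute_force_quartile_oracle(self, values):
        samples = [_sample(f"P{i}", 1.0, v) for i, v in enumerate(values)]
        got = [s.outlier_flag for s in flag_outliers(samples)]
        assert got == self.brute_force_flags(values)


class TestSbrAtMotorOnset:
    def test_linear_extrapolation_to_duration_zero(self):
        s = assign_affected_side(make_series([0, 2], [0.9, 0.7]))
        # durations 1 and 3 with SBR 0.9 and 0.7 -> 1.0 at duration 0
        assert sbr_at_motor_onset(s) == pytest.approx(1.0)

    def test_zero_slope_gives_mean(self):
        s = assign_affected_side(make_series([0, 1, 2], [0.8, 0.8, 0.8]))
        assert sbr_at_motor_onset(s) == pytest.approx(0.8)

    def test_matches_ols_intercept_oracle(self, rng):
        t = np.array([0.0, 1.0, 2.0, 4.0])
        y = 1.1 - 0.09 * t + rng.normal(0, 0.04, 4)
        s = assign_affected_side(make_series(t, y, right=[2.0] * 4))
        d = np.array([v.disease_duration for v in s.visits])
        X = np.column_stack([np.ones(4), d])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert sbr_at_motor_onset(s) == pytest.approx(beta[0], abs=1e-12)

    def test_missing_duration_is_an_error(self):
        s = assign_affected_side(make_series([0, 2], [0.9, 0.7]))
        s.visits[1] = dataclasses.replace(s.visits[1], disease_duration=None)
        with pytest.raises(ValueError):
            sbr_at_motor_onset(s)
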