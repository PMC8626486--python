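import warnings

import numpy as np
import pytest

from dattraj.io_cohort import SubjectSeries, VisitRecord
from dattraj.synthetic_cohort import SimulationConfig, simulate_cohort
from dattraj.trajectory import (
    ControlAgingModel,
    IntegrationDivergedError,
    NoIntersectionError,
    Trajectory,
    anchor_and_localize,
    estimate_premotor_phase,
    find_degeneration_onset,
    fit_control_aging_model,
    integrate_trajectory,
)


class TestControlAgingModel:
    def test_noise_free_line_recovered_exactly(self):
        cfg = SimulationConfig(n_controls=30, n_pd=0, noise_sd=0.0, seed=1)
        cohort, _, _ = simulate_cohort(cfg)
        m = fit_control_aging_model(cohort)
        assert m.c1 == pytest.approx(cfg.control_slope, abs=1e-10)
        assert m.c2 == pytest.approx(cfg.control_intercept, abs=1e-8)

    def test_matches_normal_equations_oracle(self, small_cohort):
        _, cohort, _ = small_cohort
        ages, sbrs = [], []
        for s in cohort.controls:
            for v in s.visits:
                ages.append(v.age_at_visit)
                sbrs.append(0.5 * (v.sbr_putamen_left + v.sbr_putamen_right))
        X = np.column_stack([np.ones(len(ages)), ages])
        beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(sbrs))
        m = fit_control_aging_model(cohort)
        assert m.c1 == pytest.approx(beta[1], abs=1e-10)
        assert m.c2 == pytest.approx(beta[0], abs=1e-8)

    def test_slope_recovery_within_two_se(self):
        cfg = SimulationConfig(n_controls=200, n_pd=0, seed=9)
        cohort, _, _ = simulate_cohort(cfg)
        m = fit_control_aging_model(cohort)
        ages = np.array([v.age_at_visit for s in cohort.controls for v in s.visits])
        se = m.residual_sd / np.sqrt(((ages - ages.mean()) ** 2).sum())
        assert abs(m.c1 - cfg.control_slope) < 2 * se


class TestHeunIntegration:
    def test_zero_rhs_gives_constant(self):
        t, v, nc = integrate_trajectory(lambda s: 0.0, 1.3, 0.0, 5.0, 0.1)
        assert np.allclose(v, 1.3)
        assert nc == 0

    def test_exponential_oracle(self):
        f = lambda s: -0.2 * (s - 0.3)
        t, v, _ = integrate_trajectory(f, 2.13, 0.0, 20.0, 0.01)
        exact = 0.3 + 1.83 * np.exp(-0.2 * t)
        assert np.max(np.abs(v - exact) / exact) < 1e-4

    def test_second_order_convergence(self):
        f = lambda s: -0.2 * (s - 0.3)
        errs = []
        for h in (0.1, 0.05):
            t, v, _ = integrate_trajectory(f, 2.13, 0.0, 20.0, h)
            errs.append(np.max(np.abs(v - (0.3 + 1.83 * np.exp(-0.2 * t)))))
        ratio = errs[0] / errs[1]
        assert 3.3 < ratio < 4.7

    def test_backward_direction_reverses_time(self):
        f = lambda s: -0.2 * (s - 0.3)
        t, v, _ = integrate_trajectory(f, 1.0, 0.0, 5.0, 0.01, "backward")
        exact = 0.3 + 0.7 * np.exp(-0.2 * t)  # t negative: growth backwards
        assert np.allclose(v, exact, rtol=1e-4)

    def test_divergence_raises_with_step_info(self):
        with pytest.raises(IntegrationDivergedError, match="step"):
            integrate_trajectory(lambda s: s**2, 2.0, 0.0, 10.0, 0.1, bound=1e3)

    def test_floor_clipping_counted(self):
        _, v, nc = integrate_trajectory(lambda s: -1.0, 1.0, 0.0, 5.0, 0.1,
                                        floor=0.0)
        assert nc > 0
        assert v.min() == 0.0


def _pd_subject(sid, onset_sbrs, aao):
    # two visits placing the more-affected (left) line through onset_sbr at d=0
    visits = [
        VisitRecord(age_at_visit=aao + d, disease_duration=d,
                    sbr_putamen_left=onset_sbrs - 0.05 * d,
                    sbr_putamen_right=onset_sbrs + 0.2 - 0.05 * d)
        for d in (1.0, 3.0)
    ]
    return SubjectSeries(subject_id=sid, group="sPD", visits=visits, aao=aao)


class TestAnchoring:
    control = ControlAgingModel(c1=0.0, c2=2.0, n=100, residual_sd=0.1)

    def test_anchor_is_mean_of_subject_onset_sbrs(self):
        subs = [_pd_subject("A", 0.8, 50.0), _pd_subject("B", 1.2, 70.0)]
        traj = anchor_and_localize(lambda s: -0.1 * (s - 0.3), subs, self.control)
        assert traj.anchor_sbr == pytest.approx(1.0)
        assert traj.value_at(0.0) == pytest.approx(1.0)

    def test_age_axis_uses_median_aao(self):
        subs = [_pd_subject("A", 1.0, 50.0), _pd_subject("B", 1.0, 60.0),
                _pd_subject("C", 1.0, 70.0)]
        traj = anchor_and_localize(lambda s: -0.1 * (s - 0.3), subs, self.control)
        assert traj.motor_onset_age == pytest.approx(60.0)
        assert traj.ages[np.searchsorted(traj.times, 0.0)] == pytest.approx(60.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            anchor_and_localize(lambda s: -0.1, [], self.control)


class TestDegenerationOnset:
    def test_closed_form_crossing(self):
        # flat control line at 2.0; backward exponential from anchor 1.0
        # crosses at ln(1.7/0.7)/0.2 years before motor onset
        control = ControlAgingModel(c1=0.0, c2=2.0, n=10, residual_sd=0.1)
        sub = [_pd_subject("A", 1.0, 60.0)]
        f = lambda s: -0.2 * (s - 0.3)
        traj = anchor_and_localize(f, sub, control, step=0.01)
        onset_age, premotor = find_degeneration_onset(traj, control)
        expected = np.log(1.7 / 0.7) / 0.2
        assert premotor == pytest.approx(expected, abs=0.01)
        assert onset_age == pytest.approx(60.0 - expected, abs=0.01)

    def test_step_sensitivity_below_hundredth_year(self):
        control = ControlAgingModel(c1=0.0, c2=2.0, n=10, residual_sd=0.1)
        sub = [_pd_subject("A", 1.0, 60.0)]
        f = lambda s: -0.2 * (s - 0.3)
        onsets = []
        for step in (0.1, 0.01):
            traj = anchor_and_localize(f, sub, control, step=step)
            onsets.append(find_degeneration_onset(traj, control)[0])
        assert abs(onsets[0] - onsets[1]) < 0.01

    def test_flat_trajectory_below_line_raises(self):
        control = ControlAgingModel(c1=0.0, c2=2.0, n=10, residual_sd=0.1)
        traj = Trajectory(
            times=np.linspace(-30, 0, 301), values=np.full(301, 1.0),
            anchor_sbr=1.0, median_aao=60.0, step=0.1,
        )
        with pytest.raises(NoIntersectionError):
            find_degeneration_onset(traj, control)


class TestEndToEnd:
    def test_subject_order_permutation_invariance(self):
        cfg = SimulationConfig(n_controls=60, n_pd=80, seed=5)
        cohort, _, _ = simulate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = estimate_premotor_phase(cohort, "sPD")
            cohort.subjects = list(reversed(cohort.subjects))
            b = estimate_premotor_phase(cohort, "sPD")
        assert a.premotor_duration == pytest.approx(b.premotor_duration, abs=1e-9)
        assert a.anchor_sbr == pytest.approx(b.anchor_sbr, abs=1e-12)

    def test_window_bias_shrinks_with_followup_span(self):
        # per-subject slopes measure the decline near the window midpoint,
        # so the premotor estimate carries a positive bias that grows with
        # the follow-up span and vanishes as the window shrinks
        errs = {}
        for span in (4.0, 1.0):
            cfg = SimulationConfig(n_controls=150, n_pd=200, noise_sd=0.005,
                                   n_visits_per_subject=4, followup_span=span,
                                   motor_threshold_sd=0.0, k_log_sd=0.0,
                                   seed=17)
            cohort, truth, _ = simulate_cohort(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = estimate_premotor_phase(cohort, "sPD")
            errs[span] = est.premotor_duration - truth.median_premotor_duration
        assert errs[4.0] > errs[1.0] > -0.5
        assert abs(errs[1.0]) < 1.2

    def test_reduction_rate_consistent_with_trajectory(self):
        cfg = SimulationConfig(n_controls=60, n_pd=80, seed=5)
        cohort, _, _ = simulate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = estimate_premotor_phase(cohort, "sPD")
        traj = est.trajectory
        drop = est.control_model(est.onset_age) - traj.value_at(0.0)
        assert est.reduction_per_year == pytest.approx(
            drop / est.premotor_duration, rel=1e-6)
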