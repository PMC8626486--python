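"""Seeded synthetic cohorts with the longitudinal structure the estimator assumes.

The generator emulates a DAT-imaging study: healthy controls whose
averaged putaminal SBR declines linearly with age, and PD subjects whose
putaminal SBR follows the control line until a latent degeneration-onset
age and then decays as a negative exponential toward a floor.  Motor
onset is the first time the more-affected putamen drops below a fixed
fraction of the age-matched control mean, so every simulated subject
carries a noise-free ground-truth premotor duration against which the
full estimation pipeline can be checked.

Asymmetry between hemispheres is modelled as an onset lag: the
less-affected putamen starts the identical decline a few years later.
Both sides therefore obey the same autonomous rate law dS/dt = −k(S −
floor), which is exactly the structure the rate-function stage fits.

Every random component (onset ages, rate constants, visit schedules,
measurement noise, genotypes, control ages) draws from an independent
named substream of the master seed, so individual components can be
frozen in tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_cohort import Cohort, SubjectSeries, VisitRecord


class NoPhenoconversionError(RuntimeError):
    """The simulated trajectory never crosses the motor-onset threshold."""


@dataclass(frozen=True)
class GroupModifier:
    """Group-level shift of the latent onset age and multiplier on k."""

    k_multiplier: float = 1.0
    onset_age_offset: float = 0.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults are tuned to the magnitudes of a multi-site DAT-SPECT
    study: the control line gives mean putaminal SBR ≈ 2.13 at age 61,
    PD subjects convert ≈ 10 years after latent onset at the default
    rate constant and threshold, and the more-/less-affected baseline
    split lands near 0.7 / 1.0.
    """

    n_controls: int = 200
    n_pd: int = 300
    # non-PD aging line: SBR = intercept + slope * age
    control_intercept: float = 2.74
    control_slope: float = -0.01  # SBR / year, negative
    control_age_mean: float = 61.0
    control_age_sd: float = 11.0
    control_age_range: tuple[float, float] = (40.0, 85.0)
    # PD state
    onset_age_mean: float = 50.0  # latent degeneration onset, years
    onset_age_sd: float = 8.0
    decline_rate_k: float = 0.15  # 1 / year
    k_log_sd: float = 0.15  # between-subject lognormal spread of k
    decline_floor: float = 0.30  # SBR
    motor_threshold_frac: float = 0.35  # fraction of age-matched control mean
    # between-subject spread of the motor threshold fraction: real cohorts
    # show wide variation in SBR at motor onset (median [IQR] ~0.75 [0.34])
    motor_threshold_sd: float = 0.05
    # the less-affected side starts the same decline later, after this
    # fraction of the subject's premotor interval has elapsed (a fixed
    # fraction of disease progress, so the inter-side SBR gap at
    # presentation is comparable across fast- and slow-declining groups)
    asymmetry_onset_frac: float = 0.30
    # visit schedule: protocol follow-up grid (years after baseline); with
    # fewer visits than grid points, missed follow-ups are dropped at random
    protocol_visit_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0)
    n_visits_per_subject: int = 3
    followup_span: float = 4.0  # years, <= 5
    baseline_duration_max: float = 3.0  # disease duration at first scan ~ U(0, max)
    # measurement
    noise_sd: float = 0.10  # SBR units, per region per visit
    # caudate (copies the putaminal machinery, slower decline)
    caudate_scale: float = 1.394
    caudate_k_fraction: float = 0.5
    # group structure: sizes per PD group and their modifiers
    pd_group_sizes: Mapping[str, int] | None = None  # default {"sPD": n_pd}
    group_modifiers: Mapping[str, GroupModifier] = field(default_factory=dict)
    # genetics: optional GRS layer
    with_genotypes: bool = False
    n_snps: int = 45
    # high polygenic load -> earlier latent onset but slower decline; the
    # slower decline lengthens the premotor phase (~+1 yr/SD), so the onset
    # shift is sized to leave a net motor-AAO correlation near -0.14
    grs_onset_shift_per_sd: float = -2.2  # years of latent onset per GRS SD
    grs_k_multiplier_per_sd: float = 0.90  # k *= mult**z
    seed: int = 0

    def validate(self) -> None:
        if self.control_slope >= 0:
            raise ValueError("control_slope must be negative")
        if self.decline_rate_k <= 0:
            raise ValueError("decline_rate_k must be positive")
        if not 0 < self.motor_threshold_frac < 1:
            raise ValueError("motor_threshold_frac must be in (0, 1)")
        if self.followup_span > 5:
            raise ValueError("followup_span must be <= 5 years")
        if not 2 <= self.n_visits_per_subject <= 4:
            raise ValueError("n_visits_per_subject must be 2-4")

    def control_line(self, age):
        return self.control_intercept + self.control_slope * np.asarray(age, float)

    def groups(self) -> dict[str, int]:
        return dict(self.pd_group_sizes) if self.pd_group_sizes else {"sPD": self.n_pd}


@dataclass
class GroundTruth:
    """Per-subject latent quantities the generator knows and the data hide."""

    table: pd.DataFrame  # subject_id, group, onset_age, motor_onset_age, premotor_duration, k

    @property
    def median_premotor_duration(self) -> float:
        return float(self.table["premotor_duration"].median())

    def for_group(self, group: str) -> "GroundTruth":
        return GroundTruth(self.table[self.table["group"] == group].reset_index(drop=True))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["onset", "rate", "schedule", "noise", "genotype", "control_age", "side"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _visit_offsets(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Scan times (years after the first scan) for one subject.

    Visits sit on the study's protocol grid truncated to the follow-up
    span; a subject with fewer scans than grid points has missed
    follow-up visits, dropped at random (the baseline scan is always
    kept).  Spans shorter than the grid spacing fall back to evenly
    spaced scans.
    """
    n = config.n_visits_per_subject
    grid = [g for g in config.protocol_visit_grid if g <= config.followup_span]
    if len(grid) < n:
        return np.linspace(0.0, config.followup_span, n)
    if len(grid) == n:
        return np.asarray(grid)
    followups = rng.choice(grid[1:], size=n - 1, replace=False)
    return np.concatenate([[grid[0]], np.sort(followups)])


def simulate_control(config: SimulationConfig, streams, subject_id: str) -> SubjectSeries:
    """One healthy control: linear SBR-vs-age decline plus measurement noise."""
    lo, hi = config.control_age_range
    age0 = float(np.clip(
        streams["control_age"].normal(config.control_age_mean, config.control_age_sd),
        lo, hi,
    ))
    noise = streams["noise"]
    visits = []
    for off in _visit_offsets(config, streams["schedule"]):
        age = age0 + off
        put = config.control_line(age)
        cn = config.caudate_scale * put
        visits.append(VisitRecord(
            age_at_visit=age,
            sbr_putamen_left=put + noise.normal(0, config.noise_sd),
            sbr_putamen_right=put + noise.normal(0, config.noise_sd),
            sbr_caudate_left=cn + noise.normal(0, config.noise_sd),
            sbr_caudate_right=cn + noise.normal(0, config.noise_sd),
        ))
    sex = "F" if streams["control_age"].random() < 0.4 else "M"
    return SubjectSeries(subject_id=subject_id, group="control", visits=visits, sex=sex)


def latent_sbr(config: SimulationConfig, onset_age: float, k: float, age) -> np.ndarray:
    """Noise-free putaminal SBR: control line before onset, exponential decay after."""
    age = np.asarray(age, float)
    pre = config.control_line(age)
    s_onset = config.control_line(onset_age)
    post = config.decline_floor + (s_onset - config.decline_floor) * np.exp(
        -k * (age - onset_age)
    )
    return np.where(age < onset_age, pre, post)


def motor_onset_age(config: SimulationConfig, onset_age: float, k: float,
                    horizon: float = 80.0,
                    threshold_frac: float | None = None) -> float:
    """First age at which the declining latent SBR reaches the motor threshold.

    The threshold is ``motor_threshold_frac`` times the age-matched
    control line; the crossing is solved by bracketed root finding on
    the noise-free trajectory.  Raises :class:`NoPhenoconversionError`
    when no crossing exists within ``horizon`` years of latent onset
    (e.g. the decline floor sits above the threshold, or k ≈ 0).
    """

    frac = config.motor_threshold_frac if threshold_frac is None else threshold_frac

    def g(age):
        return (latent_sbr(config, onset_age, k, age)
                - frac * config.control_line(age))

    # first sign change on a dense grid (the threshold line declines too,
    # so late re-crossings can exist; motor onset is the first crossing)
    grid = onset_age + np.linspace(0.0, horizon, int(horizon * 8) + 1)
    vals = np.array([g(a) for a in grid])
    below = np.nonzero(vals <= 0)[0]
    if below.size == 0:
        raise NoPhenoconversionError(
            f"trajectory never reaches {frac:.2f} of the "
            f"control line within {horizon:.0f} years of latent onset "
            f"(k={k:.4g}, floor={config.decline_floor})"
        )
    i = below[0]
    if vals[i] == 0:
        return float(grid[i])
    return float(brentq(g, grid[i - 1], grid[i], xtol=1e-10))


def simulate_pd_subject(config: SimulationConfig, streams, subject_id: str,
                        group: str = "sPD", grs_z: float = 0.0
                        ) -> tuple[SubjectSeries, dict]:
    """One PD subject plus their ground-truth record.

    The more-affected putamen leaves the control line at the latent
    onset age; the less-affected side starts the identical decline
    ``asymmetry_lag_years`` later.  Motor onset is solved on the
    noise-free more-affected trajectory, so ground truth is independent
    of measurement noise.
    """
    mod = config.group_modifiers.get(group, GroupModifier())
    onset = streams["onset"].normal(config.onset_age_mean, config.onset_age_sd)
    onset += mod.onset_age_offset + config.grs_onset_shift_per_sd * grs_z
    k = config.decline_rate_k * mod.k_multiplier
    if config.k_log_sd > 0:
        k *= float(np.exp(streams["rate"].normal(0.0, config.k_log_sd)))
    k *= config.grs_k_multiplier_per_sd ** grs_z

    # truncate at +/-2.5 SD so the threshold stays above the decline floor
    frac = float(np.clip(
        streams["onset"].normal(config.motor_threshold_frac, config.motor_threshold_sd),
        config.motor_threshold_frac - 2.5 * config.motor_threshold_sd,
        config.motor_threshold_frac + 2.5 * config.motor_threshold_sd,
    ))
    t_mo = motor_onset_age(config, onset, k, threshold_frac=frac)
    lag = config.asymmetry_onset_frac * (t_mo - onset)

    d0 = streams["schedule"].uniform(0.0, config.baseline_duration_max)
    durations = d0 + _visit_offsets(config, streams["schedule"])
    ages = t_mo + durations

    more = latent_sbr(config, onset, k, ages)
    less = latent_sbr(config, onset + lag, k, ages)
    kc = k * config.caudate_k_fraction
    cfg_cn = dataclasses.replace(
        config,
        control_intercept=config.caudate_scale * config.control_intercept,
        control_slope=config.caudate_scale * config.control_slope,
        decline_floor=config.caudate_scale * config.decline_floor,
    )
    cn_more = latent_sbr(cfg_cn, onset, kc, ages)
    cn_less = latent_sbr(cfg_cn, onset + lag, kc, ages)

    left_is_more = bool(streams["side"].random() < 0.5)
    noise = streams["noise"]

    def obs(x):
        return float(x + noise.normal(0, config.noise_sd))

    visits = []
    for i, age in enumerate(ages):
        pl, pr = (more[i], less[i]) if left_is_more else (less[i], more[i])
        cl, cr = (cn_more[i], cn_less[i]) if left_is_more else (cn_less[i], cn_more[i])
        visits.append(VisitRecord(
            age_at_visit=float(age),
            disease_duration=float(durations[i]),
            sbr_putamen_left=obs(pl),
            sbr_putamen_right=obs(pr),
            sbr_caudate_left=obs(cl),
            sbr_caudate_right=obs(cr),
        ))
    sex = "F" if streams["side"].random() < 0.35 else "M"
    series = SubjectSeries(
        subject_id=subject_id, group=group, visits=visits, sex=sex, aao=float(t_mo)
    )
    truth = {
        "subject_id": subject_id,
        "group": group,
        "onset_age": float(onset),
        "motor_onset_age": float(t_mo),
        "premotor_duration": float(t_mo - onset),
        "k": float(k),
        "grs_z": float(grs_z),
    }
    return series, truth


def simulate_genotypes(config: SimulationConfig, streams, subject_ids
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Risk-allele counts (subjects × SNPs) and a log-OR weights table.

    Single homogeneous population: per-SNP risk-allele frequencies are
    drawn once, counts are Binomial(2, p) per subject.
    """
    rng = streams["genotype"]
    snps = [f"rs{1000 + j}" for j in range(config.n_snps)]
    freqs = rng.uniform(0.1, 0.5, size=config.n_snps)
    weights = pd.DataFrame({
        "snp": snps,
        "risk_allele": rng.choice(list("ACGT"), size=config.n_snps),
        "log_or": rng.uniform(0.05, 0.35, size=config.n_snps),
    })
    counts = rng.binomial(2, freqs, size=(len(subject_ids), config.n_snps))
    genotypes = pd.DataFrame(counts, index=pd.Index(subject_ids, name="subject_id"),
                             columns=snps)
    return genotypes, weights


def _grs_z(genotypes: pd.DataFrame, weights: pd.DataFrame) -> pd.Series:
    w = weights.set_index("snp")["log_or"]
    grs = genotypes.mul(w, axis=1).sum(axis=1)
    sd = grs.std(ddof=1)
    return (grs - grs.mean()) / (sd if sd > 0 else 1.0)


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[Cohort, GroundTruth, dict[str, pd.DataFrame]]:
    """Compose a full cohort: controls, PD groups, optional genotypes.

    Returns the cohort, the per-PD-subject ground truth and an extras
    dict holding ``genotypes`` / ``weights`` tables when the GRS layer
    is enabled.  Per-subject failures (no phenoconversion) are
    re-raised with the subject index attached.
    """
    config.validate()
    streams = _streams(config.seed)
    subjects: list[SubjectSeries] = []
    truths: list[dict] = []

    for i in range(config.n_controls):
        subjects.append(simulate_control(config, streams, f"C{i:04d}"))

    pd_ids: list[str] = []
    plan: list[tuple[str, str]] = []
    idx = 0
    for group, n in config.groups().items():
        for _ in range(n):
            sid = f"P{idx:04d}"
            plan.append((sid, group))
            pd_ids.append(sid)
            idx += 1

    extras: dict[str, pd.DataFrame] = {}
    grs_z = pd.Series(0.0, index=pd_ids)
    if config.with_genotypes:
        genotypes, weights = simulate_genotypes(config, streams, pd_ids)
        extras = {"genotypes": genotypes, "weights": weights}
        grs_z = _grs_z(genotypes, weights)

    for sid, group in plan:
        try:
            series, truth = simulate_pd_subject(
                config, streams, sid, group=group, grs_z=float(grs_z[sid])
            )
        except NoPhenoconversionError as e:
            raise NoPhenoconversionError(f"subject {sid}: {e}") from e
        subjects.append(series)
        truths.append(truth)

    cohort = Cohort(
        subjects=subjects,
        metadata={"source": "dattraj.synthetic_cohort", "seed": config.seed,
                  "schema_version": 1},
    )
    truth = GroundTruth(pd.DataFrame(truths))
    return cohort, truth, extras
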