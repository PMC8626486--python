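# dattraj

Premotor-stage trajectory reconstruction of putaminal dopamine-transporter
binding in Parkinson disease.

Dopaminergic degeneration in Parkinson disease begins years before motor
symptoms, but longitudinal DAT imaging covers each patient for only a few
years. `dattraj` reconstructs the hidden multi-decade time course of
putaminal specific binding ratios (SBR = (target − reference)/reference)
from such short windows and dates the onset of degeneration, for
researchers modelling disease progression in cohorts like PPMI.

## The method

Each subject with ≥ 2 scans contributes, per putamen, a baseline SBR and
an annual change rate (the OLS slope of SBR on time). Treating subjects
as snapshots of one common disease course, the rate–level relation
defines a first-order ODE for the PD state,

    dS/dt = f(S),

where f is a restricted cubic spline (knots at the 5/35/65/95 — or, for
< 100 putamina, 10/50/90 — percentiles of baseline SBR) fitted through a
linear mixed model with a per-subject random intercept. The ODE is
integrated with the modified Euler (Heun) method, anchored at motor
onset with the mean per-subject SBR extrapolated to disease duration 0,
and placed on an age axis via the group's median age at motor onset.
The healthy state is the control aging line SBR = c1·age + c2; the
*premotor phase* is the interval between the backward trajectory's
intersection with that line and motor onset.

The package also provides a seeded synthetic-cohort generator with
ground-truth premotor durations (so the whole pipeline is testable
without restricted data), the subject exclusion and outlier-flag rules,
polygenic risk scores (GRS = Σ risk-allele count × log OR) with median/
quartile stratification, and mixed-model group comparisons of annual
change rates with Bonferroni correction.

## Worked example

```python
import warnings
from dattraj import SimulationConfig, simulate_cohort, estimate_premotor_phase

cfg = SimulationConfig(seed=1)                  # 200 controls, 300 PD
cohort, truth, _ = simulate_cohort(cfg)
est = estimate_premotor_phase(cohort, "sPD")

print(f"estimated premotor phase : {est.premotor_duration:.1f} years "
      f"(generator truth {truth.median_premotor_duration:.1f})")
print(f"degeneration onset age   : {est.onset_age:.1f} years")
print(f"SBR at motor onset       : {est.anchor_sbr:.2f} "
      f"({est.anchor_pct_of_control:.1f}% of age-matched controls)")
print(f"premotor SBR reduction   : {est.reduction_per_year:.2f} per year")
```

prints

```
estimated premotor phase : 10.3 years (generator truth 10.0)
degeneration onset age   : 49.3 years
SBR at motor onset       : 0.71 (33.0% of age-matched controls)
premotor SBR reduction   : 0.15 per year
```

i.e. on this synthetic cohort the degeneration is estimated to start
10.3 years before motor onset (truth: 10.0), at which point putaminal
binding has fallen to a third of the age-matched control level, losing
0.15 SBR units per year during the premotor phase. Biases of the
procedure under sparse, noisy follow-up are quantified in
[docs/methods.md](docs/methods.md).

The same stages are exposed on the command line:

```sh
dattraj simulate --out cohort.csv --truth truth.csv --seed 1
dattraj rates    --cohort cohort.csv --out rates.csv --report excl.json
dattraj estimate --cohort cohort.csv --group sPD --out traj.json
dattraj compare  --cohort cohort.csv --groups sPD,GBA --out contrasts.json
```

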