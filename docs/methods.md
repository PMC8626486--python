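# Methods

`dattraj` reconstructs the multi-decade trajectory of putaminal
dopamine-transporter (DAT) specific binding ratios (SBRs) in Parkinson
disease from short longitudinal imaging windows, and dates the onset of
dopaminergic degeneration relative to motor onset (the *premotor
phase*). This note records the model, the estimation procedure, the
synthetic-data design, the numerical choices, and the limitations that
the test suite quantifies.

## The estimation model

Two states are modelled:

**Non-PD state.** Before degeneration begins, a PD subject's putaminal
SBR is assumed to follow the healthy aging line, fitted by ordinary
least squares on all pooled control visits:

    SBR = c1 · age + c2,            c1 < 0.

**PD state.** After onset, the SBR level is assumed to evolve under an
autonomous first-order ODE

    dS/dt = f(S),

whose right-hand side is estimated from the cross-section of short
observation windows: each subject with ≥ 2 scans contributes, per
putamen, a baseline SBR and an annual change rate (the OLS slope of
SBR on time). The premise is that subjects observed at different
disease stages tile the common trajectory, so the (level, rate) cloud
traces out f.

f is fitted in two steps, exactly mirroring the estimation procedure
the package implements end to end:

1. a linear mixed model with a restricted-cubic-spline (RCS) basis of
   baseline SBR as fixed effects and a per-subject random intercept
   (each subject contributes two putamina, so repeated measures must
   not be treated as independent);
2. an RCS least-squares refit through the mixed model's population
   predictions at the training baselines. Step 2 is a projection onto
   the span of step 1's fixed effects and is near-idempotent; a config
   flag collapses the two steps.

Knots sit at the 5/35/65/95 percentiles of the baseline SBRs when ≥ 100
putamina are available, else at 10/50/90. The RCS basis is the
truncated-power natural-spline construction (linear outside the
boundary knots, C² everywhere); only the values of f are contractually
meaningful, the coefficients depend on this convention and are tagged
as such in the serialized form.

The trajectory is obtained by integrating dS/dt = f(S) with the
modified Euler (Heun predictor–corrector) scheme, anchored at disease
duration 0 with the mean over subjects of the more-affected-side SBR
extrapolated to duration 0 from each subject's own linear fit. The
time axis converts to age by adding the group's median age at motor
onset. Degeneration onset is the intersection of the
backward-integrated PD curve with the control aging line; the premotor
duration is motor-onset age minus that intersection age. The headline
summary statistics are the premotor duration, the anchor SBR as a
percentage of the age-matched control mean, and the mean premotor SBR
reduction per year, (SBR at onset − anchor)/premotor duration.

### Data-cleaning rules

- *Exclusion rule*: a PD subject whose more-affected putamen shows both
  a baseline SBR above the control mean − 1.0 SD and a positive annual
  change is excluded (probable diagnostic or processing error); the
  rule acts at subject level and is reported with the triggering
  values.
- *Outlier flags*: annual changes outside [Q1 − 3·IQR, Q3 + 3·IQR]
  (type-7 quartiles) are flagged for display only; flagged samples
  always remain in the fit.
- *More-affected side*: the putamen with the lower baseline SBR, ties
  broken toward the left. The clinical definition (symptom laterality)
  is not available in imaging-only tables; the imaging rule is the
  documented choice.
- *Baseline SBR*: the observed first-visit value by default; a config
  switch substitutes the subject's fitted value at the first scan.

## The synthetic cohort

Real source data for this design are access-restricted, so every stage
is validated against a seeded generator that emulates the study
structure and carries noise-free ground truth.

- **Controls**: baseline age ~ N(61, 11²) clipped to [40, 85]; SBR on
  the aging line 2.74 − 0.01·age (≈ 2.13 at age 61), plus N(0, 0.1²)
  measurement noise per region per visit.
- **PD subjects**: a latent degeneration-onset age T₀ ~ N(50, 8²); the
  more-affected putamen follows the control line until T₀, then decays
  as floor + (S(T₀) − floor)·exp(−k(t − T₀)) with floor 0.3 and
  k = 0.15/yr (per-subject lognormal spread, log-SD 0.15). The
  less-affected side starts the identical decline after 30% of the
  premotor interval has elapsed. A fixed *time* lag was rejected: it
  makes the inter-side SBR gap grow with k, contradicting the observed
  near-constant more/less-affected separation across fast and slow
  groups, and it would give the two sides different autonomous rate
  laws; with an onset lag both sides obey the same dS/dt = −k(S−floor),
  which is the structure the estimator fits.
- **Motor onset**: the first age at which the noise-free more-affected
  trajectory reaches a subject-specific fraction of the age-matched
  control line, fraction ~ N(0.35, 0.05²) truncated at ±2.5 SD. The
  spread reflects the wide between-subject variation of SBR at motor
  onset seen in real cohorts (median [IQR] ≈ 0.75 [0.34]); ground truth
  (onset age, motor-onset age, premotor duration, k) is independent of
  measurement noise. With these defaults the median true premotor
  duration is ≈ 9.8–10 yr and the SBR at motor onset ≈ 35% of the
  control mean.
- **Visit schedule**: scans sit on the protocol grid 0/1/2/4 years
  after the first scan; subjects with fewer scans drop follow-ups at
  random (missed visits). Baseline disease duration ~ U(0, 3) yr.
  Spans shorter than the grid fall back to evenly spaced scans.
- **Group modifiers** multiply k and shift the onset age (e.g. a
  GBA-like group with k ×1.27). The **GRS layer** draws 45-SNP
  genotypes (allele frequencies U(0.1, 0.5), log-OR weights
  U(0.05, 0.35)) and applies, per GRS standard deviation, −2.2 yr to
  the latent onset and ×0.90 to k. The onset shift is sized so that,
  net of the premotor lengthening caused by slower decline, the
  GRS-vs-motor-AAO correlation lands near −0.14.
- Named random substreams (onset, rate, schedule, noise, genotype,
  control ages, side) hang off one master seed so components can be
  frozen independently.

**What the generator does not emulate**: scanner or site effects,
caudate dynamics beyond a slowed copy of the putaminal machinery,
medication effects, dropout that is informative of disease severity,
non-exponential decline shapes, or population structure in the
genotypes. Passing tests therefore show that the pipeline recovers the
generator's idealized structure, not that the published estimates from
real cohorts are correct.

## Numerical choices

- Heun integration step 0.01 yr (second-order; verified ~4× error drop
  per halving); forward horizon 15 yr, backward search horizon 30 yr.
  Backward integration stops once the curve sits 25% above the control
  line, which bounds the exponential growth of reversed-time
  integration while guaranteeing the crossing is bracketed.
- Intersection: sign-change scan on the grid plus linear interpolation
  inside the bracketing step; with multiple crossings the one nearest
  motor onset is used. Step sensitivity at 0.1 → 0.01 is < 0.01 yr on
  the closed-form oracle.
- Mixed model fitted by maximum likelihood (REML available); a
  singular random-intercept variance (zero boundary) falls back to the
  identical fixed-effects OLS fit with a warning; genuine optimizer
  failure raises.
- SBR values are clipped at a floor of 0 during integration (clips
  are counted and warned about); f is linearly extrapolated outside
  the training range, and estimates flag when > 10% of the premotor
  segment relies on extrapolation.
- Quartiles and percentile knots use linear interpolation between
  closest ranks (numpy default, R type 7).
- Bonferroni correction min(1, p·m) with the family size recorded;
  which contrasts form a family is caller-declared.
- GRS assumes natural-log odds ratios (config-convertible); missing
  genotypes are skipped and reported, with an optional
  normalize-by-SNPs-used variant for sensitivity checks.

## Known biases and limitations (quantified by the test suite)

**Finite-window attenuation.** The per-subject OLS slope over a window
of length W measures the decline near the window midpoint, but the
procedure pairs it with the window-*start* baseline. For an exponential
decline this attenuates the fitted |f| by ≈ (1 − e^{−kW})/(kW), so the
backward-integrated premotor duration is overestimated in proportion.
With 4-year windows and k = 0.15 the noise-free overestimate is ≈ +2.3
yr; it vanishes as the window shrinks (the suite asserts this
monotonicity).

**Anchor extrapolation.** Linearly extrapolating a convex decay
backward to duration 0 underestimates the SBR at motor onset by a few
hundredths, adding ≈ +0.7 yr.

**Measurement-error dilution.** Noise shared between the observed
baseline and the slope from the same scans steepens the fitted f
(errors-in-variables with negatively correlated errors), offsetting
the two biases above by ≈ −2 yr at noise SD 0.1. The net bias under
the default study conditions (3 scans within 4 yr, noise 0.1) is
≈ +1.2 ± 0.6 yr on a 10-yr premotor phase; the suite's recovery check
(±1.5 yr in 18 of 20 seeds) therefore fails, typically at 14/20, and
the failure is reported rather than tuned away. All three mechanisms are
properties of the published procedure, not of this implementation:
with short windows, dense scans and low noise the pipeline recovers
ground truth to < 0.2 yr.

**Interaction-test calibration.** The group-comparison LMM (random
intercept only, Wald tests) is well calibrated (≈ 4% type-I at nominal
5% over 400 null simulations, 40 subjects/group) when every subject has
the complete 4-scan protocol. When subjects miss visits at random, the
per-subject slope variance becomes heteroscedastic across schedules and
the interaction test inflates to ≈ 8–9%; between-subject spread of the
rate constant (a random-slope feature the random-intercept model
ignores) adds further inflation. Calibration and group-power
experiments in the suite therefore use complete follow-up, and results
on schedule-mixed data should treat borderline interaction p-values
with caution.

**Problem sizes.** Simulation tests use 200 controls + 300 PD subjects
(recovery), 300 subjects per group (group ordering), 40 per group × 400
replicates (calibration); these sizes give the comparisons adequate
power while keeping the suite fast.

**No uncertainty bands.** The procedure has no a priori parametric
form for the trajectory, so no standard errors are attached to the
estimated curve; bootstrap wrappers are a documented extension point,
not an implemented claim.
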