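# Methods

This note documents the models, conventions and numerical choices behind
`penflux`, and what the synthetic-data tests do and do not establish.

## Measurement model

### Flux conversion

A period's emission rate is computed from the mean net concentration over
the period's non-excluded readings:

    flux (g/min) = c_net · Q · 1000 / (Vs · T_K / 273.15) · MW / denom

* `Vs` = 22.4 L/mol — the analyzers hold temperature and pressure constant,
  so a single molar volume is used for every gas.
* `T_K` — the sample temperature. Which sensor defines "sample temperature"
  is genuinely ambiguous in practice (analyzer-internal vs. enclosure
  RH/T sensor); the pipeline uses the enclosure sensor averaged over the
  period, and `period_flux` accepts any temperature the caller prefers, so
  the analyzer-constant-temperature convention is a one-line change.
* Net concentrations are *never* clamped at zero. Enclosures can read below
  ambient (consistently so for N2O), and truncation would bias daily means
  upward.
* No recovery-factor correction is applied to fluxes. A tracer-recovery test
  characterizes a facility but the analysis operates on uncorrected fluxes;
  the sealed-box simulation (below) checks that the *ideal* pipeline
  recovers ~100%.

### Airflow

Each enclosure has two fans calibrated at cycle start and end. Fan
efficiency decays between the two points; with exactly two calibrations the
only identifiable decay curve is a line, so per-fan flow is linear in time
and enclosure outflow is the sum over fans, evaluated at the period
midpoint. Extrapolation outside the calibration window raises.

### Validity rules

* Large-door and bunk-flap events exclude the affected enclosure's readings
  from 5 min before opening to 15 min after closing (inclusive endpoints);
  overlapping windows are unioned, making exclusion idempotent. Small-door
  traffic excludes nothing.
* A 15-min period is valid with ≥ 16 surviving 15-s readings (4 min).
* A day (0800-anchored; `time_s = 0` is 0800 of day 0) is valid with ≥ 4
  valid periods. The continuous nine-source rotation yields at most 11
  periods per enclosure-day.
* An invalid day is substituted by the arithmetic mean of the per-animal
  daily emissions of days d−2, d−1, d+1, d+2, all of which must exist and be
  valid; there is deliberately no deeper imputation rule. Substitution
  operates on the daily g/animal series, after aggregation.
* A period straddling the day boundary belongs to the day containing its
  start (the convention is unstated in the protocol; it is fixed and
  documented here). After a disruption the interrupted period is discarded
  and the rotation restarts at ambient.

### Aggregation

Daily rate = mean flux over valid periods × 1,440 min ÷ headcount that day.
Animals removed mid-day count through their removal day (deterministic and
conservative). Cumulative totals sum days 0..end−1; because measurements
stop at 0500 on day 91 the 0–91 interval covers days 0..90. Standardization
divides by the enclosure's arithmetic-mean unshrunk BW at the interval-end
measurement day (the pen is the experimental unit throughout) or, for the
91-d interval, by the pen-mean HCW.

## Statistical model

### Block ANOVA

The design is balanced: one enclosure per dose × sex cell per cycle
(3 × 4 × 2 = 24 units, residual df 14). Cycle is treated as a classical
block stratum. In this balanced layout the treatment F-tests, LSMeans, SEM
and contrasts are numerically identical to a REML mixed model with random
cycle, so the closed form is used; the one behavioural difference is that
the reported SEM (√(MSE/6)) excludes the cycle variance component, which a
PROC-MIXED-style LSMean standard error would include. Contrasts against
control are unadjusted pairwise t-tests on 14 df — deliberately no
multiplicity correction, matching planned-contrast practice. The interaction
gate reports pooled dose contrasts when the dose × sex p > 0.05 and
within-sex contrasts at p ≤ 0.05 (ties route within-sex). Unbalanced tables
raise: generalizing the estimator is out of scope.

### Categorical outcomes

Pen-level category counts are fitted with a binomial logit GLM with dose,
sex, dose × sex and cycle as fixed effects — the fixed-block approximation
of the random-cycle GLMM (denominator-df conventions for such GLMMs are
unsettled; the approximation is documented rather than guessed). Contrasts
vs control are Wald tests on the logit scale averaged over sexes. Whenever a
dose arm is empty or saturated, or the fit fails to converge, the model
falls back to a conditional exact test (control vs pooled treated), using a
2 × k generalization of Fisher's test that enumerates tables with fixed
margins and sums the probabilities of tables no more probable than the one
observed.

### Dose–response and effective doses

Five candidate mean-response shapes over doses {0, 1.38, 5.5, 22.0}, each
with two free parameters and continuous at its breakpoints: (1) linear to
22; (2) linear to 1.38 then flat; (3) linear to 5.5 then flat; (4) flat to
1.38, linear to 5.5, then flat; (5) flat to 1.38, linear to 22.

The original selection procedure ("smallest p-value indicating best fit")
is underdetermined: no slope t-test on four means with their SEM produces
p-values anywhere near the magnitudes such procedures report, so the exact
test is not reconstructible. The package's documented choice: estimate the
slope by OLS over the means on the sloped segment (the plateau means enter
through the candidate's continuity constraint), scale it by the candidate's
full-design dose spread, t = b_seg·√Sxx_full / SEM on the ANOVA residual
df, and select the smallest p (ties toward fewer segments). This statistic
was chosen because it is the variant that both ranks the candidates sensibly
on real LSMean patterns and recovers every generating shape as noise → 0;
a pure segment-variance test fails the latter for shape 4, and a full-LS
slope test ranks shape 2 above shape 3 on shallow-then-flat patterns. The
resulting p-values order the candidates but are not calibrated tail
probabilities, and the package treats them only as ranks.

Consequently the **maximum effective dose** (the selected plateau model's
join point) is gated on the overall ANOVA dose F-test (p ≤ 0.05) rather
than on the reconstructed slope p — the same gate that licenses the planned
contrasts from which the **minimum effective dose** (smallest dose with
contrast p < 0.05) is read. Models 1 and 5 have no plateau and return no
maximum effective dose. Candidate discrimination between shapes 1 and 5 is
intrinsically weak (their designs nearly coincide because 1.38 is small
relative to 22), so near-certain selection requires mean-level noise below
~0.1% of the response range — the selection-consistency simulations run at
that level.

## Synthetic trial generator

The generator emulates the trial's data-producing process, not cattle
physiology: effects are injected phenomenologically.

* **Emission rates.** Per-animal daily rates with a linear within-cycle ramp
  for NH3 (57.4 + 0.625·day g/animal/d, fitted to control totals of ~415 g
  over days 0–7 and ~7,783 g over 91 d; excreta accumulate, so emissions
  grow); constant rates for CH4 (115 g/d), CO2 (7.9 kg/d), H2S (0.23 g/d)
  and N2O (−0.30 g/d, a net sink relative to ambient).
* **Dose and sex effects.** Multiplicative NH3 dose effects (1.0, 0.911,
  0.881, 0.867) matching ~9/12/13% cumulative reductions; heifer/steer rate
  ratios of 0.88–0.96 for the positive-rate gases.
* **Variance components.** Lognormal, mean-one cycle (σ = 0.17) and pen
  multipliers (σ = 0.06–0.30 by gas; additive for sign-changing N2O). Pen
  σ's were back-solved from the contrast precision of the emulated trial
  (residual CVs of ~6–10%), and the larger cycle component reflects that
  most of the printed SEMs is season-to-season variance. Within-period
  analyzer noise and an AR(1) ambient baseline (φ = 0.9) sit on top.
* **Diurnal pattern.** A sinusoid (default amplitude 0.25, peak 1400) on
  the flux; the continuous rotation samples it essentially without bias,
  whereas restricting sampling to a fixed daytime window overestimates the
  daily mean — the property that motivates round-the-clock rotation.
* **Schedule.** 15-s readings, 15-min periods, nine sources; concentrations
  are synthesized by inverting the flux equation at the recorded (single
  precision) temperature and the period-midpoint airflow, so a noise-free
  configuration is recovered by the pipeline to ~1e-9 relative error — the
  conservation property the test suite asserts.
* **Husbandry tables.** Initial BW ~N(475/432, 20) kg by sex; per-dose ADG
  (1.27–1.43 kg/d); DMI targets 9.1/8.6 kg/d with 2% refusals; per-dose
  dressing fractions (0.615–0.628) and carcass-trait distributions matching
  the emulated dose patterns; daily Bernoulli removals (hazard 3.3e-4) with
  a 10-head floor.

What passing tests show: the pipeline arithmetic, filtering logic and
statistical machinery are correct for data with this structure. What they do
not show: robustness to real-world pathologies the generator omits —
analyzer drift and span errors, non-instant mixing after door events,
correlated multi-gas failures, weighing errors, or emission dynamics beyond
a smooth ramp plus sinusoid.

## Problem sizes

Default test configurations use shortened runs (4–10 days, one gas, one to
three cycles) chosen so each property is decisively testable at interactive
runtimes; the acceptance script runs the full 91-day, five-gas, three-cycle
trial once, plus 2,000 null ANOVA simulations, 500 coverage simulations and
100 selection draws per candidate shape.

## Known limitations

* Unbalanced designs (lost pens, missing cells) are rejected, not estimated.
* The GLMM for categorical outcomes is approximated with fixed blocks.
* Dose–response p-values are ranking statistics (see above).
* The quality-grade mapping covers A/B-maturity carcasses only; marbling
  breakpoints follow the standard USDA marbling-degree boundaries (≥700
  Prime; 600 upper 2/3 Choice; 500 low Choice; 400 Select; below, Standard).
* The N-conservation efficiency evaluates the carcass equivalence factor at
  reporting precision (31.1 kg per kg NH3); using full precision shifts
  efficiencies by ~0.1 point.
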