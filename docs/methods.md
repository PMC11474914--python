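# Methods

## Model structure

The decision model is a closed-cohort, discrete-time Markov model with
three states: controlled glycaemia (HbA1c < 7%), uncontrolled glycaemia
(HbA1c ≥ 7%) and death. Cycle length is one year. The cohort enters at
age 40 with 16% controlled / 84% uncontrolled and is propagated until
age 100, where death is forced (the conventional operationalisation of
a "lifetime" horizon with an age-indexed mortality table). There are no
explicit complication states: complications enter as state-specific
annual costs, and the health burden of poor control enters through a
lower utility and a mortality relative risk.

Within a cycle, events are sequenced **death first, then transition**:
background mortality removes occupancy from each living state, then
survivors redistribute according to the strategy's annual HbA1c
transition matrix. No published convention exists for this ordering, so
it is a config switch (`engine.death_first`); the default is death
first, and the panel simulator uses the same order so that estimation
targets are consistent with the engine. Rewards (cost, QALY, LY) accrue
on the **post-transition** occupancy and are discounted by
`(1 + r)^{-t}` with the first cycle at `t = 1`, `r = 3%/year` by
default. A half-cycle correction (averaging start- and end-of-cycle
occupancy) is available but off by default. These conventions matter at
the second decimal of lifetime totals, which is why they are explicit
config options rather than hard-coded choices.

Mortality applies the relative risk for uncontrolled diabetes
(RR = 1.30, 95% CI 1.08–1.55) on the **hazard scale**:
`q_u = 1 − exp(−RR · r(age))`, the standard treatment of an all-cause
mortality relative risk. Controlled patients take the background rate
unchanged.

The engine is vectorised over a batch axis (`run_cohort_batch`), so a
probabilistic sensitivity analysis propagates thousands of parameter
draws in a single pass; the scalar `run_cohort` is the batch of size
one and a regression test pins their equality.

## Parameters

Defaults (all overridable via YAML config; an empty file is the base
case):

| Parameter | Default | Units / note |
|---|---|---|
| start age / max age | 40 / 100 | years |
| discount rate | 0.03 | per year, 0–5% in one-way SA |
| initial controlled fraction | 0.16 | — |
| utilities (controlled / uncontrolled) | 0.75 / 0.71 | EQ-5D-3L tariff values; a source text variant of 0.76 for controlled is accepted via config |
| mortality RR (uncontrolled) | 1.30 | CI 1.08–1.55 used in one-way SA |
| annual P(u→c) by strategy | 0.17 / 0.24 / 0.26 / 0.28 | annual, 6-, 4-, 3-monthly |
| annual P(c→u) by strategy | 0.58 / 0.67 / 0.69 / 0.69 | idem |
| unit costs | 244.66 (inpatient day), 38.97 (clinic visit), 81.55 (emergency/outpatient visit), 59.31 (treatment) | 2019 USD |
| complication costs | 398.53 / 510.12 | controlled / uncontrolled (ratio 1.28) |
| testing panel by tests/year | 106.46 / 116.11 / 125.75 / 135.40 | 1–4 HbA1c tests plus fixed annual investigations |
| threshold λ | 2661.97 | USD per QALY |

Currency arithmetic is internal USD 2019; ZAR inputs convert at
R14.45/USD, and a CPI map supports re-basing costs from other years.
The medication mix (22/27/41/9% across regimens — published values,
which sum to 0.99) is stored for documentation and sensitivity use
only; costing uses the single published average treatment cost.

### Inpatient annualization factor

The published mean inpatient days (7–9 days/year) multiplied by the
published per-day cost (USD 244.66) cannot be reconciled with the
published cohort-average annual cost (~USD 1004): the implied inpatient
component alone would be ~USD 2100. The costing layer therefore carries
an explicit `inpatient_annualization_factor` in [0, 1] multiplying mean
inpatient days before costing. By default it is **calibrated** in
closed form (the annual cost is affine in the factor) so that the
0.16/0.84-weighted annual cost at one test/year equals USD 1004.39;
the solution is ≈ 0.0602. This is an engineering bridge that preserves
every published unit cost while matching the published total; the
calibration event is logged, and the factor can be pinned in config.
A consequence worth knowing: the cohort-average cost difference between
testing frequencies is exactly the testing-panel price difference,
because all other components are frequency-invariant.

## Transition estimation

Patients are observed exactly at the monitoring interval, so estimation
uses the discrete-time Markov MLE at that interval — row-normalised
counts of consecutive-visit state pairs — annualised by raising the
interval matrix to the number of intervals per year. A continuous-time
intensity model would add nothing here, since observations are exactly
equally spaced by design. Pairs in which the patient dies before the
next visit are dropped: mortality enters the cohort model through the
life table and relative risk, and keeping death-censored pairs would
double-count it. Confidence intervals are a nonparametric bootstrap
over patients (default B = 1000, percentile method, seeded); resampling
visits instead of patients would break within-patient dependence. An
origin state with *no* observed pairs raises an error (no silent
prior); a degenerate row (all pairs to one state) yields a 0/1 estimate
with a warning.

## Synthetic data

The generator stands in for three restricted inputs.

**Life table.** Gompertz–Makeham annual hazard
`r(x) = c + a·e^{bx}` with `c = 0.003`, `a = 3×10⁻⁵`, `b = 0.095`
over ages 40–100 — a plausible adult schedule for a middle-income
population (hazard ≈ 0.004 at 40, ≈ 0.06 at 80; period life expectancy
at 40 in the low-to-mid 30s). It does not reproduce any real
population's rates, so model outputs that depend on it (absolute costs,
QALYs, LYs) are checked for structure — orderings, plausible ranges,
frontier shape — not for value equality with the published table.

**HbA1c panels.** Patients enter at uniform ages 40–65 (the emulated
registry's age distribution and follow-up are unknown, so both are free
parameters), are observed every interval, and between visits first face
an interval death risk `1 − exp(−RR_state · r(age) · Δt)` and then, if
surviving, an HbA1c transition drawn from the **interval root** of the
annual matrix — the real `(12/interval)`-th matrix root computed by
eigendecomposition, validated to be stochastic (not every annual matrix
embeds in a finer chain; invalid roots raise, naming the matrix). By
construction, annualising the interval dynamics recovers the generating
matrix exactly, so estimator bias can be measured against known truth.
All four default annual matrices have valid roots at 3, 4, 6 and 12
months.

**Utilization and utilities.** Per-patient draws use gamma
distributions (nonnegative, right-skewed) for inpatient days, clinic
visits and emergency/outpatient visits, and a beta distribution for the
EQ-5D utility, moment-matched to the published patient-level mean/SD.

What the synthetic data does *not* emulate: record linkage, HbA1c assay
error (only the dichotomised state is modelled), informative
observation timing, real demography, or correlation between utilization
and glycaemic trajectory. Passing tests therefore demonstrate that the
pipeline recovers parameters and reproduces decision structure under
its own assumptions — not that it would do so on the real registry.

## Sensitivity analyses

**One-way.** Cost and utilization parameters vary ±25% of base;
probabilities (transitions, mortality RR) vary over their 95% CIs; the
discount rate over 0–5%. The default outcome is the deterministic ICER
of 6-monthly vs annual monitoring. The calibrated inpatient factor is
frozen at its base value before perturbation — otherwise recalibration
would absorb exactly the variation being tested.

**Probabilistic.** Each iteration draws all parameters simultaneously
and runs all four strategies on the same draw (common random numbers).
Families follow the base-case table: beta for probabilities and
utilities, gamma for costs and utilization, hyperparameters by method
of moments. Uncertainty magnitudes are *standard errors of the means*:
transition CIs already are (SE = CI width/3.92); the trial-derived
utilization and utility rows publish patient-level SDs, converted via
SD/√n with the trial enrolment n = 632 (`psa.trial_n`). Mixing raw
patient-level SDs (utility SD 0.35) with CI-derived SEs (transition SE
≈ 0.013) would weight utilities hundreds of times too heavily and wash
out the strategy comparison. Unit costs without published SDs use a
coefficient of variation of 0.25, mirroring the one-way range. The
four testing-panel costs share one gamma-distributed scale factor:
they are built from the same component tests, and independent draws
would violate their monotone-in-frequency invariant. Transition rows
are parameterised by a single off-diagonal probability each, so they
cannot leave the simplex; a renormalisation guard still counts and
repairs any violation. The mortality RR is held at base in the PSA (it
is examined one-way instead).

The CEAC reports, at each λ on a 0–10 000 grid (step 100), the
fraction of iterations in which each strategy attains the maximum net
monetary benefit, ties split equally — columns sum to one by
construction. With base-case distributions the cheapest strategy
(annual) dominates at low λ and the most effective (3-monthly) at high
λ, with 6-monthly peaking in between; the crossing location inherits
Monte-Carlo and life-table uncertainty and is asserted only to exist.

## Frontier and decision rules

Strategies sort by ascending cost, ties resolved toward fewer tests per
year (less intervention), logged. Absolute dominance removes options
that cost at least as much and deliver no more effect (one comparison
strict; exact duplicates keep the lower-intensity strategy). Extended
dominance is the lower-convex-hull sweep: a kept option whose ICER to
its predecessor is at least the ICER of the next more effective option
is removed, so surviving frontier ICERs strictly increase (collinear
middle points drop under this strict rule). The decision at threshold λ
is the most effective frontier member whose ICER does not exceed λ (the
cheapest qualifies unconditionally); a property test verifies this
coincides with arg-max net monetary benefit among frontier members on a
dense λ grid. ICERs are always computed from unrounded engine output;
rounding to two decimals happens only at serialization. Recomputing
ICERs from *rounded* published inputs gives different values (e.g.
123.64/0.05 = 2472.8), which is why worked-example checks target net
monetary benefit cells — those reproduce exactly — rather than
published ICER strings.

## Subgroups

Entry-state subgroup runs ("controlled"/"uncontrolled" at time 0) reuse
the overall transition matrices with the initial distribution set to
(1, 0) or (0, 1). The original analysis estimated subgroup-specific
matrices from restricted data that are not available here; the report
bundle flags the approximation. Config placeholders accept
subgroup-specific matrices if they become available.

## Problem sizes and numerics

Default runs use a 60-cycle horizon, 5000-patient / 5-year panels for
estimation studies, B = 400–1000 bootstrap resamples and 10 000 PSA
iterations; the full suite executes in seconds because the engine is
vectorised. Occupancy conservation is enforced to 1e-9 per cycle;
matrix stochasticity to 1e-9 with clipping of eigendecomposition
residuals below 1e-12; beta-infeasible variances shrink to 95% of the
feasibility bound with a warning. All stochastic stages accept a single
integer seed and are bit-reproducible; the replication bundle embeds a
SHA-256 hash of the resolved config.

## Known limitations

- The synthetic life table is a stand-in; absolute lifetime totals are
  not comparable to analyses using national mortality estimates.
- The inpatient annualization factor is a calibration device, not an
  estimate of anything observable.
- No patient-perspective costs, mortality-event costs, or
  lipid/blood-pressure medication costs; no explicit complication
  states; no covariate-adjusted or misclassification-aware transition
  models; no EVPI/EVPPI or distributional analysis.
- The QALY threshold is applied as published even though it was derived
  on a DALY scale.
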