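# Methods

## Model structure

The model is a six-state Markov cohort simulation run in monthly cycles
over a 3-year horizon. States: risk-factor-negative (RF-), RF+ enrolled in
the lifestyle program, RF+ not enrolled, stable diabetes, complicated
diabetes, dead. "Risk-factor-positive" encodes metabolic syndrome plus
excess weight; its components are not modelled individually — the screening
outcome enters only as the probability of screening positive (0.31).
Complicated diabetes is likewise a single pooled state (neuropathy,
nephropathy, stroke, CHD are not separate states); its comorbidity burden
enters through cost multipliers only.

Two strategy arms share every parameter. Under usual care nobody is
screened into a program: all RF+ mass starts non-enrolled and no screening
or program costs are charged. Under the intervention, screening happens
once at model start (cost $35 per positive, $32 per negative screen) and
47% of positives enroll (program cost $219, charged once). There is no
re-screening or re-enrollment: an enrollee who resolves to RF- and later
relapses re-enters the *non-enrolled* RF+ state.

Enrollment effects while RF+: diabetes risk 4.8%/yr instead of 10.8%/yr,
metabolic-syndrome resolution 16.2%/yr instead of 12.1%/yr during model
year 1 (both groups resolve at 12.1%/yr in years 2-3 in the base case), and
utility 0.75 instead of 0.73. Program withdrawal is folded into the
intent-to-treat effectiveness and enrollment inputs; there is no separate
dropout transition.

## Cycle mechanics and conventions

Several sub-annual conventions are needed that a yearly description leaves
open; each is fixed as follows and exercised by tests:

* **Annual→monthly conversion**: `p_month = 1 - (1 - p_year)^(1/12)`
  (constant hazard). Twelve-cycle compounding recovers the annual
  probability to 1e-12.
* **Competing risks within a cycle**: death is applied first at the
  baseline-mortality hazard scaled by the state's relative risk
  (`q_month = 1 - (1 - q_mix)^(rr/12)`); all other transitions are
  conditional on survival, with the stay-probability as residual. Rows are
  checked to sum to 1 within 1e-12, and combined exits above 1 raise
  (unreachable at documented ranges; a guard for extreme draws).
* **Mortality mixing**: the cohort is pooled, so female and male annual
  death probabilities are mixed with the cohort's female fraction (0.75)
  *before* the relative risk and monthly conversion. At these ages and a
  3-year horizon the alternative (two parallel sex cohorts) differs at the
  second order.
* **Ageing**: the cohort's integer age advances one year every 12 cycles
  from the starting age (55 in the base case).
* **Rewards**: accrue at cycle start (state-at-start, no half-cycle
  correction); utilities and annual costs are divided by 12; discounting
  uses the compound-equivalent monthly factor `(1 + r)^(-t/12)` with
  r = 0.03/yr.
* **Cumulative incidence** is tracked by inflow accounting (total mass ever
  entering stable/complicated diabetes), not end-of-horizon occupancy.

## Costs and multipliers

Annual state costs: RF+ $1,296, RF- $616, stable and complicated diabetes
$1,684 base, all USD (2000). Demographic multipliers (female 1.14/1.25,
African American 0.82) apply to the RF+ and both diabetes costs; the five
comorbidity multipliers (angina 1.73, treated hypertension 1.24, MI history
1.90, stroke history 1.30, PVD 1.31) apply to complicated diabetes only —
the parameter table associates them with that state, and the switch is a
one-line change in `engine.py` if a different reading is wanted. The RF-
cost carries no multiplier (none is documented for it). The cohort engine
uses the expectation over independent condition flags,
`∏ (1 + prev·(mult - 1))`; the microsimulation samples the flags per
individual and confirms the expectation empirically.

## Baseline mortality

Background mortality is an annual probability of death by integer age and
sex, supplied as a CSV life table (`age,sex,q_annual`). The bundled default
(`life_table_us2000_synthetic.csv`, ages 45-70) is a **synthetic** Gompertz
table — male hazard `8.75e-5 · exp(0.085 · age)`, female hazard factor
0.57 — calibrated so q(45), q(55) and q(70) by sex approximate published
year-2000 US all-cause values (e.g. q(55) ≈ 0.0093 male, 0.0053 female).
It is not an official life table; any table in the same layout can be
substituted. Baseline mortality is a second-order input here: the cohort is
55-58 years old for only 36 cycles, and the discount sweep and tornado
confirm results are insensitive to it.

## Sensitivity analyses

**One-way (tornado)**: every non-fixed parameter is set to each end of its
documented range, all else at base, and both arms re-run; entries are
ranked by the width of the ICER interval, with entries whose swing stays
under $7,000/QALY flagged as minor. Cost-saving (dominant) endpoints are
ranked at $0/QALY. The starting age (range 45-65) is varied like any other
parameter, rounded to integer years. The discount rate is swept 0-5%
separately.

**Probabilistic (PSA)**: 1,000 independent joint draws, one per iteration,
no covariance between parameters. Families follow the parameter table:
probabilities and prevalences beta, utilities and one-time costs uniform,
death relative risks log-normal, cost multipliers normal; annual state
costs and the RF- relative risk are fixed. Calibration of each family from
(base, low, high): uniform ranges are hard support; normal uses mean = base,
sd = (high - low)/3.92; log-normal uses log-mean = ln(base) (median at
base), log-sd = (ln high - ln low)/3.92; beta pins the mean to the base
value and fits the concentration so the central 95% interval matches
(low, high) as closely as possible, falling back to method-of-moments
(sd = (high - low)/3.92) if the fit fails. Ranges for beta/log-normal/
normal are therefore read as central 95% intervals. Draws violating a
parameter invariant (e.g. a negative normal multiplier) are redrawn and
counted. Per-draw preference at a willingness-to-pay λ uses net monetary
benefit λ·ΔE − ΔC, which orders dominant/dominated draws correctly; the
CEAC reports the preferred fraction over a threshold grid including
$20,000 and $50,000 per QALY.

**Scenarios**: `no_resolution_after_y1_both` and
`no_resolution_after_y1_enrolled_only` alter the year-2-3 resolution rates;
`equal_rfpos_utilities` sets the non-enrolled RF+ utility equal to the
enrolled value (0.75 — equalized *to* the in-program weight);
`worst_case_3` combines equalized utilities with in-program diabetes risk
raised to 9.8%/yr and RF- utility lowered to 0.77; `worst_case_4` further
cuts in-program resolution to 14.1%/yr. Scenario overrides are applied as
point values (their originating ranges do not travel with them).

## Microsimulation oracle

`microsim.simulate_individuals` walks individuals through exactly the
per-cycle transition matrices of the cohort engine, so its sample means are
unbiased for the cohort expectations; the test suite requires agreement
within 3 Monte-Carlo standard errors at 200,000 individuals in the base
case and at 20,000 individuals across 20 random PSA draws. Sampled sex and
race drive only the per-individual cost multipliers (mortality stays the
pooled mixture, matching the engine's design); comorbidity flags are drawn
independently at baseline with the documented prevalences and held fixed.
The draw order is fixed (demographics, screening, enrollment, then one
uniform per individual per cycle) so runs are reproducible per seed.

## What the synthetic inputs do and do not emulate

The synthetic life table reproduces the *shape* real background mortality
needs here (monotone increase with age, female below male, plausible
mid-life levels); it does not reproduce any official table's exact values,
cohort effects or secular trends. The PSA emulates the documented
distribution families and independence assumption; it does not model
parameter correlation, which would widen the decision uncertainty. Passing
tests therefore demonstrate internal consistency and faithful mechanics,
not calibration of any input to a particular population beyond the
documented base-case values.

## Problem sizes and runtime

The deliberate sizes are: 36 cycles × 6 states for deterministic runs,
2 × 39 extra runs for the tornado, 1,000 draws × 2 arms for the PSA, and
200,000 (base) / 20 × 20,000 (random-draw) individuals for the oracle
comparisons. The full test suite runs in well under a minute on one CPU;
`scripts/acceptance.py` in a few seconds.

## Known limitations

* Horizon is 3 years; benefits of sustained risk-factor resolution beyond
  the horizon are not counted, which biases against the intervention.
* Patient time costs are excluded (modified societal perspective); costs
  are year-2000 USD with no inflation adjustment.
* The worst-case scenario ICERs divide a cost difference by a
  quality-adjusted-life-year difference of order 1e-3 or less, so they are
  numerically delicate: small changes in any sub-annual convention move
  them by tens of percent while leaving the base case essentially
  unchanged.
* No EVPI/EVPPI, no correlated PSA, no cause-specific mortality.
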