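# Methods

## Model structure

The simulator couples a population model (initial cohort + annual
entrants) with an individual-level microsimulation. State per agent: age
(integer years ≥ 20), gender, continuous BMI (kg/m²), glycemic status
(no diabetes / prediabetes / diabetes, a discretization of fasting glucose
at 100 and 125 mg/dl), vital status, and event times (diabetes onset year,
death year). Diabetes is absorbing: estimated reversion out of the
diabetes state is renormalized away rather than simulated, which keeps the
incidence measure ("new cases among those not previously diagnosed")
well-defined and monotone.

Category maps use half-open intervals: BMI normal [0, 25), overweight
[25, 30), obese [30, ∞) — BMI below 20 is mapped to the normal category
for matrix lookup, with the underweight guard (< 18.5) enforced only by
the intervention; age groups are [20,25), [25,30), …, with 100+ as the
final open band (17 groups).

### Annual cycle

The phase order is fixed and identical for all agents in a year:
mortality → intervention (year 0 only) → age increment + BMI update →
glycemic transition. Consequences of this ordering, all deliberate:

- an agent dying in year t counts in year-t mortality but does not age or
  transition that year;
- a newly incident diabetic faces the diabetic mortality model only from
  the following year;
- the intervention's BMI reduction lands before the year-0 transition, so
  the first year's transition stratum already reflects it (necessary for
  any first-year effect);
- the transition stratum is looked up at the moment of the glycemic phase
  (post-aging, post-BMI-update, post-intervention in year 0). The BMI
  drift stratum likewise uses the post-increment age.

Entrants (the population turning 20) are injected after the transition
phase, so they first progress in their second simulated year. Dead agents
are retained with a flag: denominators, conservation checks and paired-arm
id alignment all stay exact. Conservation —
alive(t+1) = alive(t) − deaths(t) + entrants(t) — is asserted in tests for
every year.

### Mortality

Never-diabetic agents: annual death probability from an age-gender life
table covering ages 20–110 (last value reused beyond). Ever-diabetic
agents: p = 1 − exp(−h₀·exp(β_age·age + β_male·1[male] + β_bmi·BMI + c)).
The covariates are deliberately restricted to age, gender and BMI; the
constant c shifts the log baseline hazard to absorb omitted risk factors
and is calibrated by bisection on c ∈ [−10, 10] (≤ 50 iterations) against
a target annual diabetic mortality rate. The calibration objective is the
*expected* cohort rate — the mean of per-agent probabilities — so it is
deterministic, strictly increasing in c, and bisection recovers a known
constant to ~1e-6 (verified against a closed-form oracle). Targets outside
the bracket raise with the reachable-rate diagnostics.

### BMI dynamics

Per (age group, gender) stratum the trend regression supplies a mean
annual change d. Each year the agent's BMI changes with probability
p_change; conditional on change, the increment is Normal(d/p_change, σ),
so the unconditional mean change equals d exactly. Defaults: σ = 0.5
kg/m², BMI floored at 15 (the floor truncation introduces a negligible
upward bias at the extreme left tail only). This Bernoulli-times-Normal
composition is the simplest family satisfying the mean constraint while
allowing year-to-year inertia.

### Transition-matrix estimation

From a longitudinal panel (subject, visit month, age, gender, BMI,
glycemic state), consecutive visit pairs whose spacing lies within ±25% of
the nominal interval are tallied per (age group, gender, BMI category)
stratum; each row of the stratum matrix is the maximum-likelihood count
proportion. Sparse strata are pooled hierarchically — drop the BMI split
first, then gender, then widen the age window one band at a time — and the
pooling path is reported through an optional log callback. Sub-annual
intervals are annualized by matrix power: exact multiplication for integer
powers, eigen-method fractional powers with row-wise Euclidean projection
onto the probability simplex otherwise, and a linear generator rescaling
I + s(P − I) (with a warning) when the matrix has no admissible real
power. The diabetes row is forced to (0, 0, 1) at the end and rows are
renormalized. Optional additive (Dirichlet) smoothing operates on the
pooled counts the estimator attaches (or on rows treated as a unit-mass
pseudo-sample when counts are absent); α = 0 is the identity and α → ∞
drives rows to uniform.

Recovery is verified by simulating panels from known matrices: 5,000
subjects × 4 annual visits recover entries to ≤ 0.02 max-abs error (≈0.004
typical); 6-month panels round-trip through the square-root/square pair to
≤ 0.03.

### Interventions

Three presets, all one-year programs applied to the same eligible pool
(alive, prediabetic, BMI ≥ 25, age in the target band, default 25–65):

| preset | BMI reduction | achievement rate | per-person cost |
|---|---|---|---|
| dpp | 7% | 38% | $1,399 |
| dpp-ymca | 5% | 32.4% | $346 |
| help-pd | 5% | 58.5% | $452 |

Achievement is all-or-nothing per person; every eligible person
participates and is charged the per-person cost regardless of achievement.
The reduction is applied once in year 0 and afterwards BMI evolves by the
ordinary drift model from the reduced value (no rebound; a rebound flag on
the spec restores pre-intervention BMI for sensitivity analysis). The
reduction is never applied below BMI 18.5 and never pushes BMI below that
floor. Per-person costs are configuration defaults taken from the
published first-year cost analyses of the three trials; their ratios
(≈ 4.05 DPP:DPP-YMCA, ≈ 1.31 HELP-PD:DPP-YMCA) match the ratios implied by
the published total-cost columns for a shared participant pool.

### Paired comparison and outcome measures

Control and intervention arms start from a bit-identical population and
share every random stream. Streams are keyed by (master seed, phase,
year), and per-agent draws are always made for the full id-aligned array
(dead agents included), so the arms stay aligned even after deaths
diverge — common random numbers in the strict sense: a zero-achievement
intervention yields bit-identical arms, and per-draw monotonicity of the
cumulative-threshold transition sampling means a BMI reduction can only
delay, never hasten, a given agent's transitions for the same uniforms.

Measures (all per 100): incidence = new cases / (alive − previously
diagnosed); prevalence = diabetic / alive (end of year, entrants
included); diabetes mortality = deaths of ever-diabetic agents / alive at
the start of the year. Improvement = (rate_noI − rate_I)/rate_noI.

Diabetes-free-survival gain, per shared id: onset in both arms → onset
delay (intervention minus control; the sign convention makes a postponed
onset a positive gain, matching the gain/loss labels of the measures it
feeds); neither arm → 0; control-only onset at t → horizon − t; there is a
symmetric negative loss for intervention-only onset; agents dying before
onset in either arm are excluded. Prevalent baseline diabetics fall in the
both-arms branch with gain 0, i.e. they dilute the mean exactly as a
whole-population mean should. Deaths averted are reported both all-cause
and diabetes-attributable, since the published accounting does not say
which it counts.

Cost accounting: aversion savings = cases averted × per-case benefit B
(default $85,200, the age-gender weighted lifetime medical cost of one
diabetes case implied consistently by all twelve published
intervention × age-band cells); total savings = aversion savings − program
cost. These identities hold exactly by construction and reproduce every
published total, including the sign of DPP's losses. Savings are
undiscounted by default; `discounted_savings` applies an annual discount
rate to the year-of-onset averted-case stream for sensitivity analysis.
The optimal-target-population search iterates the four standard bands
(25–65, 35–65, 45–65, 55–65); arbitrary bands are available through the
spec's age-band override.

## Synthetic scenario

The generator stands in for the non-public longitudinal panel and
census/survey input tables. Defaults (fixture choices, not calibration
claims): Gompertz life table (male above female, monotone in age);
diabetic hazard ≈ 1.5–2× the non-diabetic at matched age before
calibration; transition probabilities increasing in age group and BMI
category with a 12%/yr prediabetes-to-normal reversion; BMI trend +0.18
kg/m²/yr in early adulthood declining to −0.15 in old age (p_change 0.7,
σ 0.5); joint initial distribution with U.S.-like age structure, diabetes
prevalence ≈ 6–8% and prediabetes ≈ 15–25% rising with age and BMI;
entrants 1.8% of the baseline count per year, predominantly normoglycemic.
The resulting 15-year trajectories show annual incidence ≈ 1 per 100
at-risk and prevalence passing through 8–10 per 100 mid-horizon. Within
cells, continuous BMI is uniform over the category interval (obese
truncated at 60) and exact ages uniform over the band's integer ages.

What the generator does **not** emulate: secular trends in the transition
matrices or entry distributions, correlation between BMI and glycemic
state beyond the category level, visit-level measurement error in the
panel, and non-participation. Passing tests therefore demonstrate the
mechanics, estimators and accounting are correct — not that any specific
national trajectory is reproduced; national-scale results require the real
input tables, which the CSV interfaces accept.

## Numerical and interface choices

- All randomness flows from one master seed through named (phase, year)
  substreams (Philox-backed numpy generators); identical seeds and inputs
  give bit-identical event streams, asserted in tests.
- Transition-row sampling uses cumulative thresholds with a final-index
  clip against float round-off; row sums are validated to 1 ± 1e-9.
- CSV round-trips are lossless: floats are written via `repr` and parsed
  with round-trip precision.
- The run manifest records the master seed, scenario parameters, package
  version and SHA-256 of every input table — sufficient to reproduce a run
  byte-identically.
- Problem sizes in the test and acceptance runs (50,000 agents, 15-year
  horizon, 30 replicate seeds; 5,000-subject panels) were chosen as the
  smallest sizes at which the directional intervention effects and
  recovery errors are comfortably resolved.

## Known limitations

Annual time step only; no competing-risk decomposition of causes of
death; no metformin arm, repeated/booster interventions or dose-response
adherence; no migration or child/adolescent modeling; no race/ethnicity,
family-history or physical-activity covariates; no QALY weighting. The
long-horizon (30-year) economics inherit the usual compounding uncertainty
of one-year-effect assumptions.
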