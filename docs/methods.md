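# Methods

This note documents the model implemented in `endotdm`: its structure and
assumptions, the conventions chosen where several were defensible, what the
synthetic generators do and do not emulate, and known limitations.

## Decision problem and model structure

The policy question is whether measuring serum endoxifen three months into
adjuvant tamoxifen therapy, and doubling the dose for patients below the
5.97 ng/mL target, is cost-effective for ERα-positive breast cancer in the
Netherlands. The model compares two strategies over the lifetime of a
cohort starting at age 53: *no monitoring* and *monitoring*.

The model is a three-state partitioned-survival cohort model on a 28-day
cycle grid running to age 100 (613 cycles). Rather than inventing per-cycle
transition probabilities, state occupancy is read directly from survivor
functions at each cycle boundary — the partitioned form is exact for the
defining identity RD = OS − DFS:

- `OS(t) = S_bc(t) · S_bg(t)`, breast-cancer mortality times background
  survival (independent additive hazards). OS is identical for both
  strategies and all subcohorts: monitoring is assumed to change time to
  recurrence but not overall survival.
- Each subcohort's disease-free occupancy is `min(S_dfs(t), OS(t))`;
  `RD = OS − DFS`, `dead = 1 − OS`.

### Survival inputs

Disease events follow lognormal accelerated-failure-time curves
`S(t) = 1 − Φ((ln t − μ)/σ)`, with the tabulated intercept μ (log-years)
and σ = exp(log-scale): recurrence-free survival for low-endoxifen
patients (μ = 3.28, σ = e^0.61, median ≈ 26.6 y) and breast-cancer
mortality (μ = 3.71, σ = e^0.40; S(15 y) ≈ 0.75, consistent with 15-year
ER-positive outcomes under tamoxifen). Time is in years; the intercepts
only make sense on that scale. High-endoxifen recurrence applies the
hazard ratio on the survivor function, `S^HR` with HR = 0.74 — the
standard way of grafting a Cox-model hazard ratio onto a parametric
baseline, even though the lognormal is not itself a proportional-hazards
family.

Background mortality is an age-indexed period life table q(x); fractional
years assume a constant hazard within each year of age. The bundled table
is a **synthetic** Gompertz–Makeham stand-in (see below); a genuine
national CSV table can be dropped in.

### Why DFS is *not* multiplied by background survival

Two conventions were open: (a) deplete the disease-free state by other-cause
mortality, `DFS = S_dfs · S_bg` capped at OS, or (b) take the trial-based
disease-free curve as-is, capped at OS. The package defaults to (b):
disease-free-survival curves estimated from trial data already count deaths
as events, so multiplying by background survival a second time
double-counts mortality among the disease-free; the cap at OS depletes the
DFS tail where extrapolated recurrence-free survival would otherwise exceed
the probability of being alive. Convention (b) also reproduces the
published base case to a few percent, while (a) roughly doubles the
incremental effect; (a) remains available via the
`background_mortality_on_dfs` switch.

### Strategies

With `p_start` = 76% of patients high from the start and `p_after` = 94%
high after escalation (both tabulated as *cohort-level* fractions):

- no monitoring: {76% high-from-start, 24% low-forever}, no test costs;
- monitoring: {76% high-from-start, `p_after − p_start` = 18% switching to
  the high hazard at day 182, 6% low-forever}; everyone is tested at day
  91 and the 24% low fraction is retested at day 182.

Reading the 94% as a cohort-level fraction (rather than as a conditional
probability among escalated patients) matches the reported conditional
literature value (75% of escalated patients converting: 0.76 + 0.24·0.75 =
0.94) and makes exactly five one-way scenarios eliminate the QALY benefit:
equal utilities (two ways), HR = 1.00, `p_start` raised to 0.94, and
`p_after` lowered to 0.76. The converted mass is floored at zero because a
dose increase is modelled as never lowering a patient's concentration.
Escalated patients adopt the lower hazard only once adequacy is confirmed
at the second test (day 182); `benefit_from_first_test = True` moves that
to day 91. Subcohort membership is fixed after day 182.

### Accounting conventions

- Half-cycle correction: state occupancy enters cost/QALY accrual as the
  trapezoidal mean of the two cycle boundaries.
- Annual state costs and utilities are prorated per cycle
  (annual × 28/365.25).
- The one-off death cost applies to the deaths of each cycle; tests are
  charged in the cycle whose start boundary is nearest the scheduled day
  (day 91 → cycle 3, day 182 → cycle 7), only for patients alive then.
- Discounting at the cycle midpoint: 4.0%/year for costs, 1.5%/year for
  effects (Dutch guidance; the input table also circulates with 4.5% —
  `discount_rate_costs` is configurable).
- No terminal bonus for the mass still alive at age 100.
- A QALY difference below 1e-10 is treated as structurally zero (sums of
  ~600 cycle accruals carry ~1e-13 of floating-point noise).

## Sensitivity analysis

**One-way (tornado):** each of the 13 scalar inputs (the two survival
pairs flattened) is set to its low and high endpoint with all else at base;
entries are sorted by the swing in incremental cost. Scenarios with zero
QALY benefit leave the ICER undefined.

**Probabilistic (PSA):** all inputs are drawn jointly per trial.

- Survival (intercept, log-scale) pairs: bivariate normal via the Cholesky
  factor of their covariance. The original covariance is unpublished, so
  standard errors are backed out of the deterministic ranges
  ((high − low)/3.92) and the correlation defaults to 0, configurable
  through `survival_correlation` (e.g. from a `fit_parametric` covariance).
- Hazard ratio: exp(Normal(−0.301, 0.153)), truncated at 1.00 by
  *clipping*. Clipping (not rejection) creates a ~2.5% point mass of
  no-effect trials — P(Z > 0.301/0.153) — which is what keeps the
  acceptability curve from reaching 100%.
- Proportions: Beta(14.8, 4.7) and Beta(13.2, 0.8), drawn **comonotonically**
  (one shared uniform through both inverse CDFs). Independent draws would
  give ~5–7% of trials in which escalation *lowers* the fraction on target —
  structurally impossible here — and would depress the CEAC plateau well
  below its reported level; the coupling preserves both marginals while
  keeping the converted mass positive.
- Costs: gamma with the tabulated shape/scale. Utilities: beta, with the
  RD draw clipped to its paired DFS draw.

CEAC(λ) is the fraction of trials in which monitoring shows a QALY benefit
*and* positive net monetary benefit at willingness-to-pay λ. The benefit
requirement matters: trials whose benefit is truncated away (HR at 1.00 or
equal utilities) usually still save costs, so a pure NMB > 0 definition
would count them and push the curve to ~97%; requiring a benefit reproduces
the reported ~90% plateau, whose deficit then equals the clipping mass
exactly (`require_benefit=False` restores the literal definition). NMB
summaries report the mean and percentile 2.5/97.5 interval per λ.

## Synthetic data

**Life table.** Gompertz–Makeham hazard μ(x) = A + B·exp(s·(x − 53)) with
A = 2·10⁻⁴, B = 1.8375·10⁻³, s = 0.11, tabulated as q(x) = 1 − e^(−μ(x))
for ages 0–105. B was calibrated once so that remaining life expectancy at
age 53 is 33.0 years, matching a recent Dutch female period table; q(53) ≈
0.0020 and q(80) ≈ 0.035 are Dutch-like. It is a smooth two-parameter
stand-in: it does not reproduce infant/accident-hump mortality (irrelevant
from age 53) or year-to-year irregularities of a real table, so base-case
totals computed with it sit a few percent away from values computed with
the genuine table.

**Serum cohort.** Steady-state occasion-1 concentrations at 20 mg/day are
lognormal (median 7.33 ng/mL, log-SD 0.5 — a coefficient of variation
near 55%, typical of endoxifen exposure). Patients below 5.97 ng/mL are
escalated (23/113 to 30 mg, the rest to 40 mg); the occasion-2
concentration scales as (dose/20)^0.733 with lognormal inter-occasion noise
(SD 0.25). The median is calibrated so 34% of patients fall below the
threshold and the dose exponent so ~66% of escalated patients reach it —
the margins of the observed clinic cohort. Only these threshold margins are
calibrated; the full concentration distribution, dose-decision behaviour
and loss to follow-up of a real clinic are not emulated, so passing tests
validate the threshold bookkeeping, not endoxifen pharmacokinetics.

**Microsimulation oracle.** Each simulated patient draws a subcohort by
weight and a single uniform rank U; time to recurrence and time to death
are both obtained by inverting the subcohort's DFS occupancy curve and the
OS curve at U (comonotone coupling). This realises the partitioned
occupancy min(S_dfs, OS) exactly in expectation — independent event times
would give S_dfs·S_bc·S_bg instead, which is *not* the cohort model — and
the cause of death never needs to be resolved because the death cost is
cause-independent. Patients accrue the identical half-cycle, midpoint-
discounted amounts as the trace, so sample means are unbiased for the trace
totals and the 100,000-patient agreement test has exact 3-standard-error
coverage.

## Survival fitting

`reconstruct_event_counts` recovers integer events/censorings per interval
from a published curve and its at-risk table (events = n·(1 − S_next/S),
deterministic largest-remainder rounding; censorings absorb the remaining
at-risk decline), after which `fit_parametric` maximises the likelihood of
any of four families — exponential, Weibull, lognormal, log-logistic —
on exact times or interval-censored counts (fitting is delegated to
`lifelines`; interval data right-censor drop-outs at the interval start).
`select_best` minimises AIC with BIC and parameter count as tie-breakers.
The covariance of the fitted (intercept, log-scale) can be fed back into
the PSA through `survival_correlation`.

## Problem sizes used in tests

The shipped test-suite and acceptance runs use a 10,000-trial PSA, a
100,000-patient microsimulation, 5,000-event fitting samples and 20
replicates for Wald coverage — sizes at which Monte-Carlo error is well
below the decision-relevant differences while a full run stays in the
tens of seconds.

## Known limitations

- The bundled life table is synthetic (see above); exact replication of
  published totals needs the genuine national table.
- Locoregional recurrences stay in RD (no re-treatment pathway); no
  aromatase-inhibitor sequencing; dose escalation is assumed to leave
  quality of life unchanged.
- The 5.97 ng/mL threshold and HR 0.74 derive from a single retrospective
  source; the model propagates their uncertainty but cannot repair it.
- The published test-cost gamma row (shape 61.5, scale 1.8) implies a mean
  of 110.7 against a printed base of 113 — a 2% inconsistency in the
  source table itself, visible in one internal-consistency test.
- Cost inputs are used as printed (2017 euros); no re-inflation or currency
  conversion is provided.
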