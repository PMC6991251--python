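# Methods

This note records the statistical model the package implements, the
conventions and numerical choices behind it, what the synthetic-data
generator does and does not emulate, and the simulation sizes used by
the test suite.

## Estimand and identification

The target quantity is the counterfactual cumulative risk of a
time-to-event outcome under sustained use of each insulin regimen (HI:
human only; AI: analogue with or without human), in a new-user cohort
followed from the index dispensing. Follow-up is discretised into
90-day quarters; the per-protocol analysis right-censors at the first
protocol deviation, and inverse-probability weights re-create the
pseudo-population in which treatment assignment and censoring are
independent of the measured covariates.

Identification rests on the sequential randomization assumption: no
unmeasured confounding of the index treatment choice given baseline
covariates *V*, and no unmeasured common causes of censoring and
outcome given (*V*, *L(t)*), the time-varying covariate history. The
synthetic scenarios satisfy these assumptions by construction; on real
data they are untestable.

## Cohort construction conventions

* **Quarters** are 0-based half-open 90-day windows from day 0; "1 year"
  is the end of quarter 4, "2 years" the end of quarter 8, and hazards
  are evaluated over the first 10 quarters.
* **Arm assignment**: AI if any day-0 fill is analogue (concomitant
  human insulin is allowed), HI if all day-0 fills are human. A missing
  day-0 fill violates the new-user design and is an error.
* **Exposure**: each fill covers `supply_days` (180 default, 365
  sensitivity) or until the next fill *of the same class* — stockpiling
  is null within class, and chaining within class means concomitant
  fills of the other class neither sustain nor curtail a regimen. AI
  continuity is anchored to analogue fills; HI is violated by any
  analogue fill; inhaled/animal ("other") fills interrupt either
  regimen.
* **Censoring causes** and dating: supply lapse of the defining class
  (cause `gap` when a later fill of that class exists, `no_fill`
  otherwise; `switch` for an AI participant whose analogue supply
  lapses while human fills continue), violating fills (`switch`),
  enrollment coverage gap > 90 days (dated at the last covered day),
  pregnancy, death (for nonfatal outcomes), administrative end.
  Same-day ties break as event > death > disenrollment > switch >
  gap/no fill > pregnancy > administrative end.
* **Risk sets.** A terminal row is flagged `at_risk` when the censoring
  takes effect at or beyond its quarter's end, so the quarter was fully
  at risk. Hazard models (the MSMs) use exactly the `at_risk` rows:
  a supply lapse landing on a quarter boundary keeps every completed
  quarter in the risk set, while a mid-quarter censoring contributes no
  hazard information. Censoring rows do enter the censoring-mechanism
  models — the row where a censoring takes effect carries that
  quarter's covariates. Without this convention the life-table hazard
  is systematically inflated (events before the censoring date are
  kept while the matching person-time is dropped); the distinction is
  worth roughly a percentage point of cumulative risk at ten quarters
  in our scenarios.
* An event in the same quarter as a censoring date counts as an event
  when its day is no later than the censoring day.

## Weighting

Stabilised weights multiply a treatment factor (marginal over
covariate-conditional probability of the observed arm, evaluated at
quarter 0) by per-quarter factors for each active censoring mechanism,
factorised sequentially (regimen interruption, then disenrollment, then
death, each conditional on surviving the earlier causes within the
quarter). Numerator models condition on arm and quarter only — the
conventional stabilisation choice; baseline covariates may be added via
configuration. Denominators add baseline and time-varying covariates.
Death-censoring weights are on by default for nonfatal outcomes
(`death_ipcw`); pregnancy censoring is treated as noninformative (it is
rare and not behaviourally driven in the scenarios). Weights are
truncated from above at 20 (no lower bound); predicted probabilities
are clipped to [1e−6, 1 − 1e−6] and denominator clip-floor hits are
counted as positivity diagnostics.

## Models and inference

* Censoring mechanisms are pooled logistic fits with one indicator per
  quarter (no global intercept — the same model space as intercept plus
  reference-coded indicators, but quasi-separation in a quarter with no
  censoring events stays confined to that quarter's coefficient).
  Quarters with no censoring events contribute a factor of exactly one.
* The saturated MSM hazard is the closed-form weighted MLE
  Σw·Y / Σw per (quarter, regimen) cell; the proportional MSM adds a
  single regimen term to the quarter indicators, and exp(β) is reported
  as the hazard ratio — a discrete-time odds ratio that approximates
  the hazard ratio while quarterly hazards are small (≤ a few percent
  here). Empty cells are warnings at fit time and errors when risks are
  requested; sparse data should use the proportional model.
* All CIs are percentile intervals from a participant-level
  nonparametric bootstrap (default 500 replicates, minimum 100) that
  refits propensities, weights and MSMs on every resample. The
  area-between-curves statistic T = Σ_t RD(t) gets a two-tailed p-value
  from the normal approximation 2·Φ(−|T|/SE_boot). Replicates with an
  empty stratum are dropped and counted; more than 20% dropped is an
  error.
* The discrete Super Learner selects among candidate adjustment sets by
  V-fold cross-validated negative Bernoulli log-likelihood, folds
  partitioning participants, ties broken by candidate order, winner
  refit on all data. Selection runs once on the original data; bootstrap
  replicates refit the selected specification (re-running selection
  inside the bootstrap would multiply cost without changing the
  selected set in any scenario we examined). A convex-combination
  learner is out of scope.

## Numerical implementation

All logistic fits share one Newton–Raphson (IRLS) solver: linear
predictors clipped at ±30, coefficients projected into the same box
(quasi-separated cells saturate harmlessly), ridge 1e−10 on the
Hessian, step-halving on likelihood decrease, convergence at a relative
step below 1e−9. The bootstrap path warm-starts every refit from the
full-data coefficients and uses plain Newton steps at tolerance 1e−6.
Numerator models whose covariates are constant within (quarter × arm)
cells are fit on weighted cell aggregates — the identical MLE at a cost
independent of n. The solver is cross-checked against statsmodels GLM,
and the unit-weight survival curves against a brute-force life table
and the Kaplan–Meier estimator, in the test suite.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not the surface realism of claims data. Per participant: baseline
covariates (standardised age; a cardiovascular-history indicator,
p = 0.25); a logistic index-treatment draw; an AR(1) "severity" process
(ρ = 0.7, innovation sd 0.5, optionally arm-dependent) updated
quarterly; quarterly logistic draws for on-time refill, class switch,
disenrollment, death and the outcome. Refills land on quarter
boundaries; a missed refill either ends dispensing (`no_fill`) or is
followed by one late fill 270 days after the last (a dateable >180-day
`gap`), with probability 0.5 each. Within a quarter the order is death
(day +10), disenrollment (day +30), pregnancy (day +40), outcome
(day +45): a process striking earlier removes the participant from the
later draws, which keeps the observational ground truth consistent with
the Monte-Carlo oracle (which forces the regimen and disables
adherence/disenrollment processes).

Preset scenarios: `null_confounding` (everything independent, quarterly
event hazard 2%), `confounded` (cardiovascular history and age raise
both analogue initiation and the event hazard; severity drives refill
failure and disenrollment as well as the hazard; null regimen effect),
`informative_censoring` (unconfounded treatment, shared severity
process), `proportional_effect` (as `confounded`, lighter, plus a
constant regimen odds effect of 1.5). Event and censoring rates are
set an order of magnitude above the motivating study's (~2–2.5%
quarterly event hazard versus ~0.4%) so that estimator bias on the
order of 0.01 cumulative risk is resolvable at n = 20 000; the
censoring processes load mainly on baseline covariates and the current
severity value so the pooled-logistic weight models are (near-)
correctly specified — consistency of IPW requires that, and the
generator is designed to satisfy the method's assumptions, not to
defeat them. What passing tests therefore show is that the pipeline is
a correct implementation of IPW estimation under its stated
assumptions; they say nothing about unmeasured confounding, coding
artefacts, or covariate distributions in real claims data.

## Simulation sizes in the test suite

Property and recovery tests use n = 20 000 cohorts (oracle: 50 000
Monte-Carlo replicates; bias criteria averaged over 10 seeds, so the
Monte-Carlo error of the bias estimate is ~0.003). Effect-recovery
coverage uses 20 seeded runs with 100 bootstrap replicates each. The
type-I-error study of the area test uses 200 null cohorts of n = 3000
with 100 bootstrap replicates per test — sizes chosen to keep the full
suite around twenty minutes on one CPU while leaving the acceptance
bands meaningful (binomial SE of a 5% rejection rate over 200 runs is
1.5 percentage points).

## Known limitations

* The hazard ratio is a discrete-time odds ratio; with large quarterly
  hazards it drifts from the true hazard ratio, and marginal odds
  ratios are non-collapsible — the proportional-effect recovery checks
  hold because quarterly hazards are small.
* For nonfatal outcomes with death present, death-IPCW targets the
  risk that would be observed if death were (conditionally) independent
  censoring; the oracle treats death as a competing event. The preset
  scenarios keep death hazards at zero except where death handling is
  itself under test.
* Variance is bootstrap-only; no sandwich/influence-function option.
* The regimen-interruption mechanism pools gap, switch and no-fill into
  one model; their behavioural decisions precede the censoring date by
  up to two quarters, so the pooled model conditioning on current
  covariates is an approximation (empirically negligible here; lagged
  covariates can be added through the configuration if needed).
* Multiple enrollment spans, mixed-class index fills and `other`-class
  interruptions are supported in the builder but arise in the generator
  only through configuration, not by default.
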