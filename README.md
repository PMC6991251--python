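# pptrial

Per-protocol target-trial emulation from dispensing records, with
stabilised inverse-probability weighting and logistic marginal structural
models.

## The problem

Observational comparisons of two drug regimens — here the motivating case
of *human insulin only* (HI) versus *analogue insulin with or without
human insulin* (AI) in insulin-naive adults — face two biases that a
randomized trial would not: the regimen chosen at the first fill depends
on baseline prognosis, and staying on the regimen (refilling on time, not
switching, staying enrolled, staying alive) depends on evolving health.
`pptrial` implements the standard epidemiological answer: emulate the
trial's protocol. Everyone enters at their first dispensing (day 0),
is assigned the arm defined by the index fill, and is right-censored at
the first protocol deviation — a supply gap of more than the assumed
days of supply (180 days; 365 in sensitivity analyses), a class switch,
no further fill, a health-plan coverage gap of more than 90 days,
pregnancy, death, or the administrative end of follow-up. Confounding
and informative censoring are then removed by weighting.

The package is for biostatisticians and pharmacoepidemiologists who want
a tested, seedable implementation of this pipeline — including a
synthetic-cohort generator with known counterfactual ground truth, so
every estimator can be validated against a Monte-Carlo oracle.

## The model

Follow-up is discretised into 90-day quarters *t* = 0, 1, …, 9. For each
quarter and regimen *a*, the discrete-time counterfactual hazard is
*h(t, a)* and the survival and cumulative risk are

    S_a(t) = prod_{k < t} (1 − h(k, a)),     Risk_a(t) = 1 − S_a(t).

Each person-quarter receives a stabilised inverse-probability weight

    sw(t) = P_num(A=a) / P_den(A=a | V) ×
            prod_{k ≤ t} prod_m P_num(uncensored_m at k) / P_den(uncensored_m at k | V, L(k))

with one factor per censoring mechanism *m* (regimen interruption,
disenrollment, and — for nonfatal outcomes — death), baseline covariates
*V* and time-varying covariates *L(k)*. Weights are truncated at 20.
Propensity models are pooled logistic fits; the adjustment set can be
fixed or chosen by a discrete Super Learner (V-fold cross-validated
Bernoulli log-likelihood over candidate sets, folds partitioning
participants).

Two weighted MSMs are fit: a *saturated* model (one hazard per quarter ×
regimen cell, closed-form weighted MLE) giving the survival curves and
risk differences at 1 year (quarter 4) and 2 years (quarter 8), and a
*proportional* model (quarter indicators plus one regimen term) whose
exp(β) is reported as the hazard ratio. The area-between-curves statistic
T = Σ_t [Risk_AI(t) − Risk_HI(t)] is tested against zero, and all
confidence intervals come from a participant-level nonparametric
bootstrap that re-runs the entire pipeline per replicate.

## Worked example

```python
import pptrial as pt

config = pt.preset_scenario("confounded", n_participants=10_000, seed=1)
raw = pt.generate_cohort(config)                     # six raw study tables
table = pt.build_person_quarters(raw, pt.BuildConfig(supply_days=180))

print(pt.summarize_follow_up(table).as_frame())

analysis = pt.PerProtocolAnalysis(table, pt.AnalysisConfig(
    baseline_covariates=("age_std", "cvd_history"),
    time_varying_covariates=("severity",)))
result = analysis.run(bootstrap_reps=200, seed=2)
```

This prints the follow-up accounting (10 000 participants: 17.6% reach
the outcome, 58.8% are censored for interruption of the initial regimen
— 22.7% gap, 26.0% no further fill, 10.1% switch — 11.0% disenroll,
12.5% reach the administrative end) and the fitted `result` holds

```text
HR  1.067 (95% CI 0.968-1.186)
RD 1y +0.0149 (95% CI -0.0004 to +0.0292)
RD 2y +0.0122 (95% CI -0.0104 to +0.0388)
area T +0.0941, p = 0.247
```

i.e. after weighting, the confounded scenario (whose true regimen effect
is null) shows no significant difference between the regimens — while
the crude analysis (`AnalysisConfig(unadjusted=True)`) is visibly
biased. `result.risks` holds the counterfactual risk curves for
plotting.

The same pipeline is available from the shell:

```bash
pptrial simulate --scenario confounded --n 10000 --seed 1 --out-dir raw/
pptrial build-cohort --in-dir raw/ --supply-days 180 --out cohort.csv \
    --summary-out summary.json
pptrial fit --cohort cohort.csv --baseline-covariates age_std,cvd_history \
    --time-varying-covariates severity --bootstrap 200 --seed 2 --out report.json
```

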