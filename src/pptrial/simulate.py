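"""Synthetic longitudinal cohort generator with a Monte-Carlo oracle.

The generator emulates the data sources of a new-user, active-comparator
pharmacoepidemiology study of two insulin regimens: at an index date
(day 0) every participant fills a first insulin prescription whose class
(human vs analogue) is confounded by baseline covariates; afterwards the
participant refills quarterly, may leave a refill gap, switch insulin
class, disenroll from the health plan, die, or experience the study
outcome.  Time-varying covariates follow an autoregressive process and
may drive adherence, disenrollment and the outcome hazard at once, which
is exactly the informative-censoring structure inverse-probability
weighting is meant to remove.

``true_counterfactual_risks`` is the ground-truth oracle: it forces the
regimen, disables refill gaps/switches and disenrollment, and reports
Monte-Carlo cumulative incidence under each regimen.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigError

__all__ = [
    "CovariateSpec",
    "ArUpdate",
    "RefillModel",
    "SimConfig",
    "RawStudyData",
    "SimTruth",
    "generate_cohort",
    "true_counterfactual_risks",
    "preset_scenario",
    "SCENARIOS",
]

QUARTER_DAYS = 90
#: within-quarter day offsets; the ordering (death, then disenrollment and
#: pregnancy, then the outcome) is the simulated ground truth — a process
#: striking earlier in the quarter removes the participant from the later
#: draws of that quarter
DEATH_OFFSET = 10
DISENROLL_OFFSET = 30
PREGNANCY_OFFSET = 40
EVENT_OFFSET = 45


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate: name + distribution family + parameters.

    Supported families: ``normal`` (mean, sd), ``bernoulli`` (p),
    ``uniform`` (low, high).
    """

    name: str
    family: str
    params: Mapping[str, float]


@dataclass(frozen=True)
class ArUpdate:
    """AR(1) update of a time-varying covariate.

    L(0) = init_intercept + sum(init_coefs * V) + init_sd * eps
    L(t) = drift + rho * L(t-1) + arm_ai * A + noise_sd * eps
    """

    init_intercept: float = 0.0
    init_coefs: Mapping[str, float] = field(default_factory=dict)
    init_sd: float = 1.0
    rho: float = 0.7
    drift: float = 0.0
    arm_ai: float = 0.0
    noise_sd: float = 0.5


@dataclass(frozen=True)
class RefillModel:
    """Quarterly refill behaviour as two logistic draws.

    ``refill`` gives the log-odds of refilling on time at the next quarter
    boundary (otherwise a supply gap starts); among on-time refills,
    ``switch`` gives the log-odds that the fill is of the other insulin
    class.  Coefficient maps use ``intercept``, baseline and time-varying
    covariate names, and ``arm_ai``.
    """

    refill: Mapping[str, float]
    switch: Mapping[str, float]


@dataclass(frozen=True)
class SimConfig:
    n_participants: int
    seed: int
    baseline_covariates: Sequence[CovariateSpec]
    treatment_model: Mapping[str, float]
    refill_model: RefillModel
    disenrollment_model: Mapping[str, float]
    outcome_model: Mapping[str, float]
    covariate_update: Mapping[str, ArUpdate]
    death_model: Mapping[str, float] | None = None
    pregnancy_model: Mapping[str, float] | None = None
    horizon_quarters: int = 10
    outcome_name: str = "event"
    #: probability that a gap in refills is followed by one late fill
    #: (270 days after the last fill), yielding a dateable >180-day gap
    #: rather than outright discontinuation
    gap_resume_prob: float = 0.5
    #: probability that an analogue initiator also fills human insulin on
    #: day 0 (the AI regimen allows concomitant human insulin)
    ai_day0_human_prob: float = 0.3

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.horizon_quarters < 1:
            raise ConfigError("horizon_quarters must be >= 1")
        if not 0.0 <= self.gap_resume_prob <= 1.0:
            raise ConfigError("gap_resume_prob must lie in [0, 1]")
        if not 0.0 <= self.ai_day0_human_prob <= 1.0:
            raise ConfigError("ai_day0_human_prob must lie in [0, 1]")
        names = set()
        for spec in self.baseline_covariates:
            if spec.name in names:
                raise ConfigError(f"duplicate baseline covariate {spec.name!r}")
            names.add(spec.name)
            p = dict(spec.params)
            if spec.family == "normal":
                if p.get("sd", 1.0) < 0:
                    raise ConfigError(f"baseline_covariates[{spec.name}]: sd must be >= 0")
            elif spec.family == "bernoulli":
                if not 0.0 <= p.get("p", 0.5) <= 1.0:
                    raise ConfigError(f"baseline_covariates[{spec.name}]: p must lie in [0, 1]")
            elif spec.family == "uniform":
                if p.get("low", 0.0) > p.get("high", 1.0):
                    raise ConfigError(f"baseline_covariates[{spec.name}]: low > high")
            else:
                raise ConfigError(
                    f"baseline_covariates[{spec.name}]: unknown family {spec.family!r}"
                )
        for name, ar in self.covariate_update.items():
            if ar.init_sd < 0 or ar.noise_sd < 0:
                raise ConfigError(f"covariate_update[{name}]: sd must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


# ---------------------------------------------------------------------------
# containers


@dataclass
class RawStudyData:
    """The six raw study tables keyed by participant id (days from index)."""

    dispensings: pd.DataFrame   # participant, day, insulin_class
    enrollment: pd.DataFrame    # participant, start_day, end_day
    events: pd.DataFrame        # participant, outcome, day
    deaths: pd.DataFrame        # participant, day
    baseline_covariates: pd.DataFrame   # participant + covariate columns
    quarterly_covariates: pd.DataFrame  # participant, quarter + columns

    _TABLES = ("dispensings", "enrollment", "events", "deaths",
               "baseline_covariates", "quarterly_covariates")

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(path / f"{name}.csv", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "RawStudyData":
        path = Path(path)
        return cls(**{name: pd.read_csv(path / f"{name}.csv") for name in cls._TABLES})


@dataclass
class SimTruth:
    """Monte-Carlo counterfactual cumulative risks under one forced regimen.

    ``risk[k]`` is the cumulative incidence by the end of quarter ``k``
    (1-based; ``risk[0] == 0``), with binomial Monte-Carlo standard errors.
    """

    config: SimConfig
    regimen: str
    mc_reps: int
    risk: np.ndarray
    mc_se: np.ndarray


# ---------------------------------------------------------------------------
# linear predictors


def _linear_predictor(coefs: Mapping[str, float], frame: Mapping[str, np.ndarray],
                      n: int, *, model_name: str) -> np.ndarray:
    eta = np.full(n, float(coefs.get("intercept", 0.0)))
    for name, c in coefs.items():
        if name == "intercept":
            continue
        if name not in frame:
            raise ConfigError(f"{model_name}: unknown covariate {name!r}")
        eta = eta + float(c) * frame[name]
    return eta


def _hazard(coefs: Mapping[str, float] | None, frame, n, *, model_name) -> np.ndarray:
    if coefs is None:
        return np.zeros(n)
    return expit(_linear_predictor(coefs, frame, n, model_name=model_name))


def _draw_baseline(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = config.n_participants
    out: dict[str, np.ndarray] = {}
    for spec in config.baseline_covariates:
        p = dict(spec.params)
        if spec.family == "normal":
            out[spec.name] = rng.normal(p.get("mean", 0.0), p.get("sd", 1.0), n)
        elif spec.family == "bernoulli":
            out[spec.name] = rng.binomial(1, p.get("p", 0.5), n).astype(float)
        elif spec.family == "uniform":
            out[spec.name] = rng.uniform(p.get("low", 0.0), p.get("high", 1.0), n)
    return out


def _update_tv(config: SimConfig, rng, V, arm_ai, t, prev):
    """One step of the AR(1) time-varying covariate processes."""
    n = len(arm_ai)
    cur: dict[str, np.ndarray] = {}
    for name, ar in config.covariate_update.items():
        if t == 0:
            val = np.full(n, ar.init_intercept)
            for vname, c in ar.init_coefs.items():
                if vname not in V:
                    raise ConfigError(f"covariate_update[{name}]: unknown covariate {vname!r}")
                val = val + c * V[vname]
            val = val + ar.init_sd * rng.standard_normal(n)
        else:
            val = (ar.drift + ar.rho * prev[name] + ar.arm_ai * arm_ai
                   + ar.noise_sd * rng.standard_normal(n))
        cur[name] = val
    return cur


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: SimConfig) -> RawStudyData:
    """Simulate the six raw study tables under the configured mechanism.

    Treatment is drawn once at the index date from the baseline-covariate
    logistic model; refill gaps/switches, disenrollment, death and the
    outcome are drawn quarter by quarter.  Identical configs (including
    the seed) produce identical tables.
    """
    config.validate()
    n = config.n_participants
    H = config.horizon_quarters
    rng = np.random.default_rng(config.seed)

    V = _draw_baseline(config, rng)
    eta_a = _linear_predictor(config.treatment_model, V, n, model_name="treatment_model")
    arm_ai = (rng.random(n) < expit(eta_a)).astype(float)

    death_q = np.full(n, -1, dtype=np.int64)
    event_q = np.full(n, -1, dtype=np.int64)
    disen_q = np.full(n, -1, dtype=np.int64)
    preg_q = np.full(n, -1, dtype=np.int64)
    fail_q = np.full(n, -1, dtype=np.int64)    # quarter whose end-of-quarter refill was missed
    switch_q = np.full(n, -1, dtype=np.int64)  # quarter whose end-of-quarter refill switched class

    tv_hist: dict[str, np.ndarray] = {name: np.empty((n, H)) for name in config.covariate_update}
    tv = None
    for t in range(H):
        tv = _update_tv(config, rng, V, arm_ai, t, tv)
        for name, val in tv.items():
            tv_hist[name][:, t] = val
        frame = {**V, **tv, "arm_ai": arm_ai}

        active = (death_q < 0) & (event_q < 0)

        # death first within a quarter: a participant cannot have both
        if config.death_model is not None:
            p_death = _hazard(config.death_model, frame, n, model_name="death_model")
            died = active & (rng.random(n) < p_death)
            death_q[died] = t
            active = active & ~died

        alive = death_q < 0
        p_dis = _hazard(config.disenrollment_model, frame, n, model_name="disenrollment_model")
        dis = alive & (event_q < 0) & (disen_q < 0) & (rng.random(n) < p_dis)
        disen_q[dis] = t

        if config.pregnancy_model is not None:
            p_preg = _hazard(config.pregnancy_model, frame, n, model_name="pregnancy_model")
            preg = alive & (event_q < 0) & (preg_q < 0) & (rng.random(n) < p_preg)
            preg_q[preg] = t

        # the outcome strikes last in the quarter: participants removed by
        # death, disenrollment or pregnancy earlier in the quarter are not
        # at risk of the event in that quarter
        p_event = _hazard(config.outcome_model, frame, n, model_name="outcome_model")
        got_event = (active & ~(disen_q == t) & ~(preg_q == t)
                     & (rng.random(n) < p_event))
        event_q[got_event] = t

        # refill behaviour for the fill due at day 90*(t+1)
        filling = alive & (fail_q < 0) & (switch_q < 0)
        p_refill = _hazard(config.refill_model.refill, frame, n, model_name="refill_model.refill")
        on_time = rng.random(n) < p_refill
        p_switch = _hazard(config.refill_model.switch, frame, n, model_name="refill_model.switch")
        switched = rng.random(n) < p_switch
        fail_q[filling & ~on_time] = t
        switch_q[filling & on_time & switched] = t

    resume = rng.random(n) < config.gap_resume_prob

    # --- dispensing records -------------------------------------------------
    horizon_day = H * QUARTER_DAYS
    big = np.int64(1 << 40)
    stop = np.minimum.reduce([
        np.where(fail_q >= 0, fail_q, big),
        np.where(switch_q >= 0, switch_q, big),
        np.where(death_q >= 0, death_q, big),
        np.full(n, H - 1, dtype=np.int64),
    ])
    init_count = stop + 1
    pid = np.arange(n, dtype=np.int64)
    fill_pid = np.repeat(pid, init_count)
    ends = np.cumsum(init_count)
    fill_q = np.arange(ends[-1]) - np.repeat(ends - init_count, init_count)
    init_class = np.where(arm_ai > 0, "analogue", "human")
    records = [pd.DataFrame({
        "participant": fill_pid,
        "day": fill_q * QUARTER_DAYS,
        "insulin_class": np.repeat(init_class, init_count),
    })]

    # concomitant human fill on day 0 for some analogue initiators
    conc = (arm_ai > 0) & (rng.random(n) < config.ai_day0_human_prob)
    if conc.any():
        records.append(pd.DataFrame({
            "participant": pid[conc],
            "day": 0,
            "insulin_class": "human",
        }))

    # class switch: quarterly fills of the other class from the next boundary on
    sw = switch_q >= 0
    if sw.any():
        sw_pid = pid[sw]
        first = switch_q[sw] + 1
        last = np.where(death_q[sw] >= 0, np.minimum(death_q[sw], H - 1), H - 1)
        cnt = np.maximum(last - first + 1, 0)
        keep = cnt > 0
        sw_pid, first, cnt = sw_pid[keep], first[keep], cnt[keep]
        e = np.cumsum(cnt)
        q = np.arange(e[-1] if len(e) else 0) - np.repeat(e - cnt, cnt) + np.repeat(first, cnt)
        other = np.where(arm_ai[sw_pid] > 0, "human", "analogue")
        records.append(pd.DataFrame({
            "participant": np.repeat(sw_pid, cnt),
            "day": q * QUARTER_DAYS,
            "insulin_class": np.repeat(other, cnt),
        }))

    # a resumed fill 270 days after the last fill documents a >180-day gap
    res = (fail_q >= 0) & resume & (death_q < 0)
    res_day = fail_q * QUARTER_DAYS + 270
    res = res & (res_day < horizon_day)
    if res.any():
        records.append(pd.DataFrame({
            "participant": pid[res],
            "day": res_day[res],
            "insulin_class": init_class[res],
        }))

    dispensings = (pd.concat(records, ignore_index=True)
                   .sort_values(["participant", "day", "insulin_class"], kind="mergesort")
                   .reset_index(drop=True))

    # --- remaining tables ---------------------------------------------------
    enroll_end = np.where(disen_q >= 0, disen_q * QUARTER_DAYS + DISENROLL_OFFSET,
                          horizon_day + 2 * QUARTER_DAYS)
    enrollment = pd.DataFrame({"participant": pid, "start_day": 0, "end_day": enroll_end})

    ev_mask = event_q >= 0
    events = pd.DataFrame({
        "participant": pid[ev_mask],
        "outcome": config.outcome_name,
        "day": event_q[ev_mask] * QUARTER_DAYS + EVENT_OFFSET,
    })
    if (preg_q >= 0).any():
        pr = preg_q >= 0
        events = pd.concat([events, pd.DataFrame({
            "participant": pid[pr],
            "outcome": "pregnancy",
            "day": preg_q[pr] * QUARTER_DAYS + PREGNANCY_OFFSET,
        })], ignore_index=True)
    events = events.sort_values(["participant", "day"], kind="mergesort").reset_index(drop=True)

    d_mask = death_q >= 0
    deaths = pd.DataFrame({
        "participant": pid[d_mask],
        "day": death_q[d_mask] * QUARTER_DAYS + DEATH_OFFSET,
    })

    baseline = pd.DataFrame({"participant": pid, **V})
    quarterly = pd.DataFrame({
        "participant": np.repeat(pid, H),
        "quarter": np.tile(np.arange(H), n),
        **{name: arr.reshape(-1) for name, arr in tv_hist.items()},
    })

    return RawStudyData(dispensings, enrollment, events, deaths, baseline, quarterly)


# ---------------------------------------------------------------------------
# oracle


def true_counterfactual_risks(config: SimConfig, regimen: str,
                              mc_reps: int = 50_000, seed: int = 0) -> SimTruth:
    """Monte-Carlo counterfactual cumulative incidence under a forced regimen.

    The regimen is assigned to everyone, refill gaps/switches and
    disenrollment are disabled, and covariates, death and the outcome
    evolve per the configured models.  With a nonzero death hazard the
    returned risks are cumulative incidence with death as a competing
    event (death is drawn first within a quarter).
    """
    if mc_reps < 1000:
        raise ConfigError("mc_reps must be >= 1000")
    if regimen not in ("HI", "AI"):
        raise ConfigError(f"regimen must be 'HI' or 'AI', got {regimen!r}")
    config.validate()
    cfg = replace(config, n_participants=mc_reps)
    n = mc_reps
    H = cfg.horizon_quarters
    rng = np.random.default_rng(seed)

    V = _draw_baseline(cfg, rng)
    arm_ai = np.full(n, 1.0 if regimen == "AI" else 0.0)
    event_q = np.full(n, -1, dtype=np.int64)
    death_q = np.full(n, -1, dtype=np.int64)

    tv = None
    for t in range(H):
        tv = _update_tv(cfg, rng, V, arm_ai, t, tv)
        frame = {**V, **tv, "arm_ai": arm_ai}
        active = (death_q < 0) & (event_q < 0)
        if cfg.death_model is not None:
            p_death = _hazard(cfg.death_model, frame, n, model_name="death_model")
            died = active & (rng.random(n) < p_death)
            death_q[died] = t
            active = active & ~died
        p_event = _hazard(cfg.outcome_model, frame, n, model_name="outcome_model")
        event_q[active & (rng.random(n) < p_event)] = t

    risk = np.zeros(H + 1)
    for k in range(1, H + 1):
        risk[k] = np.mean((event_q >= 0) & (event_q <= k - 1))
    se = np.sqrt(risk * (1.0 - risk) / mc_reps)
    return SimTruth(config=config, regimen=regimen, mc_reps=mc_reps, risk=risk, mc_se=se)


# ---------------------------------------------------------------------------
# preset scenarios


def _base_preset(**overrides) -> dict:
    base = dict(
        n_participants=10_000,
        seed=0,
        baseline_covariates=(
            CovariateSpec("age_std", "normal", {"mean": 0.0, "sd": 1.0}),
            CovariateSpec("cvd_history", "bernoulli", {"p": 0.25}),
        ),
        covariate_update={
            "severity": ArUpdate(init_intercept=0.0, init_coefs={"cvd_history": 0.5},
                                 init_sd=1.0, rho=0.7, noise_sd=0.5),
        },
        horizon_quarters=10,
        outcome_name="event",
        death_model=None,
        pregnancy_model=None,
    )
    base.update(overrides)
    return base


SCENARIOS = ("null_confounding", "confounded", "informative_censoring", "proportional_effect")


def preset_scenario(name: str, *, n_participants: int | None = None,
                    seed: int | None = None) -> SimConfig:
    """Return a fully specified :class:`SimConfig` for a named scenario.

    ``null_confounding``: treatment, censoring and outcome mutually
    independent (all covariate coefficients zero), null regimen effect.
    ``confounded``: baseline covariates raise both the odds of analogue
    initiation and the outcome hazard, and adherence/disenrollment depend
    on covariates (informative censoring); null regimen effect.
    ``informative_censoring``: unconfounded treatment, but censoring and
    outcome share the time-varying severity process.
    ``proportional_effect``: like ``confounded`` with a constant regimen
    log-odds effect log(1.5) on the outcome.
    """
    if name == "null_confounding":
        kw = _base_preset(
            treatment_model={"intercept": 0.0},
            refill_model=RefillModel(refill={"intercept": _logit(0.88)},
                                     switch={"intercept": _logit(0.03)}),
            disenrollment_model={"intercept": _logit(0.02)},
            outcome_model={"intercept": _logit(0.02)},
        )
    elif name == "confounded":
        kw = _base_preset(
            treatment_model={"intercept": -0.8, "cvd_history": 1.2, "age_std": 0.4},
            refill_model=RefillModel(
                refill={"intercept": _logit(0.88), "cvd_history": -0.5, "severity": -0.25},
                switch={"intercept": _logit(0.03)}),
            disenrollment_model={"intercept": _logit(0.02), "cvd_history": 0.4,
                                 "severity": 0.2},
            outcome_model={"intercept": _logit(0.025), "cvd_history": 0.9,
                           "age_std": 0.4, "severity": 0.5},
        )
    elif name == "informative_censoring":
        kw = _base_preset(
            treatment_model={"intercept": -0.5},
            refill_model=RefillModel(
                refill={"intercept": _logit(0.88), "severity": -0.7},
                switch={"intercept": _logit(0.03)}),
            disenrollment_model={"intercept": _logit(0.02), "severity": 0.5},
            outcome_model={"intercept": _logit(0.02), "severity": 0.7},
        )
    elif name == "proportional_effect":
        kw = _base_preset(
            treatment_model={"intercept": -0.6, "cvd_history": 0.8, "age_std": 0.3},
            refill_model=RefillModel(
                refill={"intercept": _logit(0.88), "cvd_history": -0.4, "severity": -0.2},
                switch={"intercept": _logit(0.03)}),
            disenrollment_model={"intercept": _logit(0.02), "cvd_history": 0.3,
                                 "severity": 0.15},
            outcome_model={"intercept": _logit(0.02), "cvd_history": 0.5,
                           "age_std": 0.25, "severity": 0.3,
                           "arm_ai": math.log(1.5)},
        )
    else:
        raise ConfigError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIOS)}")
    if n_participants is not None:
        kw["n_participants"] = n_participants
    if seed is not None:
        kw["seed"] = seed
    return SimConfig(**kw)
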