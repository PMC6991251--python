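"""Propensity-score mechanisms and discrete Super Learner selection.

Four mechanisms are modelled: the baseline treatment choice
(``treatment_at_index``) and the per-quarter probabilities of remaining
uncensored by each censoring process — regimen interruption
(gap/switch/no fill), plan disenrollment, and death.  The censoring
mechanisms are factorised sequentially: each is fit on the person-quarters
still uncensored by the earlier processes within the quarter, pooled
across quarters with quarter-indicator terms.

``super_learner_select`` implements the discrete Super Learner: V-fold
cross-validated negative Bernoulli log-likelihood over candidate logistic
covariate-adjustment sets, folds partitioning participants, winner refit
on all data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._solver import LogisticFit, fit_logistic
from .exceptions import ConvergenceError, SchemaError, SeparationError

log = logging.getLogger(__name__)

__all__ = [
    "TREATMENT", "REGIMEN", "DISENROLLMENT", "DEATH", "MECHANISMS",
    "MechanismSpec", "PropensityFit", "SuperLearnerReport",
    "fit_mechanism", "predict_probability", "predict_uncensored",
    "super_learner_select",
]

TREATMENT = "treatment_at_index"
REGIMEN = "uncensored_regimen"
DISENROLLMENT = "uncensored_disenrollment"
DEATH = "uncensored_death"
MECHANISMS = (TREATMENT, REGIMEN, DISENROLLMENT, DEATH)

#: censoring causes attributed to each mechanism, in factorisation order
MECHANISM_CAUSES = {
    REGIMEN: ("gap", "switch", "no_fill"),
    DISENROLLMENT: ("disenrollment",),
    DEATH: ("death",),
}
CENSORING_ORDER = (REGIMEN, DISENROLLMENT, DEATH)

#: predicted probabilities are clipped to this interval
CLIP = 1e-6


@dataclass(frozen=True)
class MechanismSpec:
    """What to fit: mechanism, stabilisation role, and the adjustment set.

    ``covariates`` may name baseline and time-varying columns plus the
    derived indicator ``arm_ai``; numerator sets conventionally hold only
    ``arm_ai`` (plus optional baseline covariates), while denominator sets
    add the time-varying history.
    """

    mechanism: str
    role: str = "denominator"
    covariates: tuple[str, ...] = ()
    include_site_year_interaction: bool = False

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.role not in ("numerator", "denominator"):
            raise ValueError(f"role must be numerator or denominator, got {self.role!r}")


@dataclass
class PropensityFit:
    spec: MechanismSpec
    beta: np.ndarray
    names: list[str]
    horizon: int
    interaction_levels: list | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.beta, index=self.names)


@dataclass
class SuperLearnerReport:
    mechanism: str
    candidates: list[MechanismSpec]
    losses: list[float]
    selected: MechanismSpec
    folds: int
    seed: int


# ---------------------------------------------------------------------------
# design matrices


def _column(table, name: str) -> np.ndarray:
    if name == "arm_ai":
        if "arm_ai" in table:
            return np.asarray(table["arm_ai"], dtype=np.float64)
        if "arm" in table:
            return (np.asarray(table["arm"]) == "AI").astype(np.float64)
        raise SchemaError("covariate column 'arm_ai' (or 'arm') missing from table")
    if name not in table:
        raise SchemaError(f"covariate column {name!r} missing from table")
    return np.asarray(table[name], dtype=np.float64)


def build_design(table, covariates: Sequence[str], *, quarter_dummies: bool,
                 horizon: int, site_year_levels: list | None = None,
                 include_site_year: bool = False):
    """Expand a table into (X, names, site_year_levels).

    ``site_year_levels`` (from a fit) aligns interaction dummies between
    fitting and prediction; unseen combinations map to the reference.
    """
    n = len(table) if isinstance(table, pd.DataFrame) else len(next(iter(table.values())))
    cols: list[np.ndarray] = []
    names: list[str] = []
    if quarter_dummies:
        # one indicator per quarter, no global intercept: quarters with no
        # censoring saturate their own coefficient without destabilising
        # the rest of the fit
        q = np.asarray(table["quarter"], dtype=np.int64)
        for k in range(horizon):
            cols.append((q == k).astype(np.float64))
            names.append(f"quarter_{k}")
    else:
        cols.append(np.ones(n))
        names.append("intercept")
    for c in covariates:
        cols.append(_column(table, c))
        names.append(c)
    levels = site_year_levels
    if include_site_year:
        site = np.asarray(table["site"]) if "site" in table else None
        year = np.asarray(table["year"]) if "year" in table else None
        if site is None or year is None:
            raise SchemaError("site/year interaction requested but 'site' or 'year' "
                              "column missing from table")
        combo = np.char.add(np.char.add(site.astype(str), ":"), year.astype(str))
        if levels is None:
            levels = sorted(set(combo))[1:]  # first combination is the reference
        for lv in levels:
            cols.append((combo == lv).astype(np.float64))
            names.append(f"site_year[{lv}]")
    return np.column_stack(cols), names, levels


def mechanism_response(causes: np.ndarray, mechanism: str,
                       at_risk: np.ndarray | None = None) -> np.ndarray:
    """Per-row response: 1 if the row is not censored by this mechanism.

    A terminal row that still spans a full quarter at risk (``at_risk``
    true: the censoring takes effect only at the quarter's end, e.g. at
    the horizon boundary) counts as uncensored for the quarter.
    """
    own = MECHANISM_CAUSES[mechanism]
    resp = ~np.isin(causes, own)
    if at_risk is not None:
        resp |= np.asarray(at_risk, dtype=bool)
    return resp.astype(np.float64)


def mechanism_mask(causes: np.ndarray, mechanism: str,
                   at_risk: np.ndarray | None = None) -> np.ndarray:
    """Rows in this mechanism's risk set: not censored by an earlier cause."""
    prior: list[str] = []
    for m in CENSORING_ORDER:
        if m == mechanism:
            break
        prior.extend(MECHANISM_CAUSES[m])
    mask = ~np.isin(causes, prior)
    if at_risk is not None:
        mask |= np.asarray(at_risk, dtype=bool)
    return mask


# ---------------------------------------------------------------------------
# fitting and prediction


def _prepare(table: pd.DataFrame, spec: MechanismSpec, horizon: int | None):
    causes = np.asarray(table["censor_cause"].astype(str))
    H = int(horizon if horizon is not None else np.asarray(table["quarter"]).max() + 1)
    if spec.mechanism == TREATMENT:
        sub = table[np.asarray(table["quarter"]) == 0]
        y = _column(sub, "arm_ai")
        qd = False
    else:
        at_risk = (np.asarray(table["at_risk"], dtype=bool)
                   if "at_risk" in table.columns else None)
        sub = table[mechanism_mask(causes, spec.mechanism, at_risk)]
        sub_risk = (np.asarray(sub["at_risk"], dtype=bool)
                    if at_risk is not None else None)
        y = mechanism_response(np.asarray(sub["censor_cause"].astype(str)),
                               spec.mechanism, sub_risk)
        qd = True
    X, names, levels = build_design(
        sub, spec.covariates, quarter_dummies=qd, horizon=H,
        include_site_year=spec.include_site_year_interaction)
    return sub, X, y, names, levels, H


def fit_mechanism(table: pd.DataFrame, spec: MechanismSpec,
                  horizon: int | None = None) -> PropensityFit:
    """Pooled maximum-likelihood logistic fit of one mechanism.

    The treatment mechanism is fit on the quarter-0 rows; censoring
    mechanisms are fit on all person-quarters still uncensored by earlier
    causes, with quarter-indicator terms.
    """
    sub, X, y, names, levels, H = _prepare(table, spec, horizon)
    if len(y) == 0:
        raise SeparationError(f"{spec.mechanism}: no rows to fit")
    if y.min() == y.max():
        raise SeparationError(
            f"{spec.mechanism}: response is constant ({y[0]:.0f} everywhere); "
            "the model is degenerate — reduce the covariate set or drop the mechanism")
    res = fit_logistic(X, y, compute_cov=True)
    if not res.converged:
        raise ConvergenceError(
            f"{spec.mechanism}: IRLS did not converge in {res.n_iter} iterations")
    if res.separated:
        log.warning("%s: quasi-separated fit (a coefficient hit the bound); "
                    "predicted probabilities saturate", spec.mechanism)
    return PropensityFit(
        spec=spec, beta=res.beta, names=names, horizon=H, interaction_levels=levels,
        diagnostics={"loglik": res.loglik, "n_iter": res.n_iter,
                     "converged": res.converged, "separated": res.separated,
                     "n_obs": len(y), "clip": CLIP,
                     "bse": res.bse, "z": res.beta / np.where(res.bse > 0, res.bse, np.inf)},
    )


def _predict_response_prob(fit: PropensityFit, table) -> np.ndarray:
    X, _, _ = build_design(
        table, fit.spec.covariates, quarter_dummies=fit.spec.mechanism != TREATMENT,
        horizon=fit.horizon, site_year_levels=fit.interaction_levels,
        include_site_year=fit.spec.include_site_year_interaction)
    return np.clip(expit(X @ fit.beta), CLIP, 1.0 - CLIP)


def predict_uncensored(fit: PropensityFit, table) -> np.ndarray:
    """P(remained uncensored by this mechanism) per row (censoring fits)."""
    return _predict_response_prob(fit, table)


def predict_probability(fit: PropensityFit, table) -> np.ndarray:
    """Probability of each row's observed status under the fit.

    For the treatment mechanism this is P(A = observed arm); for censoring
    mechanisms it is P(uncensored) on uncensored rows and P(censored) on
    rows ending in that mechanism's cause.  Probabilities are clipped to
    [1e-6, 1 - 1e-6].
    """
    p1 = _predict_response_prob(fit, table)
    if fit.spec.mechanism == TREATMENT:
        a = _column(table, "arm_ai")
        return np.where(a > 0, p1, 1.0 - p1)
    causes = np.asarray(table["censor_cause"].astype(str))
    at_risk = (np.asarray(table["at_risk"], dtype=bool)
               if "at_risk" in table.columns else None)
    y = mechanism_response(causes, fit.spec.mechanism, at_risk)
    return np.where(y > 0, p1, 1.0 - p1)


# ---------------------------------------------------------------------------
# discrete Super Learner


def super_learner_select(table: pd.DataFrame, mechanism: str,
                         candidate_sets: Sequence[MechanismSpec], folds: int = 10,
                         seed: int = 0, horizon: int | None = None
                         ) -> tuple[PropensityFit, SuperLearnerReport]:
    """Pick the candidate adjustment set with minimal cross-validated loss.

    Loss is the mean negative Bernoulli log-likelihood over held-out rows,
    with folds partitioning participants (not rows).  Ties break in
    candidate order; candidates failing on any fold are dropped with a
    warning.  The winner is refit on the full data.
    """
    if len(candidate_sets) == 0:
        raise ValueError("at least one candidate is required")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    for spec in candidate_sets:
        if spec.mechanism != mechanism:
            raise ValueError("all candidates must target the same mechanism")

    # risk set and response are shared by all candidates
    probe = _prepare(table, candidate_sets[0], horizon)
    sub, y, H = probe[0], probe[2], probe[5]
    pids = np.asarray(sub["participant"])
    unique_pids = np.unique(pids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique_pids))
    fold_of_pid = dict(zip(unique_pids[perm], np.arange(len(unique_pids)) % folds))
    fold = np.array([fold_of_pid[p] for p in pids])

    losses: list[float] = []
    kept: list[MechanismSpec] = []
    for spec in candidate_sets:
        X, _, _ = build_design(
            sub, spec.covariates, quarter_dummies=spec.mechanism != TREATMENT,
            horizon=H, include_site_year=spec.include_site_year_interaction)
        total = 0.0
        ok = True
        for v in range(folds):
            tr = fold != v
            te = ~tr
            if y[tr].min() == y[tr].max() or te.sum() == 0:
                ok = False
                break
            res = fit_logistic(X[tr], y[tr])
            if not res.converged:
                ok = False
                break
            p = np.clip(expit(X[te] @ res.beta), CLIP, 1.0 - CLIP)
            total += -np.sum(y[te] * np.log(p) + (1.0 - y[te]) * np.log1p(-p))
        if ok:
            losses.append(total / len(y))
            kept.append(spec)
        else:
            warnings.warn(f"super learner: dropping candidate {spec.covariates} "
                          "(degenerate or non-convergent on a fold)")
    if not kept:
        raise ConvergenceError("super learner: every candidate failed cross-validation")
    best = int(np.argmin(losses))  # argmin keeps the first minimum: ties by order
    winner = kept[best]
    fit = fit_mechanism(table, winner, horizon=H)
    report = SuperLearnerReport(mechanism=mechanism, candidates=kept, losses=losses,
                                selected=winner, folds=folds, seed=seed)
    return fit, report
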