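"""Weighted logistic marginal structural models for discrete-time hazards.

Two MSMs are fit to the weighted person-quarter data: a *saturated* model
with one hazard per (quarter, regimen) cell — whose weighted MLE is the
closed-form ratio sum(w*Y)/sum(w) within each cell — and a *proportional*
model with common quarter effects plus a single regimen term whose
exponent is reported as the hazard ratio (a discrete-time odds ratio that
approximates the hazard ratio while quarterly hazards are small).

Survival curves are products of one minus the hazards; risks are their
complements; the area-between-curves statistic is the sum over quarters
of the risk differences, tested against zero with a participant-level
bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from ._solver import fit_logistic
from .exceptions import ConvergenceError, EmptyStratumError, InputError
from .weights import WeightTable

__all__ = [
    "ARMS", "HazardSurface", "MSMResult",
    "fit_saturated_msm", "fit_proportional_msm", "survival_and_risks",
    "risk_difference", "area_statistic", "area_between_curves_test",
    "bootstrap_cis",
]

ARMS = ("HI", "AI")
#: fallback when no at_risk column is present: rows in follow-up, events,
#: and administrative-end rows span a full quarter at risk
_MSM_CAUSES = ("none", "admin_end")


@dataclass
class HazardSurface:
    """Per-(quarter, regimen) discrete hazards h(t, a).

    ``hazard`` is indexed by quarter 0..H-1 with columns HI and AI;
    strata with no at-risk weight are NaN and listed in ``undefined``.
    """

    hazard: pd.DataFrame
    model_form: str
    undefined: list = field(default_factory=list)

    @property
    def horizon(self) -> int:
        return len(self.hazard)


@dataclass
class MSMResult:
    hazard_ratio: float
    hazard_ratio_ci: tuple[float, float] | None
    risk_difference_1y: float
    risk_difference_1y_ci: tuple[float, float] | None
    risk_difference_2y: float
    risk_difference_2y_ci: tuple[float, float] | None
    survival: pd.DataFrame
    risks: pd.DataFrame
    area_statistic: float
    area_p_value: float | None
    bootstrap_reps: int = 0
    bootstrap_dropped: int = 0
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)


def _aligned_weights(table: pd.DataFrame, weights: WeightTable | None) -> np.ndarray:
    if weights is None:
        return np.ones(len(table))
    merged = table[["participant", "quarter"]].merge(
        weights.table[["participant", "quarter", "sw_trunc"]],
        on=["participant", "quarter"], how="left", validate="one_to_one")
    w = merged["sw_trunc"].to_numpy()
    if np.isnan(w).any():
        raise InputError("weight table does not cover every person-quarter row")
    return w


def _msm_rows(table: pd.DataFrame) -> np.ndarray:
    """Hazard-model risk set: rows spanning a full quarter at risk."""
    if "at_risk" in table.columns:
        return np.asarray(table["at_risk"], dtype=bool)
    return np.isin(np.asarray(table["censor_cause"].astype(str)), _MSM_CAUSES)


def fit_saturated_msm(table: pd.DataFrame, weights: WeightTable | None = None,
                      horizon: int | None = None) -> HazardSurface:
    """Closed-form weighted MLE of the saturated hazard model.

    h(t, a) = sum(w * Y) / sum(w) over at-risk rows in stratum (t, a);
    empty strata are flagged, not errors, until risks are requested.
    """
    import warnings as _warnings

    H = int(horizon if horizon is not None else np.asarray(table["quarter"]).max() + 1)
    keep = _msm_rows(table)
    sub = table[keep]
    w = _aligned_weights(sub, weights) if weights is not None else np.ones(keep.sum())
    q = np.asarray(sub["quarter"], dtype=np.int64)
    a = (np.asarray(sub["arm"]) == "AI").astype(np.int64)
    y = np.asarray(sub["event"], dtype=np.float64)
    idx = q * 2 + a
    denom = np.bincount(idx, weights=w, minlength=2 * H)
    numer = np.bincount(idx, weights=w * y, minlength=2 * H)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(denom > 0, numer / np.maximum(denom, 1e-300), np.nan)
    hz = pd.DataFrame({"HI": h[0::2], "AI": h[1::2]},
                      index=pd.RangeIndex(H, name="quarter"))
    undefined = [(int(t), arm) for arm, col in zip(ARMS, ["HI", "AI"])
                 for t in range(H) if not np.isfinite(hz[col].iloc[t])]
    if undefined:
        _warnings.warn(f"saturated MSM: empty strata {undefined}")
    return HazardSurface(hazard=hz, model_form="saturated", undefined=undefined)


def fit_proportional_msm(table: pd.DataFrame, weights: WeightTable | None = None,
                         horizon: int | None = None
                         ) -> tuple[HazardSurface, float, float]:
    """Weighted pooled logistic fit with quarter indicators plus one
    regimen term; returns (hazard surface, regimen coefficient, naive SE)."""
    H = int(horizon if horizon is not None else np.asarray(table["quarter"]).max() + 1)
    keep = _msm_rows(table)
    sub = table[keep]
    w = _aligned_weights(sub, weights) if weights is not None else None
    q = np.asarray(sub["quarter"], dtype=np.int64)
    a = (np.asarray(sub["arm"]) == "AI").astype(np.float64)
    y = np.asarray(sub["event"], dtype=np.float64)
    # one indicator per quarter (no global intercept) plus the regimen term
    X = np.column_stack([(q == k).astype(float) for k in range(H)] + [a])
    res = fit_logistic(X, y, weights=w, compute_cov=True)
    if not res.converged:
        raise ConvergenceError(
            f"proportional MSM did not converge in {res.n_iter} iterations")
    beta = float(res.beta[-1])
    se = float(res.bse[-1])
    eta0 = res.beta[:H]
    hz = pd.DataFrame({"HI": expit(eta0), "AI": expit(eta0 + beta)},
                      index=pd.RangeIndex(H, name="quarter"))
    return HazardSurface(hazard=hz, model_form="proportional"), beta, se


def survival_and_risks(surface: HazardSurface) -> tuple[pd.DataFrame, pd.DataFrame]:
    """S_a(t) = prod_{k<t}(1 - h(k, a)) and Risk_a(t) = 1 - S_a(t).

    Both frames are indexed by t = 0..H (end-of-quarter counts; t=0 is
    the index date with survival one).
    """
    if surface.undefined:
        t, arm = surface.undefined[0]
        raise EmptyStratumError(
            f"hazard undefined in stratum (quarter={t}, arm={arm}); "
            "consider the proportional model for sparse data")
    H = surface.horizon
    surv = {}
    for arm in ARMS:
        s = np.empty(H + 1)
        s[0] = 1.0
        s[1:] = np.cumprod(1.0 - surface.hazard[arm].to_numpy())
        surv[arm] = s
    survival = pd.DataFrame(surv, index=pd.RangeIndex(H + 1, name="quarter"))
    return survival, 1.0 - survival


def risk_difference(risks: pd.DataFrame, t: int) -> float:
    """Risk_AI(t) - Risk_HI(t); reference regimen is human insulin."""
    if t not in risks.index:
        raise InputError(f"quarter {t} beyond the fitted horizon")
    return float(risks.loc[t, "AI"] - risks.loc[t, "HI"])


def area_statistic(risks: pd.DataFrame) -> float:
    """T = sum over quarters 1..H of the per-quarter risk differences."""
    rd = risks["AI"].to_numpy() - risks["HI"].to_numpy()
    return float(rd[1:].sum())


# ---------------------------------------------------------------------------
# participant-level bootstrap (generic, callable-pipeline interface)


def _participant_blocks(data: pd.DataFrame):
    df = data.sort_values(["participant", "quarter"], kind="mergesort").reset_index(drop=True)
    pid = np.asarray(df["participant"])
    first = np.r_[True, pid[1:] != pid[:-1]]
    starts = np.nonzero(first)[0]
    counts = np.diff(np.r_[starts, len(df)])
    return df, starts, counts


def _resample(df, starts, counts, rng) -> pd.DataFrame:
    m = len(starts)
    idx = rng.integers(0, m, m)
    L = counts[idx]
    ends = np.cumsum(L)
    rows = np.arange(ends[-1]) - np.repeat(ends - L, L) + np.repeat(starts[idx], L)
    out = df.iloc[rows].copy()
    out["participant"] = np.repeat(np.arange(m), L)  # fresh ids for duplicates
    return out


def _bootstrap_stats(pipeline: Callable[[pd.DataFrame], Mapping[str, float]],
                     data: pd.DataFrame, B: int, seed: int | None):
    if B < 100:
        raise InputError("at least 100 bootstrap replicates are required")
    df, starts, counts = _participant_blocks(data)
    rng = np.random.default_rng(seed)
    stats: list[Mapping[str, float]] = []
    dropped = 0
    for _ in range(B):
        rep = _resample(df, starts, counts, rng)
        try:
            stats.append(pipeline(rep))
        except (EmptyStratumError, ConvergenceError):
            dropped += 1
    if dropped > 0.2 * B:
        raise EmptyStratumError(
            f"{dropped}/{B} bootstrap replicates failed (empty strata or "
            "non-convergence); the data are too sparse for this analysis")
    return stats, dropped


def area_between_curves_test(pipeline: Callable[[pd.DataFrame], pd.DataFrame],
                             data: pd.DataFrame, B: int = 500,
                             seed: int | None = None) -> tuple[float, float]:
    """Two-tailed test that the area between the survival curves is null.

    ``pipeline`` maps a person-quarter table to a risk frame (as returned
    by :func:`survival_and_risks`); it is re-run in full on every
    participant-resampled replicate.  The p-value is the normal
    approximation 2*Phi(-|T|/SE_boot).
    """
    T = area_statistic(pipeline(data))
    stats, dropped = _bootstrap_stats(lambda d: {"T": area_statistic(pipeline(d))},
                                      data, B, seed)
    ts = np.array([s["T"] for s in stats])
    se = float(ts.std(ddof=1))
    if se == 0.0:
        return T, 1.0 if T == 0.0 else 0.0
    return T, float(2.0 * norm.sf(abs(T) / se))


def bootstrap_cis(pipeline: Callable[[pd.DataFrame], Mapping[str, float]],
                  data: pd.DataFrame, B: int = 500, seed: int | None = None
                  ) -> dict[str, tuple[float, float]]:
    """Percentile 95% CIs from a participant-level nonparametric bootstrap.

    ``pipeline`` maps a person-quarter table to a mapping of named scalar
    statistics (e.g. hazard ratio, risk differences); the full pipeline is
    re-run per replicate and seeds make the intervals reproducible.
    """
    stats, dropped = _bootstrap_stats(pipeline, data, B, seed)
    keys = stats[0].keys()
    out = {}
    for k in keys:
        vals = np.array([s[k] for s in stats])
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[k] = (float(lo), float(hi))
    return out
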