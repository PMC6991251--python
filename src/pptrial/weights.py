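"""Stabilised inverse-probability weights: assembly, truncation, diagnostics.

The per-row weight is

    sw(t) = [P_num(A) / P_den(A)]  x  prod_{k<=t} prod_m  P_num(uncensored by m at k)
                                                          / P_den(uncensored by m at k)

with one factor per modelled censoring mechanism m.  Stabilisation (a
marginal numerator model over a covariate-conditional denominator) keeps
the weights mean-one among rows remaining at risk; truncation caps them
at a fixed bound (20 in the primary analysis, upper bound only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError
from .propensity import TREATMENT, PropensityFit, predict_probability, predict_uncensored

__all__ = ["WeightTable", "compute_stabilized_weights", "truncate_weights",
           "weight_diagnostics"]


@dataclass
class WeightTable:
    """Per person-quarter stabilised weights and their components.

    ``table`` has columns participant, quarter, numerator, denominator,
    sw, sw_trunc; ``truncation_bound`` is +inf until
    :func:`truncate_weights` is applied.
    """

    table: pd.DataFrame
    truncation_bound: float = np.inf
    n_truncated: int = 0
    diagnostics: dict = field(default_factory=dict)


def _cumprod_within(pid: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Cumulative product within contiguous participant blocks (log-space)."""
    lv = np.log(values)
    cs = np.cumsum(lv)
    first = np.r_[True, pid[1:] != pid[:-1]]
    idx = np.nonzero(first)[0]
    offset = np.repeat(cs[idx] - lv[idx], np.diff(np.r_[idx, len(pid)]))
    return np.exp(cs - offset)


def compute_stabilized_weights(table: pd.DataFrame,
                               numerator_fits: Mapping[str, PropensityFit],
                               denominator_fits: Mapping[str, PropensityFit]
                               ) -> WeightTable:
    """Assemble stabilised weights from mechanism fits.

    ``numerator_fits`` and ``denominator_fits`` map mechanism names to
    fits and must cover the same mechanisms.  The treatment factor is
    evaluated on the quarter-0 row and carried forward; censoring factors
    accumulate as a cumulative product over quarters.  Rows after
    censoring do not exist, so no weight is assigned to censored futures.
    """
    if set(numerator_fits) != set(denominator_fits):
        raise InputError("numerator and denominator fits must cover the same mechanisms")
    df = table.sort_values(["participant", "quarter"], kind="mergesort")
    pid = np.asarray(df["participant"])
    n = len(df)

    num_row = np.ones(n)
    den_row = np.ones(n)
    floor_hits = 0
    for mech, nfit in numerator_fits.items():
        dfit = denominator_fits[mech]
        if mech == TREATMENT:
            continue
        p_num = predict_uncensored(nfit, df)
        p_den = predict_uncensored(dfit, df)
        floor_hits += int(np.sum(p_den <= dfit.diagnostics.get("clip", 1e-6)))
        num_row *= p_num
        den_row *= p_den

    num_cum = _cumprod_within(pid, num_row)
    den_cum = _cumprod_within(pid, den_row)

    if TREATMENT in numerator_fits:
        first = np.r_[True, pid[1:] != pid[:-1]]
        base = df[first]
        tn = predict_probability(numerator_fits[TREATMENT], base)
        td = predict_probability(denominator_fits[TREATMENT], base)
        counts = np.diff(np.r_[np.nonzero(first)[0], n])
        num_cum = num_cum * np.repeat(tn, counts)
        den_cum = den_cum * np.repeat(td, counts)

    sw = num_cum / den_cum
    out = pd.DataFrame({
        "participant": pid,
        "quarter": np.asarray(df["quarter"]),
        "numerator": num_cum,
        "denominator": den_cum,
        "sw": sw,
        "sw_trunc": sw,
    })
    diags = {"denominator_floor_hits": floor_hits}
    if floor_hits:
        diags["positivity_warning"] = (
            f"{floor_hits} denominator probabilities at the clip floor "
            "(possible positivity violation)")
    return WeightTable(table=out, diagnostics=diags)


def truncate_weights(weights: WeightTable, bound: float = 20.0) -> WeightTable:
    """Cap weights at ``bound`` (upper bound only): sw_trunc = min(sw, bound)."""
    if not bound > 0:
        raise InputError("truncation bound must be positive")
    sw = weights.table["sw"].to_numpy()
    if np.any(sw <= 0) or not np.all(np.isfinite(sw)):
        raise InputError("stabilised weights must be positive and finite")
    out = weights.table.copy()
    out["sw_trunc"] = np.minimum(sw, bound)
    n_trunc = int(np.sum(sw > bound))
    diags = dict(weights.diagnostics)
    diags["n_truncated"] = n_trunc
    return WeightTable(table=out, truncation_bound=bound, n_truncated=n_trunc,
                       diagnostics=diags)


def weight_diagnostics(weights: WeightTable) -> pd.DataFrame:
    """Per-quarter mean, max, 99th percentile and truncated-row count."""
    df = weights.table
    if df.empty:
        raise InputError("empty weight table")
    bound = weights.truncation_bound

    def _one(g: pd.Series) -> pd.Series:
        return pd.Series({
            "mean": g.mean(),
            "max": g.max(),
            "p99": g.quantile(0.99),
        })

    out = df.groupby("quarter")["sw_trunc"].apply(_one).unstack()
    out["n_truncated"] = df[df["sw"] > bound].groupby("quarter")["sw"].count().reindex(
        out.index, fill_value=0).astype(int)
    out["n_rows"] = df.groupby("quarter")["sw"].count()
    return out
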