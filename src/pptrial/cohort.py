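"""Per-protocol analytic cohort construction.

Turns raw dispensing / enrollment / event tables into the person-quarter
dataset of a per-protocol target-trial emulation: regimen arm assigned at
the index fill (day 0), exposure sustained under a fixed days-of-supply
rule, and follow-up right-censored at the earliest protocol deviation
(supply gap, class switch, no refill), plan disenrollment (coverage gap
of more than 90 days), pregnancy, death, or the administrative end of
follow-up.  Quarters are 0-based half-open 90-day windows from the index
date; "1 year" is the end of quarter 4 and "2 years" the end of quarter 8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .simulate import RawStudyData, QUARTER_DAYS

__all__ = [
    "CAUSES",
    "BuildConfig",
    "FollowUpSummary",
    "assign_arm",
    "exposure_timeline",
    "censoring_schedule",
    "build_person_quarters",
    "summarize_follow_up",
    "percentage",
]

#: censoring causes; ``none`` marks in-follow-up (and event) rows
CAUSES = ("none", "gap", "switch", "no_fill", "disenrollment",
          "pregnancy", "death", "admin_end")
CAUSE_CODE = {c: i for i, c in enumerate(CAUSES)}

# same-day tie-break order (events are handled separately and take
# precedence over everything)
_PRECEDENCE = {"death": 1, "disenrollment": 2, "switch": 3, "gap": 4,
               "no_fill": 4, "pregnancy": 5, "admin_end": 6}

HUMAN, ANALOGUE, OTHER = "human", "analogue", "other"


@dataclass(frozen=True)
class BuildConfig:
    """Cohort-construction settings.

    ``supply_days`` is the assumed maximum duration of one dispensing
    (180 in the primary analysis, 365 in the sensitivity analysis);
    stockpiling is null, so a new fill of the same class supersedes the
    remaining supply.  ``admin_end_day`` is the outcome-specific
    administrative end of follow-up in days from index.
    """

    supply_days: int = 180
    horizon_quarters: int = 10
    admin_end_day: int = 900
    outcome_name: str = "event"
    death_is_outcome: bool = False
    quarter_days: int = QUARTER_DAYS

    def __post_init__(self):
        if self.supply_days not in (180, 365):
            raise InputError("supply_days must be 180 or 365")
        if self.horizon_quarters < 1:
            raise InputError("horizon_quarters must be >= 1")
        if self.quarter_days != QUARTER_DAYS:
            raise InputError("quarter length is fixed at 90 days")


# ---------------------------------------------------------------------------
# arm assignment and exposure


def _classify_day0(classes) -> str:
    has_analogue = ANALOGUE in classes
    if has_analogue:
        return "AI"
    if all(c == HUMAN for c in classes) and len(classes) > 0:
        return "HI"
    raise InputError(f"day-0 fills {sorted(set(classes))} do not define a regimen")


def assign_arm(dispensings: pd.DataFrame, participant) -> str:
    """Regimen arm from the day-0 fills: ``AI`` if any index fill is
    analogue (with or without human insulin), ``HI`` if all are human."""
    rows = dispensings[dispensings["participant"] == participant]
    day0 = rows.loc[rows["day"] == 0, "insulin_class"].tolist()
    if not day0:
        raise InputError(
            f"participant {participant!r} has no day-0 dispensing (new-user design)")
    return _classify_day0(day0)


def exposure_timeline(dispensings: pd.DataFrame, participant,
                      supply_days: int) -> list[tuple[int, int, str]]:
    """Half-open exposure intervals [start, end) per insulin class.

    Each fill opens an interval closed at the earlier of ``supply_days``
    after dispensing or the next fill of the same class (stockpiling is
    assumed null).  Intervals are chained within class so that concomitant
    fills of another class do not curtail a regimen's supply.
    """
    rows = dispensings[dispensings["participant"] == participant]
    days = rows["day"].to_numpy()
    if len(days) and days.min() < 0:
        raise InputError("dispensing days must be nonnegative")
    out = []
    for klass, grp in rows.groupby("insulin_class"):
        d = np.unique(grp["day"].to_numpy())
        ends = np.minimum(d + supply_days, np.append(d[1:], d[-1] + supply_days))
        out.extend((int(s), int(e), klass) for s, e in zip(d, ends))
    out.sort(key=lambda iv: (iv[0], iv[2]))
    return out


# ---------------------------------------------------------------------------
# censoring schedule (list-based core shared by the public op and builder)


def _dedup_sorted(xs: list) -> list:
    out = []
    prev = None
    for x in xs:
        if x != prev:
            out.append(x)
            prev = x
    return out


def _schedule_core(arm: str, days: Sequence[int], classes: Sequence[str],
                   spans: Sequence[tuple[int, int]], death_day, preg_day,
                   config: BuildConfig) -> tuple[int, str]:
    """Earliest analytic end of follow-up and its cause.

    ``days``/``classes`` are the participant's fills sorted by day;
    ``spans`` are enrollment (start, end) pairs sorted by start.
    """
    supply = config.supply_days
    horizon_day = config.horizon_quarters * QUARTER_DAYS
    admin_day = min(config.admin_end_day, horizon_day)
    candidates = [(admin_day, _PRECEDENCE["admin_end"], "admin_end")]

    defining = ANALOGUE if arm == "AI" else HUMAN
    def_days = _dedup_sorted([d for d, c in zip(days, classes) if c == defining])

    # first day the chained supply of the regimen-defining class lapses
    lapse_day = None
    later_fill = False
    for i in range(len(def_days) - 1):
        if def_days[i + 1] - def_days[i] > supply:
            lapse_day = def_days[i] + supply
            later_fill = True
            break
    if lapse_day is None and def_days:
        lapse_day = def_days[-1] + supply
    if lapse_day is not None:
        if arm == "AI" and any(c == HUMAN and f <= lapse_day < f + supply
                               for f, c in zip(days, classes)):
            cause = "switch"      # analogue supply lapsed while human continued
        elif later_fill:
            cause = "gap"
        else:
            cause = "no_fill"
        candidates.append((lapse_day, _PRECEDENCE[cause], cause))

    # fills that violate the regimen outright
    for d, c in zip(days, classes):
        if d > 0 and (c == OTHER or (arm == "HI" and c == ANALOGUE)):
            candidates.append((d, _PRECEDENCE["switch"], "switch"))
            break

    # enrollment: a coverage gap of >90 days censors at the last covered day
    for i in range(len(spans) - 1):
        if spans[i + 1][0] < spans[i][1]:
            raise InputError("overlapping enrollment spans")
        if spans[i + 1][0] - spans[i][1] > 90:
            candidates.append((spans[i][1], _PRECEDENCE["disenrollment"],
                               "disenrollment"))
            break
    if spans and spans[-1][1] < admin_day:
        candidates.append((spans[-1][1], _PRECEDENCE["disenrollment"], "disenrollment"))

    if preg_day is not None:
        candidates.append((preg_day, _PRECEDENCE["pregnancy"], "pregnancy"))
    if death_day is not None and not config.death_is_outcome:
        candidates.append((death_day, _PRECEDENCE["death"], "death"))

    day, _, cause = min(candidates)
    return int(day), cause


def censoring_schedule(timeline, arm: str, dispensings: pd.DataFrame,
                       enrollment: pd.DataFrame, deaths: pd.DataFrame,
                       pregnancy_events: pd.DataFrame, config: BuildConfig,
                       participant=None) -> tuple[int, str]:
    """Earliest analytic end of follow-up and its cause for one participant.

    ``timeline`` is the participant's :func:`exposure_timeline` (retained
    for interface symmetry; the schedule is derived from the dispensing
    records directly).  The remaining tables may be pre-filtered to the
    participant or carry a ``participant`` column together with the
    ``participant`` argument.
    """

    def _rows(df):
        if participant is not None and df is not None and "participant" in df.columns:
            return df[df["participant"] == participant]
        return df

    disp = _rows(dispensings).sort_values("day", kind="mergesort")
    spans = sorted(map(tuple, _rows(enrollment)[["start_day", "end_day"]].to_numpy()))
    dd = _rows(deaths)
    death_day = int(dd["day"].min()) if dd is not None and len(dd) else None
    pg = _rows(pregnancy_events)
    preg_day = int(pg["day"].min()) if pg is not None and len(pg) else None
    return _schedule_core(arm, disp["day"].tolist(), disp["insulin_class"].tolist(),
                          spans, death_day, preg_day, config)


# ---------------------------------------------------------------------------
# person-quarter table


def _group_bounds(keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, first = np.unique(keys, return_index=True)
    return uniq, np.append(first, len(keys))


def build_person_quarters(raw: RawStudyData, config: BuildConfig) -> pd.DataFrame:
    """Construct the person-quarter analytic dataset.

    One row per (participant, quarter) while at risk, contiguous from
    quarter 0; the outcome is assigned to the quarter containing its day,
    an event taking precedence over a same-day censoring.  Baseline and
    quarterly covariates are merged onto the rows.
    """
    disp = raw.dispensings.sort_values(["participant", "day"], kind="mergesort")
    if len(disp) and disp["day"].to_numpy().min() < 0:
        raise InputError("dispensing days must be nonnegative")
    d_pid = disp["participant"].to_numpy()
    d_day = disp["day"].tolist()
    d_cls = disp["insulin_class"].tolist()
    pids, bounds = _group_bounds(d_pid)

    enr = raw.enrollment.sort_values(["participant", "start_day"], kind="mergesort")
    e_pid = enr["participant"].to_numpy()
    e_start = enr["start_day"].tolist()
    e_end = enr["end_day"].tolist()
    e_uniq, e_bounds = _group_bounds(e_pid)
    span_map = {p: list(zip(e_start[e_bounds[i]:e_bounds[i + 1]],
                            e_end[e_bounds[i]:e_bounds[i + 1]]))
                for i, p in enumerate(e_uniq)}

    deaths = raw.deaths
    if len(deaths):
        if deaths["participant"].duplicated().any():
            raise InputError("at most one death per participant")
        if deaths["day"].to_numpy().min() < 0:
            raise InputError("death days must be nonnegative")
    death_map = dict(zip(deaths["participant"].tolist(), deaths["day"].tolist())) \
        if len(deaths) else {}

    ev = raw.events
    if len(ev) and ev["day"].to_numpy().min() < 0:
        raise InputError("event days must be nonnegative")
    if config.death_is_outcome:
        event_map: Mapping = death_map
    else:
        sub = ev[ev["outcome"] == config.outcome_name]
        event_map = sub.groupby("participant")["day"].min().to_dict() if len(sub) else {}
    preg = ev[ev["outcome"] == "pregnancy"] if len(ev) else ev
    preg_map = preg.groupby("participant")["day"].min().to_dict() if len(preg) else {}

    H = config.horizon_quarters
    horizon_day = H * QUARTER_DAYS

    out_pid, out_nq, out_event, out_cause, out_arm, out_full = [], [], [], [], [], []
    for i, p in enumerate(pids):
        lo, hi = bounds[i], bounds[i + 1]
        days_i, cls_i = d_day[lo:hi], d_cls[lo:hi]
        j = 0
        while j < len(days_i) and days_i[j] == 0:
            j += 1
        if j == 0:
            raise InputError(
                f"participant {p!r} has no day-0 dispensing (new-user design)")
        arm = _classify_day0(cls_i[:j])

        end_day, cause = _schedule_core(
            arm, days_i, cls_i, span_map.get(p, []),
            death_map.get(p), preg_map.get(p), config)

        ev_day = event_map.get(p)
        if ev_day is not None and ev_day <= end_day and ev_day < horizon_day:
            nq = int(ev_day) // QUARTER_DAYS + 1
            out_event.append(True)
            out_cause.append("none")
            out_full.append(True)
        else:
            nq = min(int(end_day) // QUARTER_DAYS, H - 1) + 1
            out_event.append(False)
            out_cause.append(cause)
            # the terminal row spans a full quarter at risk only when the
            # censoring takes effect at (or beyond) the quarter's end
            out_full.append(end_day >= nq * QUARTER_DAYS)
        out_pid.append(p)
        out_nq.append(nq)
        out_arm.append(arm)

    nq = np.asarray(out_nq, dtype=np.int64)
    n_rows = int(nq.sum())
    pid_rows = np.repeat(np.asarray(out_pid), nq)
    ends = np.cumsum(nq)
    quarter = np.arange(n_rows) - np.repeat(ends - nq, nq)
    last_row = ends - 1
    y = np.zeros(n_rows, dtype=np.int64)
    y[last_row[np.asarray(out_event)]] = 1
    cause_col = np.full(n_rows, "none", dtype=object)
    cause_col[last_row] = out_cause
    # at_risk marks rows spanning a full quarter at risk; a mid-quarter
    # censoring row keeps the cause label but contributes no hazard
    # information (it enters the censoring models, not the MSM risk sets)
    at_risk = np.ones(n_rows, dtype=bool)
    at_risk[last_row] = out_full

    table = pd.DataFrame({
        "participant": pid_rows,
        "quarter": quarter,
        "arm": np.repeat(np.asarray(out_arm, dtype=object), nq),
        "at_risk": at_risk,
        "event": y,
        "censor_cause": pd.Categorical(cause_col, categories=CAUSES),
    })

    base = raw.baseline_covariates
    if base is not None and len(base.columns) > 1:
        table = table.merge(base, on="participant", how="left")
    qcov = raw.quarterly_covariates
    if qcov is not None and len(qcov.columns) > 2:
        table = table.merge(qcov, on=["participant", "quarter"], how="left")
    return table


# ---------------------------------------------------------------------------
# follow-up accounting


def percentage(count: int, total: int) -> float:
    """Share of the cohort as a percentage rounded to one decimal."""
    return round(100.0 * count / total, 1)


@dataclass
class FollowUpSummary:
    """Terminal-status accounting of the analytic follow-up.

    Every participant is counted exactly once, either under the outcome
    (``event``) or under the censoring cause that ended follow-up;
    percentages are reported to one decimal of the cohort size.
    """

    cohort_size: int
    counts: dict[str, int]
    percentages: dict[str, float]
    person_quarters: dict[str, int]
    interruption_count: int = 0
    interruption_pct: float = 0.0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "count": pd.Series(self.counts),
            "percent": pd.Series(self.percentages),
        })


def summarize_follow_up(table: pd.DataFrame, cohort_size: int | None = None) -> FollowUpSummary:
    """Tally terminal statuses, percentages and person-quarters by arm."""
    if cohort_size is None:
        cohort_size = table["participant"].nunique()
    last = table.sort_values(["participant", "quarter"]).groupby("participant").tail(1)
    status = np.where(last["event"].to_numpy() == 1, "event",
                      last["censor_cause"].astype(str).to_numpy())
    counts = {k: 0 for k in ("event", *CAUSES[1:])}
    for s, c in zip(*np.unique(status, return_counts=True)):
        counts[s] = int(c)
    if sum(counts.values()) != cohort_size:
        raise InputError("terminal statuses do not partition the cohort")
    pct = {k: percentage(v, cohort_size) for k, v in counts.items()}
    interruption = counts["gap"] + counts["switch"] + counts["no_fill"]
    pq = table.groupby("arm", observed=True)["quarter"].count().to_dict()
    return FollowUpSummary(
        cohort_size=cohort_size, counts=counts, percentages=pct,
        person_quarters={str(k): int(v) for k, v in pq.items()},
        interruption_count=interruption,
        interruption_pct=percentage(interruption, cohort_size),
    )
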