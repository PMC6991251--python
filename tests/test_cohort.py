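"""Cohort builder: arms, exposure intervals, censoring, accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pptrial as pt
from pptrial.cohort import BuildConfig, CAUSES
from pptrial.exceptions import InputError
from pptrial.simulate import RawStudyData


def _disp(rows):
    return pd.DataFrame(rows, columns=["participant", "day", "insulin_class"])


def _raw(dispensings, enrollment=None, events=None, deaths=None):
    pids = dispensings["participant"].unique()
    if enrollment is None:
        enrollment = pd.DataFrame({"participant": pids, "start_day": 0,
                                   "end_day": 2000})
    if events is None:
        events = pd.DataFrame(columns=["participant", "outcome", "day"])
    if deaths is None:
        deaths = pd.DataFrame(columns=["participant", "day"])
    empty_base = pd.DataFrame({"participant": pids})
    empty_q = pd.DataFrame(columns=["participant", "quarter"])
    return RawStudyData(dispensings, enrollment, events, deaths, empty_base, empty_q)


def _schedule(dispensings, arm="HI", **kw):
    cfg = kw.pop("config", BuildConfig())
    enrollment = kw.pop("enrollment",
                        pd.DataFrame({"participant": [1], "start_day": [0],
                                      "end_day": [2000]}))
    deaths = kw.pop("deaths", pd.DataFrame(columns=["participant", "day"]))
    preg = kw.pop("pregnancy", pd.DataFrame(columns=["participant", "day"]))
    timeline = pt.exposure_timeline(dispensings, 1, cfg.supply_days)
    return pt.censoring_schedule(timeline, arm, dispensings, enrollment, deaths,
                                 preg, cfg, participant=1)


# -- arm assignment ---------------------------------------------------------

@pytest.mark.parametrize("classes, arm", [
    (["human"], "HI"),
    (["analogue", "human"], "AI"),
    (["analogue"], "AI"),
])
def test_day0_fills_define_the_regimen_arm(classes, arm):
    disp = _disp([(1, 0, c) for c in classes])
    assert pt.assign_arm(disp, 1) == arm


def test_missing_index_fill_violates_new_user_design():
    with pytest.raises(InputError, match="day-0"):
        pt.assign_arm(_disp([(1, 30, "human")]), 1)


# -- exposure timeline ------------------------------------------------------

@pytest.mark.parametrize("days, supply, expected", [
    ([0, 100], 180, [(0, 100), (100, 280)]),   # a new fill supersedes supply
    ([0], 180, [(0, 180)]),
    ([0], 365, [(0, 365)]),
])
def test_exposure_intervals_follow_the_supply_rule(days, supply, expected):
    disp = _disp([(1, d, "human") for d in days])
    tl = pt.exposure_timeline(disp, 1, supply)
    assert [(s, e) for s, e, _ in tl] == expected


def test_negative_dispensing_day_is_an_input_error():
    with pytest.raises(InputError, match="nonnegative"):
        pt.exposure_timeline(_disp([(1, -5, "human")]), 1, 180)


def test_concomitant_class_does_not_curtail_supply():
    # intervals chain within class: a human fill must not end an analogue span
    disp = _disp([(1, 0, "analogue"), (1, 10, "human")])
    tl = pt.exposure_timeline(disp, 1, 180)
    assert (0, 180, "analogue") in tl


# -- censoring schedule -----------------------------------------------------

def test_no_refill_censors_at_supply_exhaustion():
    assert _schedule(_disp([(1, 0, "human")])) == (180, "no_fill")


def test_analogue_fill_switches_a_human_only_participant():
    disp = _disp([(1, 0, "human"), (1, 60, "analogue")])
    assert _schedule(disp) == (60, "switch")


def test_enrollment_gap_censors_at_last_covered_day():
    enr = pd.DataFrame({"participant": [1], "start_day": [0], "end_day": [45]})
    disp = _disp([(1, 0, "human"), (1, 80, "human"), (1, 160, "human")])
    assert _schedule(disp, enrollment=enr) == (45, "disenrollment")


def test_analogue_lapse_with_continuing_human_is_a_switch():
    disp = _disp([(1, 0, "analogue"), (1, 90, "human"), (1, 180, "human"),
                  (1, 270, "human")])
    assert _schedule(disp, arm="AI") == (180, "switch")


def test_supply_gap_with_later_fill_is_a_gap_not_discontinuation():
    disp = _disp([(1, 0, "human"), (1, 270, "human")])
    assert _schedule(disp) == (180, "gap")


def test_inhaled_or_animal_insulin_fill_interrupts_the_regimen():
    disp = _disp([(1, 0, "human"), (1, 70, "other")])
    assert _schedule(disp) == (70, "switch")


def test_death_precedes_later_censoring_causes():
    deaths = pd.DataFrame({"participant": [1], "day": [100]})
    disp = _disp([(1, 0, "human"), (1, 80, "human"), (1, 170, "human")])
    assert _schedule(disp, deaths=deaths) == (100, "death")


def test_death_is_not_a_censoring_cause_for_fatal_outcomes():
    deaths = pd.DataFrame({"participant": [1], "day": [100]})
    disp = _disp([(1, 0, "human")])
    cfg = BuildConfig(death_is_outcome=True)
    assert _schedule(disp, deaths=deaths, config=cfg) == (180, "no_fill")


def test_pregnancy_start_censors():
    preg = pd.DataFrame({"participant": [1], "day": [40]})
    disp = _disp([(1, 0, "human"), (1, 80, "human"), (1, 170, "human")])
    assert _schedule(disp, pregnancy=preg) == (40, "pregnancy")


def test_administrative_end_bounds_follow_up():
    disp = _disp([(1, 90 * k, "human") for k in range(12)])
    assert _schedule(disp) == (900, "admin_end")
    cfg = BuildConfig(admin_end_day=500)
    assert _schedule(disp, config=cfg) == (500, "admin_end")


def test_longer_supply_sensitivity_extends_follow_up():
    disp = _disp([(1, 0, "human")])
    assert _schedule(disp, config=BuildConfig(supply_days=365)) == (365, "no_fill")


# -- person-quarter construction -------------------------------------------

def test_event_is_assigned_to_the_quarter_containing_its_day():
    raw = _raw(_disp([(1, 0, "human"), (1, 80, "human"), (1, 170, "human")]),
               events=pd.DataFrame({"participant": [1], "outcome": ["event"],
                                    "day": [95]}))
    table = pt.build_person_quarters(raw, BuildConfig())
    assert table.quarter.tolist() == [0, 1]
    assert table.event.tolist() == [0, 1]
    assert (table.censor_cause == "none").all()


def test_mid_quarter_censoring_yields_single_partial_row():
    enr = pd.DataFrame({"participant": [1], "start_day": [0], "end_day": [50]})
    raw = _raw(_disp([(1, 0, "human")]), enrollment=enr)
    table = pt.build_person_quarters(raw, BuildConfig())
    assert len(table) == 1
    assert table.censor_cause.iloc[0] == "disenrollment"
    assert not table.at_risk.iloc[0]
    assert table.event.iloc[0] == 0


def test_event_precedes_censoring_in_the_same_window():
    raw = _raw(_disp([(1, 0, "human")]),
               events=pd.DataFrame({"participant": [1], "outcome": ["event"],
                                    "day": [100]}))
    table = pt.build_person_quarters(raw, BuildConfig())
    # supply lapses at day 180 but the event at day 100 comes first
    assert table.event.tolist() == [0, 1]


def test_same_day_tie_breaks_in_favour_of_the_event():
    enr = pd.DataFrame({"participant": [1], "start_day": [0], "end_day": [30]})
    raw = _raw(_disp([(1, 0, "human")]), enrollment=enr,
               events=pd.DataFrame({"participant": [1], "outcome": ["event"],
                                    "day": [30]}))
    table = pt.build_person_quarters(raw, BuildConfig())
    assert table.event.iloc[-1] == 1


def test_boundary_censoring_preserves_completed_quarters():
    # supply exhausted exactly at day 180: quarters 0 and 1 were fully at
    # risk; the censoring row sits at quarter 2 with no at-risk time
    raw = _raw(_disp([(1, 0, "human")]))
    table = pt.build_person_quarters(raw, BuildConfig())
    assert table.quarter.tolist() == [0, 1, 2]
    assert table.at_risk.tolist() == [True, True, False]
    assert table.censor_cause.tolist()[-1] == "no_fill"


def test_no_rows_beyond_the_horizon():
    raw = _raw(_disp([(1, 90 * k, "human") for k in range(12)]))
    table = pt.build_person_quarters(raw, BuildConfig(horizon_quarters=10))
    assert table.quarter.max() == 9
    assert table.censor_cause.iloc[-1] == "admin_end"
    assert table.at_risk.all()


def test_overlapping_enrollment_spans_are_rejected():
    enr = pd.DataFrame({"participant": [1, 1], "start_day": [0, 100],
                        "end_day": [200, 400]})
    raw = _raw(_disp([(1, 0, "human")]), enrollment=enr)
    with pytest.raises(InputError, match="overlap"):
        pt.build_person_quarters(raw, BuildConfig())


def test_simulated_cohort_round_trips_without_refill_censoring():
    # with on-time refills certain and switching impossible, nobody is
    # censored for gap, no-fill or switch
    cfg = pt.preset_scenario("null_confounding", n_participants=500, seed=3)
    import dataclasses
    cfg = dataclasses.replace(cfg, refill_model=pt.RefillModel(
        refill={"intercept": 50.0}, switch={"intercept": -50.0}))
    table = pt.build_person_quarters(pt.generate_cohort(cfg), BuildConfig())
    summary = pt.summarize_follow_up(table)
    assert summary.counts["gap"] == 0
    assert summary.counts["no_fill"] == 0
    assert summary.counts["switch"] == 0


# -- accounting -------------------------------------------------------------

def test_percentages_reported_to_one_decimal():
    assert pt.percentage(5464, 127_600) == 4.3
    assert pt.percentage(73_654, 127_600) == 57.7


def test_summary_partitions_the_cohort():
    rows = []
    statuses = (["admin_end"] * 4 + ["gap"] * 3 + ["event"] * 2 + ["death"])
    for i, s in enumerate(statuses):
        rows.append({"participant": i, "quarter": 0, "arm": "HI", "at_risk": s == "event",
                     "event": int(s == "event"),
                     "censor_cause": "none" if s == "event" else s})
    table = pd.DataFrame(rows)
    summary = pt.summarize_follow_up(table)
    assert summary.percentages["admin_end"] == 40.0
    assert summary.percentages["gap"] == 30.0
    assert summary.percentages["event"] == 20.0
    assert summary.percentages["death"] == 10.0
    assert sum(summary.counts.values()) == 10


def test_summary_tallies_person_quarters_by_arm(small_cohort):
    _, _, table = small_cohort
    summary = pt.summarize_follow_up(table)
    assert summary.person_quarters["HI"] == (table.arm == "HI").sum()
    assert summary.person_quarters["AI"] == (table.arm == "AI").sum()
    assert sum(summary.counts.values()) == summary.cohort_size


# -- supply-rule monotonicity (property) ------------------------------------

@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=1000), min_size=0, max_size=8),
       st.booleans())
def test_longer_supply_never_shortens_follow_up(extra_days, analogue_arm):
    days = sorted({0, *extra_days})
    klass = "analogue" if analogue_arm else "human"
    disp = _disp([(1, d, klass) for d in days])
    arm = "AI" if analogue_arm else "HI"
    end180, _ = _schedule(disp, arm=arm, config=BuildConfig(supply_days=180))
    end365, _ = _schedule(disp, arm=arm, config=BuildConfig(supply_days=365))
    assert end365 >= end180
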