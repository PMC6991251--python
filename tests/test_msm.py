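"""Marginal structural models: hazards, curves, risk differences, area test."""

import numpy as np
import pandas as pd
import pytest

import pptrial as pt
from pptrial.exceptions import EmptyStratumError, InputError
from pptrial.msm import (ARMS, HazardSurface, area_between_curves_test,
                         area_statistic, bootstrap_cis, fit_proportional_msm,
                         fit_saturated_msm, risk_difference, survival_and_risks)
from pptrial.weights import WeightTable


def _rows(n, events, arm="HI", quarter=0, weights=None):
    df = pd.DataFrame({
        "participant": np.arange(n), "quarter": quarter, "arm": arm,
        "at_risk": True, "event": [1] * events + [0] * (n - events),
        "censor_cause": "none",
    })
    if weights is None:
        return df, None
    wt = pd.DataFrame({"participant": df.participant, "quarter": df.quarter,
                       "numerator": 1.0, "denominator": 1.0,
                       "sw": weights, "sw_trunc": weights})
    return df, WeightTable(table=wt, truncation_bound=np.inf)


def _surface(h_hi, h_ai):
    hz = pd.DataFrame({"HI": h_hi, "AI": h_ai},
                      index=pd.RangeIndex(len(h_hi), name="quarter"))
    return HazardSurface(hazard=hz, model_form="saturated")


def test_saturated_hazard_is_the_weighted_event_share():
    table, _ = _rows(10, 1)
    with pytest.warns(UserWarning, match="empty strata"):  # no AI rows
        surf = fit_saturated_msm(table, horizon=1)
    assert surf.hazard.loc[0, "HI"] == pytest.approx(0.1)
    assert (0, "AI") in surf.undefined


def test_saturated_hazard_weights_events_and_person_time():
    # event row weight 2 against nine unit-weight survivors: h = 2/11
    w = np.r_[2.0, np.ones(9)]
    table, wt = _rows(10, 1, weights=w)
    with pytest.warns(UserWarning, match="empty strata"):
        surf = fit_saturated_msm(table, wt, horizon=1)
    assert surf.hazard.loc[0, "HI"] == pytest.approx(2 / 11)


def test_saturated_mle_matches_iterative_weighted_logistic(small_cohort):
    import statsmodels.api as sm
    from pptrial.msm import _msm_rows
    _, _, table = small_cohort
    rng = np.random.default_rng(0)
    w = np.exp(rng.normal(0.0, 0.3, len(table)))
    wt = WeightTable(table=pd.DataFrame({
        "participant": table.participant, "quarter": table.quarter,
        "numerator": 1.0, "denominator": 1.0, "sw": w, "sw_trunc": w}),
        truncation_bound=np.inf)
    surf = fit_saturated_msm(table, wt)
    sub = table[_msm_rows(table)]
    ws = w[_msm_rows(table)]
    for t in range(10):
        for arm in ARMS:
            m = (sub.quarter.to_numpy() == t) & (sub.arm.to_numpy() == arm)
            if not m.any():
                continue
            y = sub.event.to_numpy()[m].astype(float)
            if y.min() == y.max():
                expected = y[0]
            else:
                glm = sm.GLM(y, np.ones((m.sum(), 1)),
                             family=sm.families.Binomial(), var_weights=ws[m])
                expected = float(glm.fit().params[0])
                expected = 1 / (1 + np.exp(-expected))
            assert surf.hazard.loc[t, arm] == pytest.approx(expected, abs=1e-8)


def test_unweighted_proportional_fit_equals_pooled_logistic(small_cohort):
    import statsmodels.api as sm
    from pptrial.msm import _msm_rows
    _, _, table = small_cohort
    _, beta, se = fit_proportional_msm(table)
    sub = table[_msm_rows(table)]
    q = sub.quarter.to_numpy()
    a = (sub.arm.to_numpy() == "AI").astype(float)
    X = np.column_stack([(q == k).astype(float) for k in range(10)] + [a])
    res = sm.GLM(sub.event.to_numpy().astype(float), X,
                 family=sm.families.Binomial()).fit()
    assert beta == pytest.approx(res.params[-1], abs=1e-8)
    assert se == pytest.approx(res.bse[-1], abs=1e-6)


def test_zero_hazards_give_unit_survival():
    surv, risks = survival_and_risks(_surface([0.0] * 3, [0.0] * 3))
    assert (surv == 1.0).all().all()
    assert (risks == 0.0).all().all()


def test_survival_is_the_product_of_one_minus_hazard():
    surv, _ = survival_and_risks(_surface([0.1, 0.1], [0.2, 0.0]))
    assert surv.loc[2, "HI"] == pytest.approx(0.81)
    assert surv.loc[2, "AI"] == pytest.approx(0.8)


def test_undefined_stratum_blocks_risk_reporting():
    surf = _surface([0.1, np.nan], [0.1, 0.1])
    surf.undefined = [(1, "HI")]
    with pytest.raises(EmptyStratumError, match="quarter=1.*HI"):
        survival_and_risks(surf)


def test_risk_difference_sign_and_arithmetic():
    risks = pd.DataFrame({"HI": [0.0, 0.042], "AI": [0.0, 0.05]},
                         index=pd.RangeIndex(2, name="quarter"))
    assert risk_difference(risks, 1) == pytest.approx(0.008)
    assert risk_difference(risks, 1) > 0  # AI above HI => positive RD
    same = pd.DataFrame({"HI": [0.0, 0.1], "AI": [0.0, 0.1]})
    assert risk_difference(same, 1) == 0.0
    with pytest.raises(InputError, match="horizon"):
        risk_difference(risks, 5)


def test_area_statistic_sums_quarterly_risk_differences():
    same = pd.DataFrame({"HI": np.linspace(0, 0.3, 11), "AI": np.linspace(0, 0.3, 11)})
    assert area_statistic(same) == 0.0
    shifted = same.assign(AI=same.AI + 0.01)
    shifted.iloc[0, shifted.columns.get_loc("AI")] = 0.0
    assert area_statistic(shifted) == pytest.approx(0.1)


def test_generic_bootstrap_interfaces_are_seed_reproducible():
    cfg = pt.preset_scenario("null_confounding", n_participants=800, seed=21)
    table = pt.build_person_quarters(pt.generate_cohort(cfg), pt.BuildConfig())

    def pipeline_risks(pq):
        return survival_and_risks(fit_saturated_msm(pq, horizon=10))[1]

    t1 = area_between_curves_test(pipeline_risks, table, B=100, seed=5)
    t2 = area_between_curves_test(pipeline_risks, table, B=100, seed=5)
    assert t1 == t2

    def pipeline_stats(pq):
        risks = pipeline_risks(pq)
        return {"rd_1y": risk_difference(risks, 4)}

    c1 = bootstrap_cis(pipeline_stats, table, B=100, seed=6)
    c2 = bootstrap_cis(pipeline_stats, table, B=100, seed=6)
    assert c1 == c2
    lo, hi = c1["rd_1y"]
    assert lo <= pipeline_stats(table)["rd_1y"] <= hi


def test_bootstrap_requires_a_minimum_replicate_count(small_cohort):
    _, _, table = small_cohort
    with pytest.raises(InputError, match="100"):
        bootstrap_cis(lambda d: {"x": 0.0}, table, B=10, seed=0)


def test_unit_weight_curves_equal_kaplan_meier(small_cohort):
    # independent oracle: lifelines KM with mid-quarter censor times coded
    # before the quarter's events
    from lifelines import KaplanMeierFitter
    _, _, table = small_cohort
    surv, _ = survival_and_risks(fit_saturated_msm(table))
    last = table.sort_values(["participant", "quarter"]).groupby("participant").tail(1)
    for arm in ARMS:
        g = last[last.arm == arm]
        ev = g.event.to_numpy().astype(bool)
        tq = g.quarter.to_numpy().astype(float)
        full = g.at_risk.to_numpy()
        times = np.where(ev, tq + 0.5, np.where(full, tq + 1.0, tq))
        km = KaplanMeierFitter().fit(times, ev)
        for t in range(1, 11):
            expected = float(km.survival_function_at_times(float(t)).iloc[0])
            assert surv.loc[t, arm] == pytest.approx(expected, abs=1e-12)
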