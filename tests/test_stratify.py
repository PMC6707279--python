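"""Dichotomization, Kaplan-Meier, log-rank and hazard-ratio contrasts."""

import numpy as np
import pandas as pd
import pytest

from coexsurv.io import SurvivalTable
from coexsurv.simulate import generate_ihc_fixture, luad_ihc_counts, simulate_survival
from coexsurv.stratify import (
    MarkerStatus,
    combine_markers,
    cox_hr_groups,
    dichotomize_expression,
    dichotomize_ihc,
    km_estimate,
    logrank_test,
)


def surv_from(times, events, ids=None):
    ids = ids or [f"S{i}" for i in range(len(times))]
    return SurvivalTable(pd.DataFrame({"sample": ids, "time": times, "event": events}))


def test_ihc_scores_split_at_two():
    table = generate_ihc_fixture({"M": {0: 1, 1: 1, 2: 1, 3: 1}})
    status = dichotomize_ihc(table, "M")
    scores = table.marker_scores("M")
    for sample, score in scores.items():
        assert status.levels[sample] == ("high" if score >= 2 else "low")


def test_ihc_fixture_prevalence():
    table = generate_ihc_fixture(luad_ihc_counts())
    status = dichotomize_ihc(table, "AK1")
    assert (status.levels == "high").sum() == 82
    assert len(status.levels) == 140


def test_expression_median_split_ties_to_low():
    v = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"), name="G")
    status = dichotomize_expression(v)
    assert set(status.levels[status.levels == "high"].index) == {"d", "e"}


def test_expression_split_balanced_at_large_n(rng):
    v = pd.Series(rng.standard_normal(1000), index=[f"S{i}" for i in range(1000)], name="G")
    status = dichotomize_expression(v)
    counts = status.levels.value_counts()
    assert abs(counts["high"] - counts["low"]) <= 1


def test_expression_constant_all_low(caplog):
    v = pd.Series(np.ones(5), index=list("abcde"), name="G")
    with caplog.at_level("WARNING"):
        status = dichotomize_expression(v)
    assert (status.levels == "low").all()


def test_expression_quantile_and_value_rules():
    v = pd.Series(np.arange(10.0), index=[f"S{i}" for i in range(10)], name="G")
    q = dichotomize_expression(v, rule=("quantile", 0.8))
    assert (q.levels == "high").sum() == 2
    f = dichotomize_expression(v, rule=("value", 7.5))
    assert (f.levels == "high").sum() == 2
    with pytest.raises(ValueError):
        dichotomize_expression(v, rule="nope")


def test_km_closed_form_two_events():
    surv = surv_from([1.0, 2.0], [1, 1])
    labels = pd.Series(["g", "g"], index=["S0", "S1"])
    curve = km_estimate(surv, labels)["g"].set_index("time")["survival"]
    assert curve.loc[1.0] == pytest.approx(0.5)
    assert curve.loc[2.0] == pytest.approx(0.0)


def test_km_all_censored_flat_at_one():
    surv = surv_from([1.0, 2.0, 3.0], [0, 0, 0])
    labels = pd.Series(["g"] * 3, index=["S0", "S1", "S2"])
    curve = km_estimate(surv, labels)["g"]
    assert (curve["survival"] == 1.0).all()


def test_km_matches_hand_computed_product_limit():
    # times 1,2,3,4,5; events 1,1,0,1,0
    # S(1)=4/5, S(2)=4/5*3/4=3/5, S(4)=3/5*1/2=3/10
    surv = surv_from([1.0, 2.0, 3.0, 4.0, 5.0], [1, 1, 0, 1, 0])
    labels = pd.Series(["g"] * 5, index=[f"S{i}" for i in range(5)])
    curve = km_estimate(surv, labels)["g"].set_index("time")["survival"]
    assert curve.loc[1.0] == pytest.approx(0.8, abs=1e-12)
    assert curve.loc[2.0] == pytest.approx(0.6, abs=1e-12)
    assert curve.loc[4.0] == pytest.approx(0.3, abs=1e-12)


def test_km_curves_non_increasing_from_one(rng):
    surv = simulate_survival(rng.standard_normal(200), 0.02, 0.01, 200.0, rng_seed=5)
    labels = pd.Series(rng.choice(["x", "y"], size=200), index=surv.frame["sample"])
    for curve in km_estimate(surv, labels).values():
        s = curve["survival"].to_numpy()
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-12)
        assert s[-1] >= 0


def manual_logrank_chi2(times, events, groups):
    """Observed-vs-expected log-rank statistic, direct summation (2 groups)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    g1 = sorted(set(groups))[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == g1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == g1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_logrank_matches_direct_formula(rng):
    n = 40
    times = rng.exponential(10, n).round(0) + 0.5
    events = (rng.uniform(size=n) < 0.7).astype(int)
    events[:2] = 1
    groups = rng.choice(["a", "b"], size=n)
    surv = surv_from(times, events)
    labels = pd.Series(groups, index=[f"S{i}" for i in range(n)])
    chi2, p = logrank_test(surv, labels)
    assert chi2 == pytest.approx(manual_logrank_chi2(times, events, groups), rel=1e-6)


def test_logrank_identical_groups_null():
    times = [1.0, 2.0, 3.0, 4.0] * 2
    events = [1, 1, 0, 1] * 2
    surv = surv_from(times, events)
    labels = pd.Series(["a"] * 4 + ["b"] * 4, index=[f"S{i}" for i in range(8)])
    chi2, p = logrank_test(surv, labels)
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=1e-6)


def test_logrank_invariant_to_relabeling(rng):
    surv = simulate_survival(rng.standard_normal(100), 0.02, 0.01, 200.0, rng_seed=6)
    labels = pd.Series(rng.choice(["a", "b"], size=100), index=surv.frame["sample"])
    chi2_1, _ = logrank_test(surv, labels)
    swapped = labels.map({"a": "b", "b": "a"})
    chi2_2, _ = logrank_test(surv, swapped)
    assert chi2_1 == pytest.approx(chi2_2, rel=1e-9)


def test_logrank_power_under_true_hazard_ratio(rng):
    """True HR 3 with 200/arm rejects at alpha=0.05 nearly always."""
    rejections = 0
    reps = 40
    for i in range(reps):
        eta = np.r_[np.zeros(200), np.full(200, np.log(3.0))]
        surv = simulate_survival(eta, 0.02, 0.005, 200.0, rng_seed=1000 + i)
        labels = pd.Series(["a"] * 200 + ["b"] * 200, index=surv.frame["sample"])
        _, p = logrank_test(surv, labels)
        rejections += p < 0.05
    assert rejections / reps >= 0.95


def test_logrank_needs_two_groups():
    surv = surv_from([1.0, 2.0], [1, 1])
    labels = pd.Series(["a", "a"], index=["S0", "S1"])
    with pytest.raises(ValueError):
        logrank_test(surv, labels)


def test_combine_markers_labels_and_missing_samples():
    a = MarkerStatus("A", pd.Series(["high", "low", "high"], index=["s1", "s2", "s3"]), "r")
    b = MarkerStatus("B", pd.Series(["low", "low"], index=["s1", "s2"]), "r")
    labels = combine_markers(a, b)
    assert labels.to_dict() == {"s1": "a-high/b-low", "s2": "a-low/b-low"}


def test_combine_independent_markers_balanced_cells(rng):
    idx = [f"S{i}" for i in range(400)]
    a = MarkerStatus("A", pd.Series(rng.choice(["low", "high"], 400), index=idx), "r")
    b = MarkerStatus("B", pd.Series(rng.choice(["low", "high"], 400), index=idx), "r")
    counts = combine_markers(a, b).value_counts()
    assert len(counts) == 4
    assert all(abs(c - 100) <= 40 for c in counts)


def test_cox_hr_identical_groups_near_one(rng):
    times = rng.exponential(30, 100)
    events = (rng.uniform(size=100) < 0.7).astype(int)
    surv = surv_from(np.r_[times, times], np.r_[events, events],
                     ids=[f"S{i}" for i in range(200)])
    labels = pd.Series(["a"] * 100 + ["b"] * 100, index=[f"S{i}" for i in range(200)])
    hr = cox_hr_groups(surv, labels, "a")
    row = hr.iloc[0]
    assert row["ci_low"] <= 1.0 <= row["ci_high"]
    assert row["hr"] == pytest.approx(1.0, abs=0.05)


def test_cox_hr_reference_swap_inverts(rng):
    eta = np.r_[np.zeros(150), np.full(150, 0.7)]
    surv = simulate_survival(eta, 0.02, 0.005, 200.0, rng_seed=77)
    labels = pd.Series(["a"] * 150 + ["b"] * 150, index=surv.frame["sample"])
    hr_ab = cox_hr_groups(surv, labels, "a").iloc[0]["hr"]
    hr_ba = cox_hr_groups(surv, labels, "b").iloc[0]["hr"]
    assert hr_ab == pytest.approx(1.0 / hr_ba, rel=1e-6)


def test_cox_hr_degenerate_inputs():
    surv = surv_from([1.0, 2.0], [1, 0])
    labels = pd.Series(["a", "b"], index=["S0", "S1"])
    with pytest.raises(ValueError):
        cox_hr_groups(surv, labels, "ref-missing")
    with pytest.raises(ValueError):
        cox_hr_groups(surv, labels, "b")  # reference has no event
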