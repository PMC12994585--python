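"""Customer estimation, missingness handling and run detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from outagecco.exposure import (
    ExposureSpec,
    audit_missingness,
    build_exposure_table,
    daily_hours_out,
    detect_runs,
    estimate_customers,
    filter_counties,
    impute_gaps,
)
from tests.conftest import make_hourly, single_county_base

M = np.nan


def brute_force_exposed_days(values, n_customers, pct, min_dur):
    """Independent oracle: scan every hour, enumerate maximal out-runs."""
    out = [min(v / n_customers, 1.0) >= pct for v in values]
    days = set()
    i = 0
    while i < len(out):
        if out[i]:
            j = i
            while j < len(out) and out[j]:
                j += 1
            if j - i >= min_dur:
                days.update({h // 24 for h in range(i, j)})
            i = j
        else:
            i += 1
    return days


# -- customer estimation -----------------------------------------------------

def test_estimate_customers_proportional_split():
    cu = pd.DataFrame(
        {"county_id": ["A", "B"], "state_id": ["S", "S"], "units": [250, 750]}
    )
    st_tot = pd.DataFrame({"state_id": ["S"], "total_customers": [1000]})
    out = estimate_customers(cu, st_tot)
    assert list(out["estimated_customers"]) == [250, 750]


def test_estimate_customers_single_county_state_and_errors():
    cu = pd.DataFrame({"county_id": ["A"], "state_id": ["S"], "units": [123]})
    st_tot = pd.DataFrame({"state_id": ["S"], "total_customers": [5000]})
    assert estimate_customers(cu, st_tot)["estimated_customers"].iloc[0] == 5000
    with pytest.raises(ValueError, match="without customer totals"):
        estimate_customers(cu, pd.DataFrame({"state_id": ["T"], "total_customers": [1]}))


def test_estimate_customers_zero_units_flagged():
    cu = pd.DataFrame(
        {"county_id": ["A", "B"], "state_id": ["S", "S"], "units": [0, 100]}
    )
    st_tot = pd.DataFrame({"state_id": ["S"], "total_customers": [900]})
    out = estimate_customers(cu, st_tot)
    assert out.loc[out["county_id"] == "A", "estimated_customers"].iloc[0] == 0
    assert out.loc[out["county_id"] == "A", "zero_units"].iloc[0]


def test_estimate_customers_within_state_sums():
    rng = np.random.default_rng(0)
    cu = pd.DataFrame(
        {
            "county_id": [f"C{i}" for i in range(30)],
            "state_id": rng.choice(["S1", "S2", "S3"], 30),
            "units": rng.integers(1, 5000, 30),
        }
    )
    st_tot = pd.DataFrame(
        {"state_id": ["S1", "S2", "S3"], "total_customers": [10000, 25000, 40000]}
    )
    out = estimate_customers(cu, st_tot)
    sums = out.groupby("state_id")["estimated_customers"].sum()
    counts = out.groupby("state_id").size()
    for s in sums.index:
        total = st_tot.set_index("state_id").loc[s, "total_customers"]
        assert abs(sums[s] - total) <= counts[s]  # rounding slack per county


# -- missingness -------------------------------------------------------------

def test_audit_missingness_fractions():
    assert audit_missingness(make_hourly([1.0] * 48))["missing_fraction"].iloc[0] == 0
    assert audit_missingness(make_hourly([M] * 48))["missing_fraction"].iloc[0] == 1
    vals = [1.0] * 36 + [M] * 12
    assert audit_missingness(make_hourly(vals))["missing_fraction"].iloc[0] == 0.25


def test_impute_gaps_locf_within_limit():
    out = impute_gaps(make_hourly([500, M, M, M, 200]), ExposureSpec())
    np.testing.assert_array_equal(
        out["customers_out"], [500, 500, 500, 500, 200]
    )


def test_impute_gaps_long_gap_and_leading_gap_zero_filled():
    spec = ExposureSpec()
    out = impute_gaps(make_hourly([500, M, M, M, M, M, 200]), spec)
    np.testing.assert_array_equal(
        out["customers_out"], [500, 0, 0, 0, 0, 0, 200]
    )
    lead = impute_gaps(make_hourly([M, M, 300]), spec)
    np.testing.assert_array_equal(lead["customers_out"], [0, 0, 300])


def test_impute_gaps_zero_policy_and_identity():
    out = impute_gaps(make_hourly([500, M, 200]), ExposureSpec(gap_fill_policy="zero"))
    np.testing.assert_array_equal(out["customers_out"], [500, 0, 200])
    clean = make_hourly([1.0, 2.0, 3.0])
    np.testing.assert_array_equal(
        impute_gaps(clean, ExposureSpec())["customers_out"], [1, 2, 3]
    )


def test_impute_is_idempotent():
    spec = ExposureSpec()
    once = impute_gaps(make_hourly([500, M, M, 200, M] + [M] * 6), spec)
    twice = impute_gaps(once.drop(columns="imputed"), spec)
    np.testing.assert_array_equal(once["customers_out"], twice["customers_out"])


def test_policies_agree_on_gap_free_series():
    vals = list(np.random.default_rng(5).integers(0, 50, 72).astype(float))
    a = impute_gaps(make_hourly(vals), ExposureSpec(gap_fill_policy="locf_then_zero"))
    b = impute_gaps(make_hourly(vals), ExposureSpec(gap_fill_policy="zero"))
    np.testing.assert_array_equal(a["customers_out"], b["customers_out"])


# -- run detection -----------------------------------------------------------

def test_detect_runs_exact_boundary():
    base = single_county_base()
    vals = [0.0] * 8 + [15.0] * 8 + [0.0] * 8  # 8 consecutive hours at 1.5%
    days = detect_runs(make_hourly(vals), base, ExposureSpec())
    assert {d for _, d in days} == {pd.Timestamp("2018-01-01")}
    vals7 = [0.0] * 8 + [15.0] * 7 + [0.0] * 9
    assert detect_runs(make_hourly(vals7), base, ExposureSpec()) == set()


def test_run_spanning_midnight_marks_both_days():
    base = single_county_base()
    vals = [0.0] * 20 + [15.0] * 8 + [0.0] * 20
    days = {d for _, d in detect_runs(make_hourly(vals), base, ExposureSpec())}
    assert days == {pd.Timestamp("2018-01-01"), pd.Timestamp("2018-01-02")}
    start_only = ExposureSpec(day_attribution="start")
    days = {d for _, d in detect_runs(make_hourly(vals), base, start_only)}
    assert days == {pd.Timestamp("2018-01-01")}


def test_overcount_clamps_ratio():
    base = single_county_base(customers=100)
    vals = [250.0] * 8 + [0.0] * 16  # more customers out than estimated
    days = detect_runs(make_hourly(vals), base, ExposureSpec())
    assert len(days) == 1


@settings(max_examples=200, deadline=None)
@given(st.lists(st.integers(0, 30), min_size=24, max_size=96), st.integers(4, 12))
def test_detect_runs_matches_brute_force(values, min_dur):
    """Property check against the windowed-scan oracle (the bulk 1e4-series
    comparison lives in the acceptance suite)."""
    base = single_county_base(customers=1000)
    vals = [float(v) for v in values]
    spec = ExposureSpec(pct_threshold=0.01, min_duration_hours=min_dur)
    got = {d for _, d in detect_runs(make_hourly(vals), base, spec)}
    expect = {
        pd.Timestamp("2018-01-01") + pd.Timedelta(days=d)
        for d in brute_force_exposed_days(vals, 1000, 0.01, min_dur)
    }
    assert got == expect


def test_daily_hours_out_bounds_and_oracle():
    base = single_county_base()
    all_out = daily_hours_out(make_hourly([100.0] * 24), base)
    assert list(all_out["hours_out"]) == [24]
    none = daily_hours_out(make_hourly([0.0] * 24), base)
    assert list(none["hours_out"]) == [0]
    rng = np.random.default_rng(8)
    vals = rng.integers(0, 25, 120).astype(float)
    got = daily_hours_out(make_hourly(list(vals)), base)["hours_out"].to_numpy()
    expect = (vals.reshape(-1, 24) >= 10).sum(axis=1)
    np.testing.assert_array_equal(got, expect)


def test_filter_counties_cutoffs():
    audits = pd.DataFrame(
        {"county_id": ["A", "B", "C"], "missing_fraction": [0.07, 0.49, 0.51]}
    )
    assert filter_counties(audits, ExposureSpec()) == ["A", "B"]
    assert filter_counties(audits, ExposureSpec(county_missing_exclusion=0.20)) == ["A"]
    with pytest.raises(ValueError, match="no counties retained"):
        filter_counties(audits, ExposureSpec(county_missing_exclusion=0.01))


def test_exposure_table_monotone_in_duration_and_threshold(tiny_sim):
    """Nesting invariants: exposed(12h) => exposed(8h) => exposed(4h) and
    exposed(5%) => exposed(3%) => exposed(1%)."""
    from outagecco.exposure import estimate_customers

    base = estimate_customers(tiny_sim.county_units, tiny_sim.state_totals)
    table = build_exposure_table(tiny_sim.hourly, base, ExposureSpec())
    for pct in (1, 3, 5):
        assert (table[f"exposed_12h_{pct}pct"] <= table[f"exposed_8h_{pct}pct"]).all()
        assert (table[f"exposed_8h_{pct}pct"] <= table[f"exposed_4h_{pct}pct"]).all()
    for dur in (4, 8, 12):
        assert (table[f"exposed_{dur}h_5pct"] <= table[f"exposed_{dur}h_3pct"]).all()
        assert (table[f"exposed_{dur}h_3pct"] <= table[f"exposed_{dur}h_1pct"]).all()
    assert table["hours_out"].between(0, 24).all()
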