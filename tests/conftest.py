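import numpy as np
import pandas as pd
import pytest

from outagecco import design, simulate


@pytest.fixture(scope="session")
def tiny_sim():
    """Full-resolution tiny study (5 counties x 60 days) with claims."""
    return simulate.simulate_study(simulate.named_config("tiny", seed=11))


@pytest.fixture(scope="session")
def daily_sim():
    """Mid-size daily-resolution study for model-layer tests."""
    return simulate.simulate_daily(simulate.SimConfig(n_counties=40, n_days=200, seed=7))


@pytest.fixture(scope="session")
def cvd_rows(daily_sim):
    return design.assemble(daily_sim.daily, "cvd")


def make_hourly(values, county_id="C0", start="2018-01-01"):
    """Hourly feed DataFrame from a plain list (np.nan = missing)."""
    ts = pd.date_range(start, periods=len(values), freq="h")
    return pd.DataFrame(
        {
            "county_id": county_id,
            "timestamp": ts,
            "customers_out": np.asarray(values, dtype=float),
        }
    )


def single_county_base(county_id="C0", customers=1000):
    return pd.DataFrame(
        {
            "county_id": [county_id],
            "state_id": ["S0"],
            "units": [customers],
            "estimated_customers": [customers],
            "zero_units": [False],
        }
    )
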