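"""Time-stratified case-crossover strata and analysis-row assembly.

The time-stratified referent scheme compares each county-day to the other
days in the same county, year, month and day-of-week stratum (4-5 days per
stratum). Assembly produces one row per county-day with the outcome count,
complete 7-day exposure and temperature histories (lags 0-6), same-day
precipitation/wind, and anomalous-temperature / wildfire-smoke flags.

Days whose lag lookback precedes the data start are dropped (complete-case
histories; the count is logged), as are strata whose outcome total is zero
or that retain fewer than two member days — neither contributes to the
conditional Poisson likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClimatologySpec",
    "build_strata",
    "assemble",
    "climatology_percentiles",
    "flag_anomalous",
    "flag_smoke",
]

log = logging.getLogger(__name__)

N_LAGS = 7


@dataclass(frozen=True)
class ClimatologySpec:
    """Anomalous-day definition: a hot day must exceed both the county's
    hot percentile and the absolute Celsius cutoff; a cold day must fall
    below both."""

    hot_percentile: float = 0.85
    cold_percentile: float = 0.15
    hot_cutoff_c: float = 24.0
    cold_cutoff_c: float = 0.0

    def __post_init__(self):
        if not self.cold_percentile < self.hot_percentile:
            raise ValueError("cold percentile must be below hot percentile")


def build_strata(dates, county_ids) -> pd.Series:
    """Stratum key "county|year|month|weekday" for aligned date/county
    sequences."""
    dates = pd.DatetimeIndex(dates)
    county_ids = pd.Series(np.asarray(county_ids, dtype=object))
    return (
        county_ids.astype(str)
        + "|"
        + pd.Series(dates.year.astype(str))
        + "|"
        + pd.Series(dates.month.astype(str))
        + "|"
        + pd.Series(dates.weekday.astype(str))
    )


def assemble(
    daily: pd.DataFrame,
    outcome: str,
    exposure_col: str = "exposed",
    hours_col: str = "hours_out",
    min_stratum_days: int = 2,
) -> pd.DataFrame:
    """Build the analysis-row table for one outcome from a daily table.

    `daily` needs columns county_id, date, the exposure indicator and hours
    columns, tmax_c, precip_mm, wind_ms, the outcome count column
    ("cvd_count"/"resp_count" or `outcome` itself), and optionally
    smoke_day / hot_day / cold_day flags. Dates must be consecutive within
    each county.

    Returns rows with y, exp_lag0..6, hours_lag0..6, tmax_lag0..6, precip,
    wind, flags and the stratum key.
    """
    ycol = outcome if outcome in daily.columns else f"{outcome}_count"
    if ycol not in daily.columns:
        raise ValueError(f"unknown outcome {outcome!r}")
    df = daily.sort_values(["county_id", "date"]).reset_index(drop=True)
    for cid, g in df.groupby("county_id"):
        deltas = np.diff(pd.DatetimeIndex(g["date"]).asi8)
        if len(deltas) and not np.all(deltas == 24 * 3600 * 10**9):
            raise ValueError(f"county {cid}: dates are not consecutive days")

    g = df.groupby("county_id")
    out = pd.DataFrame(
        {
            "county_id": df["county_id"],
            "date": df["date"],
            "y": df[ycol].to_numpy(),
            "precip": df["precip_mm"].to_numpy(),
            "wind": df["wind_ms"].to_numpy(),
        }
    )
    for l in range(N_LAGS):
        out[f"exp_lag{l}"] = g[exposure_col].shift(l).to_numpy()
        out[f"hours_lag{l}"] = g[hours_col].shift(l).to_numpy()
        out[f"tmax_lag{l}"] = g["tmax_c"].shift(l).to_numpy()
    for flag in ("smoke_day", "hot_day", "cold_day"):
        if flag in df.columns:
            out[flag] = df[flag].astype(int).to_numpy()

    lag_cols = [f"exp_lag{l}" for l in range(N_LAGS)]
    complete = out[lag_cols + [f"tmax_lag{l}" for l in range(N_LAGS)]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropped %d days with incomplete lag histories", n_dropped)
    out = out[complete].reset_index(drop=True)

    out["stratum"] = build_strata(out["date"], out["county_id"]).to_numpy()
    totals = out.groupby("stratum")["y"].transform("sum")
    sizes = out.groupby("stratum")["y"].transform("size")
    keep = (totals > 0) & (sizes >= min_stratum_days)
    log.info(
        "dropped %d rows in zero-outcome strata, %d in undersized strata",
        int((totals == 0).sum()), int(((totals > 0) & (sizes < min_stratum_days)).sum()),
    )
    return out[keep].reset_index(drop=True)


def climatology_percentiles(
    reference: pd.DataFrame,
    spec: ClimatologySpec = ClimatologySpec(),
    min_values: int = 100,
) -> pd.DataFrame:
    """Per-county cold/hot temperature percentiles from a reference series.

    `reference` has columns county_id and tmax_c. Percentiles use the
    linear-interpolation convention (recorded in the output attrs).
    Counties with fewer than `min_values` reference values are flagged and
    get no percentiles.
    """
    rows = []
    for cid, g in reference.groupby("county_id"):
        vals = g["tmax_c"].dropna().to_numpy()
        if len(vals) < min_values:
            log.warning("county %s: only %d reference values; flagged", cid, len(vals))
            rows.append((cid, np.nan, np.nan, True))
            continue
        p_cold = float(np.percentile(vals, 100 * spec.cold_percentile))
        p_hot = float(np.percentile(vals, 100 * spec.hot_percentile))
        rows.append((cid, p_cold, p_hot, False))
    out = pd.DataFrame(rows, columns=["county_id", "p_cold", "p_hot", "insufficient"])
    out.attrs["percentile_convention"] = "linear interpolation between order statistics"
    return out


def flag_anomalous(
    weather: pd.DataFrame,
    percentiles: pd.DataFrame,
    spec: ClimatologySpec = ClimatologySpec(),
) -> pd.DataFrame:
    """Add hot_day / cold_day flags to a daily weather table.

    hot_day: tmax strictly above both the county's hot percentile and the
    absolute hot cutoff; cold_day: strictly below both the cold percentile
    and cold cutoff. With cutoffs 24 C > 0 C the two are mutually exclusive.
    """
    out = weather.merge(percentiles[["county_id", "p_cold", "p_hot"]], on="county_id")
    t = out["tmax_c"]
    out["hot_day"] = ((t > out["p_hot"]) & (t > spec.hot_cutoff_c)).astype(int)
    out["cold_day"] = ((t < out["p_cold"]) & (t < spec.cold_cutoff_c)).astype(int)
    return out.drop(columns=["p_cold", "p_hot"])


def flag_smoke(smoke_ugm3) -> np.ndarray:
    """Smoke-day indicator: strictly positive wildfire-smoke PM2.5.

    Missing concentrations count as unexposed (with a warning); negative
    concentrations are physically impossible and raise.
    """
    s = pd.Series(smoke_ugm3, dtype=float)
    if (s.dropna() < 0).any():
        raise ValueError("negative smoke concentration")
    n_missing = int(s.isna().sum())
    if n_missing:
        log.warning("%d missing smoke concentrations treated as unexposed", n_missing)
    return (s.fillna(0.0) > 0).astype(int).to_numpy()
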