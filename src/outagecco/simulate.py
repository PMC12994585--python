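"""Synthetic county-level outage, weather, and hospitalization data.

Generates the four inputs the analysis pipeline consumes — hourly
customers-without-power feeds, customer-base tables, daily meteorology and
daily cause-specific hospitalization counts (or raw claims) — with fully
known ground truth, so parameter recovery, calibration and type-I error can
be tested against the truth.

The generative model mirrors the structure the analysis assumes:

* Daily outage occurrence per county follows a stationary two-state Markov
  chain whose transition probabilities are solved from the target marginal
  prevalence p and lag-1 autocorrelation rho of the binary indicator:
  ``P(0->1) = p(1-rho)``, ``P(1->1) = p + rho(1-p)``.
* An outage day carries one contiguous within-day run of >= 8 hours during
  which >= 1% of the county's customers are out, so the daily indicator
  derived by the exposure module's 8h/1% rule recovers the chain state
  exactly (absent injected missingness).
* Hourly missingness arrives MCAR in geometric-length blocks, emulating
  utility-website downtime, independent of outage state.
* Weather has a sinusoidal annual temperature cycle with AR(1) noise;
  outage days are on average colder and windier via additive shifts.
* Daily counts are Poisson with log-rate = county baseline
  + county x month x weekday stratum effect (centered within county)
  + distributed-lag outage effect (lags 0-6) + smooth lagged temperature
  effect. Lag-effect curves are drawn from the span of the natural-spline
  lag basis so the fitted constrained model is correctly specified.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import SplineSpec, lag_basis_matrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimData",
    "markov_transitions",
    "paper_like_lag_curve",
    "gen_daily_exposure",
    "gen_customer_base",
    "gen_outage_series",
    "gen_weather",
    "gen_counts",
    "gen_claims",
    "simulate_daily",
    "simulate_study",
    "make_fixture",
    "load_fixture",
    "named_config",
]

N_LAGS = 7

# ICD-10 code pools used when expanding counts into claim records.
CVD_CODES = ("I10", "I110", "I130", "I214", "I2510", "I480", "I5023", "I639")
RESP_CODES = ("J9601", "J441", "J449", "J189", "J690", "J45901", "J810")
FILLER_CODES = ("Z000", "E119", "N179", "K219", "M545", "R079", "G309",
                "F329", "D649", "E785")


def markov_transitions(p: float, rho: float) -> tuple[float, float]:
    """Transition probabilities (P(0->1), P(1->1)) of the stationary two-state
    chain with marginal prevalence `p` and lag-1 autocorrelation `rho`.

    Raises ValueError outside the feasible region
    ``-p/(1-p) <= rho <= 1`` (which keeps both probabilities in [0, 1]).
    """
    if not 0 < p < 1:
        raise ValueError("prevalence must be in (0, 1)")
    lo = -p / (1 - p)
    if not lo <= rho <= 1:
        raise ValueError(
            f"(prevalence={p}, rho={rho}) is infeasible for a two-state "
            f"Markov chain; feasible region is {lo:.4f} <= rho <= 1"
        )
    p01 = p * (1 - rho)
    p11 = p + rho * (1 - p)
    return p01, p11


def paper_like_lag_curve(
    shape: np.ndarray, anchor_lag: int, anchor: float, lag_df: int
) -> tuple[float, ...]:
    """Project a lag-effect shape onto the constrained natural-spline lag
    basis and rescale so the value at `anchor_lag` equals `anchor`.

    Ensures the true lag curve lies in the span of the fitted lag basis, so
    the constrained distributed-lag model is correctly specified and
    parameter-recovery tests measure estimation error, not projection error.
    """
    C = lag_basis_matrix(SplineSpec(df=lag_df), N_LAGS)
    gamma, *_ = np.linalg.lstsq(C, np.asarray(shape, dtype=float), rcond=None)
    curve = C @ gamma
    if curve[anchor_lag] == 0:
        raise ValueError("projected curve vanishes at the anchor lag")
    return tuple(curve * (anchor / curve[anchor_lag]))


def _default_cvd_curve() -> tuple:
    # positive lags 0-3, near-null 4-6, peak at lag 1 = +2.0%
    return paper_like_lag_curve(
        np.array([0.5, 1.0, 0.7, 0.35, 0.0, -0.1, 0.0]), 1, 0.020, lag_df=5
    )


def _default_resp_curve() -> tuple:
    # strongest same-day, peak at lag 0 = +2.5%
    return paper_like_lag_curve(
        np.array([1.0, 0.6, 0.35, 0.1, 0.0, 0.0, 0.0]), 0, 0.025, lag_df=3
    )


def _default_temp_lag_weights() -> tuple:
    # decaying lag profile in the span of the ns(3) lag basis, sum 1
    C = lag_basis_matrix(SplineSpec(df=3), N_LAGS)
    target = np.array([0.5, 0.3, 0.15, 0.08, 0.04, 0.02, 0.01])
    gamma, *_ = np.linalg.lstsq(C, target, rcond=None)
    w = C @ gamma
    return tuple(w / w.sum())


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study; `seed` determines all output."""

    n_counties: int = 50
    n_days: int = 365
    start_date: str = "2018-01-01"
    # exposure process (county-day scale)
    target_exposure_prevalence: float = 0.013
    target_lag1_autocorr: float = 0.2
    run_extra_mean_hours: float = 4.0   # run length = 8 + capped geometric
    outage_frac_max: float = 0.15       # customers out during a run: U(0.011, max)
    # missingness process (hourly feed)
    missing_block_rate: float = 0.02    # P(block starts) per county-day
    missing_block_mean_hours: float = 12.0
    # outcome process
    baseline_log_rate_range: tuple = (float(np.log(2.0)), float(np.log(12.0)))
    stratum_sd: float = 0.15
    true_lag_log_rr: tuple = field(default_factory=_default_cvd_curve)
    true_lag_log_rr_resp: tuple = field(default_factory=_default_resp_curve)
    true_hour_log_rr: tuple | None = None  # per-hour effects; overrides binary
    # temperature effect: scale * ((tmax - ref)/scale_c)^2, lag-distributed
    temp_effect_scale: float = 0.08
    temp_ref_c: float = 18.0
    temp_scale_c: float = 15.0
    temp_lag_weights: tuple = field(default_factory=_default_temp_lag_weights)
    # weather-exposure coupling
    outage_tmax_shift_c: float = -2.0
    outage_wind_shift_ms: float = 1.5
    smoke_day_prob: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_exposure_prevalence < 1:
            raise ValueError("target_exposure_prevalence must be in (0, 1)")
        if len(self.true_lag_log_rr) != N_LAGS:
            raise ValueError("true_lag_log_rr must have length 7")
        if len(self.true_lag_log_rr_resp) != N_LAGS:
            raise ValueError("true_lag_log_rr_resp must have length 7")
        if self.true_hour_log_rr is not None and len(self.true_hour_log_rr) != N_LAGS:
            raise ValueError("true_hour_log_rr must have length 7")
        markov_transitions(self.target_exposure_prevalence, self.target_lag1_autocorr)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream keyed off the root seed."""
        return np.random.default_rng([self.seed, stream])

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    @property
    def county_ids(self) -> list[str]:
        return [f"C{i:04d}" for i in range(self.n_counties)]


@dataclass
class SimTruth:
    """Ground truth behind a generated dataset."""

    baseline_log_rate: dict          # outcome -> per-county array
    stratum_effects: dict            # outcome -> DataFrame(county, month, weekday, effect)
    exposure: np.ndarray             # (n_counties, n_days) daily indicator
    hours: np.ndarray                # (n_counties, n_days) daily hours out
    true_lag_log_rr: dict            # outcome -> 7-vector
    true_hour_log_rr: tuple | None
    temp_effect: dict                # scale/ref/scale_c/lag_weights
    padded_history_days: int = N_LAGS - 1


@dataclass
class SimData:
    """A generated study: daily analysis table plus (optionally) the raw
    hourly feed, customer base and claims, and the truth behind them."""

    config: SimConfig
    daily: pd.DataFrame              # county_id, date, exposed, hours_out, weather, counts
    truth: SimTruth
    hourly: pd.DataFrame | None = None
    county_units: pd.DataFrame | None = None
    state_totals: pd.DataFrame | None = None
    claims: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------------

def gen_daily_exposure(config: SimConfig) -> np.ndarray:
    """Daily outage indicator, (n_counties, n_days), from the two-state chain
    started at its stationary distribution."""
    p, rho = config.target_exposure_prevalence, config.target_lag1_autocorr
    p01, p11 = markov_transitions(p, rho)
    rng = config.rng(1)
    u = rng.random((config.n_counties, config.n_days))
    E = np.zeros((config.n_counties, config.n_days), dtype=np.int8)
    E[:, 0] = u[:, 0] < p
    for d in range(1, config.n_days):
        prev = E[:, d - 1].astype(bool)
        thr = np.where(prev, p11, p01)
        E[:, d] = u[:, d] < thr
    return E


def _run_lengths(config: SimConfig, rng, size) -> np.ndarray:
    extra = rng.geometric(1.0 / (1.0 + config.run_extra_mean_hours), size) - 1
    return 8 + np.minimum(extra, 16)  # total length in [8, 24]


def gen_customer_base(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """County units (households + establishments) and state customer totals.

    Counties are assigned round-robin to ~n/8 states; state totals are the
    sum of county units times a small reporting factor, so the proportional
    allocation in the exposure module recovers realistic customer counts.
    """
    rng = config.rng(2)
    n_states = max(1, config.n_counties // 8)
    states = [f"S{i:02d}" for i in range(n_states)]
    county_state = [states[i % n_states] for i in range(config.n_counties)]
    units = np.round(rng.lognormal(mean=9.8, sigma=0.6, size=config.n_counties))
    units = np.maximum(units, 50).astype(int)
    county_units = pd.DataFrame(
        {"county_id": config.county_ids, "state_id": county_state, "units": units}
    )
    factor = rng.uniform(0.95, 1.05, size=n_states)
    totals = (
        county_units.groupby("state_id")["units"].sum().reindex(states)
        * factor
    ).round().astype(int)
    state_totals = pd.DataFrame(
        {"state_id": states, "total_customers": totals.to_numpy()}
    )
    return county_units, state_totals


def gen_outage_series(config: SimConfig):
    """Hourly customers-out feed per county (long table with missingness),
    plus the daily truth arrays and customer-base tables.

    Returns (hourly, exposure, hours, county_units, state_totals):
    `hourly` has columns county_id, timestamp, customers_out (NaN = missing).
    """
    from .exposure import estimate_customers  # local import; no cycle at module load

    E = gen_daily_exposure(config)
    county_units, state_totals = gen_customer_base(config)
    base = estimate_customers(county_units, state_totals)
    est = base.set_index("county_id")["estimated_customers"]

    rng = config.rng(3)
    C, D = E.shape
    H = D * 24
    lengths = _run_lengths(config, rng, (C, D)) * E  # 0 where unexposed
    starts = (rng.random((C, D)) * (24 - lengths + 1)).astype(int)
    fracs = rng.uniform(0.011, config.outage_frac_max, (C, D))

    # background blips below the 1% threshold on ~0.5% of observed hours
    blip_mask = rng.random((C, H)) < 0.005
    blip_frac = rng.uniform(0.0, 0.009, (C, H))

    # MCAR missing blocks
    miss_start_day = rng.random((C, D)) < config.missing_block_rate
    miss_start_hour = rng.integers(0, 24, (C, D))
    miss_len = rng.geometric(1.0 / config.missing_block_mean_hours, (C, D))

    timestamps = pd.date_range(config.start_date, periods=H, freq="h")
    frames = []
    hours_truth = np.zeros((C, D), dtype=np.int16)
    for c, cid in enumerate(config.county_ids):
        n_cust = int(est.loc[cid])
        arr = np.zeros(H, dtype=float)
        blips = blip_mask[c] * np.floor(blip_frac[c] * n_cust)
        arr += blips
        for d in np.flatnonzero(E[c]):
            L, s = int(lengths[c, d]), int(starts[c, d])
            arr[d * 24 + s : d * 24 + s + L] = int(np.ceil(fracs[c, d] * n_cust))
            hours_truth[c, d] = L
        for d in np.flatnonzero(miss_start_day[c]):
            t0 = d * 24 + int(miss_start_hour[c, d])
            arr[t0 : t0 + int(miss_len[c, d])] = np.nan
        frames.append(
            pd.DataFrame(
                {"county_id": cid, "timestamp": timestamps, "customers_out": arr}
            )
        )
    hourly = pd.concat(frames, ignore_index=True)
    return hourly, E, hours_truth, county_units, state_totals


def gen_weather(config: SimConfig, exposure: np.ndarray | None = None) -> pd.DataFrame:
    """Daily county meteorology; outage days shifted colder and windier.

    Returns long table (county_id, date, tmax_c, precip_mm, wind_ms,
    smoke_ugm3).
    """
    if exposure is None:
        exposure = gen_daily_exposure(config)
    rng = config.rng(4)
    C, D = exposure.shape
    doy = config.dates.dayofyear.to_numpy()
    mean_c = rng.normal(15.0, 5.0, C)
    amp_c = np.maximum(rng.normal(10.0, 2.0, C), 4.0)
    season = np.sin(2 * np.pi * (doy - 105) / 365.25)
    noise = np.empty((C, D))
    eps = rng.normal(0.0, 3.0, (C, D))
    noise[:, 0] = eps[:, 0]
    for d in range(1, D):
        noise[:, d] = 0.6 * noise[:, d - 1] + eps[:, d]
    tmax = mean_c[:, None] + amp_c[:, None] * season[None, :] + noise
    tmax = tmax + config.outage_tmax_shift_c * exposure

    precip = (rng.random((C, D)) < 0.3) * rng.exponential(5.0, (C, D))
    wind = rng.gamma(4.0, 1.0, (C, D)) + 0.5
    wind = wind + config.outage_wind_shift_ms * exposure
    smoke = (rng.random((C, D)) < config.smoke_day_prob) * rng.exponential(8.0, (C, D))

    idx = pd.MultiIndex.from_product(
        [config.county_ids, config.dates], names=["county_id", "date"]
    )
    return pd.DataFrame(
        {
            "tmax_c": tmax.ravel(),
            "precip_mm": precip.ravel(),
            "wind_ms": wind.ravel(),
            "smoke_ugm3": smoke.ravel(),
        },
        index=idx,
    ).reset_index()


def _lagged_sum(values: np.ndarray, weights) -> np.ndarray:
    """sum_l w_l * values[:, d-l], history before day 0 padded with zeros."""
    C, D = values.shape
    out = np.zeros((C, D))
    for l, w in enumerate(weights):
        if w == 0:
            continue
        out[:, l:] += w * values[:, : D - l]
    return out


def gen_counts(
    exposure: np.ndarray,
    hours: np.ndarray,
    weather: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, SimTruth]:
    """Poisson daily counts for both outcomes plus the SimTruth behind them.

    log-rate = baseline_c + stratum(c, month, weekday)
               + sum_l beta_l * exposure[d-l]   (or per-hour effects x hours)
               + temp_scale * sum_l w_l * g(tmax[d-l])
    with lag histories before the window start padded with zeros (flagged in
    the truth as `padded_history_days`).
    """
    rng = config.rng(5)
    C, D = exposure.shape
    dates = config.dates
    months = dates.month.to_numpy()
    weekdays = dates.weekday.to_numpy()

    tmax = (
        weather.pivot(index="county_id", columns="date", values="tmax_c")
        .reindex(config.county_ids)
        .to_numpy()
    )
    g = ((tmax - config.temp_ref_c) / config.temp_scale_c) ** 2
    temp_term = config.temp_effect_scale * _lagged_sum(g, config.temp_lag_weights)

    lo, hi = config.baseline_log_rate_range
    counts = {}
    baselines, strata_fx = {}, {}
    lag_truth = {
        "cvd": np.asarray(config.true_lag_log_rr),
        "resp": np.asarray(config.true_lag_log_rr_resp),
    }
    for outcome in ("cvd", "resp"):
        b = rng.uniform(lo, hi, C)
        if outcome == "resp":
            b = b - np.log(1351.0 / 805.0)  # respiratory rates run lower
        s = rng.normal(0.0, config.stratum_sd, (C, 12, 7))
        s -= s.mean(axis=(1, 2), keepdims=True)  # sum to zero within county
        stratum_term = s[np.arange(C)[:, None], (months - 1)[None, :], weekdays[None, :]]
        if config.true_hour_log_rr is not None:
            exp_term = _lagged_sum(hours.astype(float), config.true_hour_log_rr)
        else:
            exp_term = _lagged_sum(exposure.astype(float), lag_truth[outcome])
        log_mu = b[:, None] + stratum_term + exp_term + temp_term
        counts[outcome] = rng.poisson(np.exp(log_mu))
        baselines[outcome] = b
        strata_fx[outcome] = pd.DataFrame(
            {
                "county_id": np.repeat(config.county_ids, 12 * 7),
                "month": np.tile(np.repeat(np.arange(1, 13), 7), C),
                "weekday": np.tile(np.arange(7), 12 * C),
                "effect": s.ravel(),
            }
        )

    idx = pd.MultiIndex.from_product(
        [config.county_ids, dates], names=["county_id", "date"]
    )
    out = pd.DataFrame(
        {
            "cvd_count": counts["cvd"].ravel(),
            "resp_count": counts["resp"].ravel(),
        },
        index=idx,
    ).reset_index()
    truth = SimTruth(
        baseline_log_rate=baselines,
        stratum_effects=strata_fx,
        exposure=exposure,
        hours=hours,
        true_lag_log_rr={k: tuple(v) for k, v in lag_truth.items()},
        true_hour_log_rr=config.true_hour_log_rr,
        temp_effect={
            "scale": config.temp_effect_scale,
            "ref_c": config.temp_ref_c,
            "scale_c": config.temp_scale_c,
            "lag_weights": tuple(config.temp_lag_weights),
        },
    )
    return out, truth


def gen_claims(counts: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Expand daily counts into claim records that round-trip through the
    outcomes module.

    Each counted hospitalization becomes one emergency/urgent claim with a
    qualifying I- (CVD) or J- (respiratory) prefix code placed uniformly
    among the first five diagnosis positions. Extra non-counted records are
    added: planned-type claims with qualifying codes, and emergency "decoy"
    claims whose only qualifying code sits in positions 6-10.
    """
    rng = config.rng(6)
    rows = []

    def dx_row(code_pool, qual_position):
        dx = list(rng.choice(FILLER_CODES, size=10))
        dx[qual_position] = str(rng.choice(code_pool))
        return dx

    for rec in counts.itertuples(index=False):
        for outcome, n in (("cvd", rec.cvd_count), ("resp", rec.resp_count)):
            pool = CVD_CODES if outcome == "cvd" else RESP_CODES
            for _ in range(int(n)):
                rows.append(
                    (
                        rec.county_id,
                        rec.date,
                        "emergency" if rng.random() < 0.8 else "urgent",
                        dx_row(pool, int(rng.integers(0, 5))),
                    )
                )
    n_real = len(rows)
    n_extra = max(1, int(0.04 * n_real))
    all_days = counts[["county_id", "date"]].to_numpy()
    for kind in ("planned", "decoy"):
        picks = rng.integers(0, len(all_days), n_extra)
        for i in picks:
            cid, date = all_days[i]
            pool = CVD_CODES if rng.random() < 0.5 else RESP_CODES
            if kind == "planned":
                rows.append((cid, date, "planned", dx_row(pool, int(rng.integers(0, 5)))))
            else:
                adm = "emergency" if rng.random() < 0.8 else "urgent"
                rows.append((cid, date, adm, dx_row(pool, int(rng.integers(5, 10)))))

    claims = pd.DataFrame(
        [(f"CL{i:08d}", cid, date, adm, *dx) for i, (cid, date, adm, dx) in enumerate(rows)],
        columns=["claim_id", "county_id", "date", "admission_type"]
        + [f"dx{j}" for j in range(1, 11)],
    )
    return claims


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_daily(config: SimConfig) -> SimData:
    """Fast path: daily-resolution study (no hourly feed, no claims).

    Used for replicate-heavy experiments where only the model layer is
    exercised; the daily exposure indicator and hours-out come straight from
    the generative truth.
    """
    E = gen_daily_exposure(config)
    rng = config.rng(3)
    hours = (_run_lengths(config, rng, E.shape) * E).astype(np.int16)
    weather = gen_weather(config, E)
    counts, truth = gen_counts(E, hours, weather, config)
    daily = weather.merge(counts, on=["county_id", "date"])
    daily["exposed"] = truth.exposure.ravel()
    daily["hours_out"] = truth.hours.ravel()
    return SimData(config=config, daily=daily, truth=truth)


def simulate_study(config: SimConfig, with_claims: bool = True) -> SimData:
    """Full-resolution study: hourly feed with missingness, customer base,
    weather, counts and (optionally) claims."""
    hourly, E, hours, county_units, state_totals = gen_outage_series(config)
    weather = gen_weather(config, E)
    counts, truth = gen_counts(E, hours, weather, config)
    daily = weather.merge(counts, on=["county_id", "date"])
    daily["exposed"] = E.ravel()
    daily["hours_out"] = hours.ravel()
    claims = gen_claims(counts, config) if with_claims else None
    return SimData(
        config=config,
        daily=daily,
        truth=truth,
        hourly=hourly,
        county_units=county_units,
        state_totals=state_totals,
        claims=claims,
    )


def named_config(name: str, seed: int = 0) -> SimConfig:
    """Named study conditions: "null" (no outage effect), "paper-like"
    (default lag curves shaped like the published ones) and "tiny"
    (5 counties x 60 days, for fast end-to-end tests)."""
    if name == "null":
        zero = tuple([0.0] * N_LAGS)
        return SimConfig(true_lag_log_rr=zero, true_lag_log_rr_resp=zero, seed=seed)
    if name == "paper-like":
        return SimConfig(seed=seed)
    if name == "tiny":
        return SimConfig(n_counties=5, n_days=60, seed=seed)
    raise ValueError(f"unknown fixture name {name!r}")


def _truth_to_jsonable(truth: SimTruth) -> dict:
    return {
        "baseline_log_rate": {k: list(map(float, v)) for k, v in truth.baseline_log_rate.items()},
        "stratum_effects": {
            k: v.to_dict(orient="list") for k, v in truth.stratum_effects.items()
        },
        "exposure": truth.exposure.astype(int).tolist(),
        "hours": truth.hours.astype(int).tolist(),
        "true_lag_log_rr": {k: list(map(float, v)) for k, v in truth.true_lag_log_rr.items()},
        "true_hour_log_rr": (
            list(map(float, truth.true_hour_log_rr))
            if truth.true_hour_log_rr is not None
            else None
        ),
        "temp_effect": {
            k: (list(map(float, v)) if isinstance(v, tuple) else float(v))
            for k, v in truth.temp_effect.items()
        },
        "padded_history_days": truth.padded_history_days,
    }


def _truth_from_jsonable(d: dict) -> SimTruth:
    return SimTruth(
        baseline_log_rate={k: np.array(v) for k, v in d["baseline_log_rate"].items()},
        stratum_effects={k: pd.DataFrame(v) for k, v in d["stratum_effects"].items()},
        exposure=np.array(d["exposure"], dtype=np.int8),
        hours=np.array(d["hours"], dtype=np.int16),
        true_lag_log_rr={k: tuple(v) for k, v in d["true_lag_log_rr"].items()},
        true_hour_log_rr=(
            tuple(d["true_hour_log_rr"]) if d["true_hour_log_rr"] is not None else None
        ),
        temp_effect={
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in d["temp_effect"].items()
        },
        padded_history_days=d["padded_history_days"],
    )


def make_fixture(name: str, config: SimConfig, outdir, overwrite: bool = False) -> Path:
    """Write a full fixture bundle (delimited tables + truth + manifest)."""
    outdir = Path(outdir) / name
    if outdir.exists() and not overwrite:
        raise FileExistsError(f"{outdir} exists; pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_study(config)

    hourly = sim.hourly.copy()
    hourly["timestamp"] = hourly["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    hourly["customers_out"] = hourly["customers_out"].astype("Int64")
    hourly.to_csv(outdir / "outage_hours.csv", index=False)

    for frame, fname in (
        (sim.daily[["county_id", "date", "tmax_c", "precip_mm", "wind_ms", "smoke_ugm3"]], "weather.csv"),
        (sim.daily[["county_id", "date", "cvd_count", "resp_count"]], "counts.csv"),
        (sim.county_units, "county_units.csv"),
        (sim.state_totals, "state_totals.csv"),
        (sim.claims, "claims.csv"),
    ):
        frame.to_csv(outdir / fname, index=False)

    (outdir / "truth.json").write_text(json.dumps(_truth_to_jsonable(sim.truth)))
    manifest = {"name": name, "config": dataclasses.asdict(config)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_fixture(path) -> SimData:
    """Reload a fixture bundle written by :func:`make_fixture`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    cfg_d = manifest["config"]
    for key in ("baseline_log_rate_range", "true_lag_log_rr", "true_lag_log_rr_resp",
                "temp_lag_weights"):
        cfg_d[key] = tuple(cfg_d[key])
    if cfg_d.get("true_hour_log_rr") is not None:
        cfg_d["true_hour_log_rr"] = tuple(cfg_d["true_hour_log_rr"])
    config = SimConfig(**cfg_d)
    truth = _truth_from_jsonable(json.loads((path / "truth.json").read_text()))

    hourly = pd.read_csv(path / "outage_hours.csv", parse_dates=["timestamp"])
    hourly["customers_out"] = hourly["customers_out"].astype(float)
    weather = pd.read_csv(path / "weather.csv", parse_dates=["date"])
    counts = pd.read_csv(path / "counts.csv", parse_dates=["date"])
    daily = weather.merge(counts, on=["county_id", "date"])
    daily["exposed"] = truth.exposure.ravel()
    daily["hours_out"] = truth.hours.ravel()
    return SimData(
        config=config,
        daily=daily,
        truth=truth,
        hourly=hourly,
        county_units=pd.read_csv(path / "county_units.csv"),
        state_totals=pd.read_csv(path / "state_totals.csv"),
        claims=pd.read_csv(path / "claims.csv", parse_dates=["date"]),
    )
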