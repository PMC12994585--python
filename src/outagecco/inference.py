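"""Rate-ratio transformation, secondary analyses and attributable counts.

Maps fitted cross-basis coefficients back to per-lag and cumulative rate
ratios with delta-method Wald intervals, runs the continuous
hours-without-power threshold test (linear vs 3-df spline exposure-response
x lag df 3-6, ranked by common-dispersion qAIC), stratified
effect-modification fits, anomalous-temperature interaction models, the
missingness sensitivity suite, and population-attributable-fraction /
excess-hospitalization arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import CaseCrossover, CaseCrossoverResults, ModelConfig, select_model

__all__ = [
    "LagRRCurve",
    "AttributableResult",
    "lag_rr",
    "cumulative_rr",
    "exposure_response",
    "run_threshold_test",
    "stratified_emm",
    "dme_quartile_contrast",
    "interaction_analysis",
    "attributable_fraction",
    "attributable",
    "run_sensitivity_suite",
]

log = logging.getLogger(__name__)

N_LAGS = 7


@dataclass
class LagRRCurve:
    """Per-lag and cumulative rate ratios for one exposure contrast."""

    table: pd.DataFrame        # index lag0..lag6 + "cumulative"; rr, CI, log_rr, se
    contrast: float
    alpha: float

    @property
    def cumulative(self) -> tuple[float, float, float]:
        row = self.table.loc["cumulative"]
        return float(row["rr"]), float(row["rr_lo"]), float(row["rr_hi"])

    def per_lag(self) -> pd.DataFrame:
        return self.table.drop(index="cumulative")


def _curve_from_weights(W: np.ndarray, beta: np.ndarray, cov: np.ndarray,
                        contrast: float, alpha: float) -> LagRRCurve:
    z = norm.ppf(1 - alpha / 2)
    rows = []
    for l in range(W.shape[0]):
        w = W[l]
        lr = float(w @ beta)
        se = float(np.sqrt(max(w @ cov @ w, 0.0)))
        rows.append((f"lag{l}", lr, se))
    w_cum = W.sum(axis=0)
    lr = float(w_cum @ beta)
    se = float(np.sqrt(max(w_cum @ cov @ w_cum, 0.0)))
    rows.append(("cumulative", lr, se))
    tbl = pd.DataFrame(rows, columns=["lag", "log_rr", "se"]).set_index("lag")
    tbl["rr"] = np.exp(tbl["log_rr"])
    tbl["rr_lo"] = np.exp(tbl["log_rr"] - z * tbl["se"])
    tbl["rr_hi"] = np.exp(tbl["log_rr"] + z * tbl["se"])
    return LagRRCurve(table=tbl, contrast=contrast, alpha=alpha)


def lag_rr(
    results: CaseCrossoverResults, contrast: float = 1.0, alpha: float = 0.05
) -> LagRRCurve:
    """Back-transform the exposure cross-basis block into a lag-RR curve.

    The contrast is exposed-vs-unexposed for binary exposure, or `contrast`
    hours vs 0 for continuous exposure. The cumulative log-RR is the sum of
    the per-lag log-RRs; its variance is the full quadratic form over the
    summed weight vector.
    """
    if not results.converged:
        log.warning("lag_rr on a non-converged fit")
    meta = results.exposure_meta
    beta, cov = results._exposure_block()
    if np.linalg.matrix_rank(cov) < cov.shape[0]:
        raise np.linalg.LinAlgError("singular exposure covariance block")
    W = meta.contrast_weights(x1=contrast, x0=0.0)
    return _curve_from_weights(W, beta, cov, contrast, alpha)


def cumulative_rr(
    results: CaseCrossoverResults, contrast: float = 1.0, alpha: float = 0.05
):
    """Cumulative (lags 0-6) RR with CI; exp of the summed per-lag log-RRs."""
    return lag_rr(results, contrast, alpha).cumulative


def exposure_response(
    results: CaseCrossoverResults,
    grid=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """RR vs hours-without-power, per lag and cumulative, relative to 0 h.

    Returns a long table (hours, lag, rr, rr_lo, rr_hi); lag "cumulative"
    aggregates lags 0-6. RR at 0 hours is identically 1.
    """
    if grid is None:
        grid = np.arange(0, 25)
    meta = results.exposure_meta
    beta, cov = results._exposure_block()
    z = norm.ppf(1 - alpha / 2)
    rows = []
    for h in grid:
        W = meta.contrast_weights(x1=float(h), x0=0.0)
        for label, w in [(f"lag{l}", W[l]) for l in range(W.shape[0])] + [
            ("cumulative", W.sum(axis=0))
        ]:
            lr = float(w @ beta)
            se = float(np.sqrt(max(w @ cov @ w, 0.0)))
            rows.append((float(h), label, np.exp(lr), np.exp(lr - z * se),
                         np.exp(lr + z * se)))
    return pd.DataFrame(rows, columns=["hours", "lag", "rr", "rr_lo", "rr_hi"])


def run_threshold_test(rows: pd.DataFrame, outcome: str):
    """Continuous-exposure threshold test: 8 candidate models.

    {linear, natural-spline df 3} exposure-response x lag df {3, 4, 5, 6},
    ranked by qAIC under a common dispersion from the richest candidate.
    A winning linear family indicates no duration threshold.
    """
    candidates = [
        ModelConfig(outcome=outcome, exposure_kind="hours", exposure_var=var,
                    lag_df=ld)
        for var in ("linear", "ns3")
        for ld in (3, 4, 5, 6)
    ]
    best, table = select_model(candidates, rows)
    return best, table


def stratified_emm(
    rows_by_group: dict[str, pd.DataFrame],
    config: ModelConfig,
    contrast: float = 1.0,
) -> pd.DataFrame:
    """Independent refits per subgroup with a shared model configuration.

    `rows_by_group` maps subgroup labels (e.g. "age_65_75", "female",
    "dme_q1") to assembled row tables. Subgroups whose strata carry no
    information are reported as missing rather than failing. Returns a
    side-by-side per-lag RR table with one block of columns per subgroup.
    """
    pieces = {}
    for label, rows in rows_by_group.items():
        if rows is None or len(rows) == 0:
            log.warning("subgroup %s: no rows; reported as missing", label)
            pieces[label] = None
            continue
        try:
            res = CaseCrossover(rows, config).fit()
            pieces[label] = lag_rr(res, contrast=contrast).table
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("subgroup %s: %s; reported as missing", label, exc)
            pieces[label] = None
    frames = []
    for label, tbl in pieces.items():
        if tbl is None:
            tbl = pd.DataFrame(
                np.nan,
                index=[f"lag{l}" for l in range(N_LAGS)] + ["cumulative"],
                columns=["rr", "rr_lo", "rr_hi"],
            )
        frames.append(tbl[["rr", "rr_lo", "rr_hi"]].add_prefix(f"{label}:"))
    return pd.concat(frames, axis=1)


def dme_quartile_contrast(emm_table: pd.DataFrame, q1: str = "dme_q1",
                          q4: str = "dme_q4") -> pd.DataFrame:
    """First-vs-fourth-quartile comparison of the DME stratified fits."""
    cols = [f"{q1}:rr", f"{q1}:rr_lo", f"{q1}:rr_hi",
            f"{q4}:rr", f"{q4}:rr_lo", f"{q4}:rr_hi"]
    out = emm_table[cols].copy()
    out["rr_ratio_q1_vs_q4"] = out[f"{q1}:rr"] / out[f"{q4}:rr"]
    return out


def interaction_analysis(
    rows: pd.DataFrame,
    modifier: str,
    outcome: str,
    lag: int | None = None,
    alpha: float = 0.05,
):
    """Single-lag exposure x anomalous-day interaction model.

    Fits outage + modifier + outage-x-modifier terms (plus same-day
    temperature spline, precipitation and wind) using the lag with the
    largest main-analysis effect: lag 2 for CVD, lag 0 for respiratory.
    Returns (results, table) where the table reports RR on non-modifier
    days exp(b_outage) and on modifier days exp(b_outage + b_int).
    """
    config = ModelConfig(outcome=outcome, interaction=modifier, interaction_lag=lag)
    used_lag = config.resolved_interaction_lag
    expcol = f"exp_lag{used_lag}"
    overlap = int((rows[expcol].astype(float) * rows[modifier].astype(float)).sum())
    if overlap == 0:
        log.warning(
            "no %s-day exposure overlap at lag %d; interaction unidentifiable",
            modifier, used_lag,
        )
    res = CaseCrossover(rows, config).fit()
    b = res.params
    V = res.cov_params
    z = norm.ppf(1 - alpha / 2)
    b_e, b_i = b["exposure"], b["exposure_x_modifier"]
    se_e = np.sqrt(V.loc["exposure", "exposure"])
    var_mod = (
        V.loc["exposure", "exposure"]
        + V.loc["exposure_x_modifier", "exposure_x_modifier"]
        + 2 * V.loc["exposure", "exposure_x_modifier"]
    )
    se_m = np.sqrt(max(var_mod, 0.0))
    tbl = pd.DataFrame(
        {
            "log_rr": [b_e, b_e + b_i],
            "se": [se_e, se_m],
        },
        index=[f"non_{modifier}", modifier],
    )
    tbl["rr"] = np.exp(tbl["log_rr"])
    tbl["rr_lo"] = np.exp(tbl["log_rr"] - z * tbl["se"])
    tbl["rr_hi"] = np.exp(tbl["log_rr"] + z * tbl["se"])
    tbl.attrs["lag"] = used_lag
    tbl.attrs["exposed_modifier_days"] = overlap
    return res, tbl


@dataclass
class AttributableResult:
    """Population-attributable fraction and excess hospitalizations."""

    rr: float
    rr_lo: float
    rr_hi: float
    af: float
    af_lo: float
    af_hi: float
    exposed_hospitalizations: float
    excess: float
    excess_lo: float
    excess_hi: float
    window: str


def attributable_fraction(rr: float) -> float:
    """AF = (RR - 1) / RR; zero at RR = 1, monotone increasing in RR."""
    if rr <= 0:
        raise ValueError("rate ratio must be positive")
    return (rr - 1.0) / rr


def attributable(
    cumulative: tuple[float, float, float],
    exposed_hospitalizations: float,
    window: str = "outage_day",
) -> AttributableResult:
    """Excess hospitalizations from a cumulative RR and an exposed count.

    `exposed_hospitalizations` is the hospitalization count in the
    designated post-outage window (`window` is descriptive: "outage_day"
    counts hospitalizations on exposed days, "7_day" in the week after).
    CI endpoints propagate the RR CI endpoints through AF.
    """
    rr, lo, hi = cumulative
    af, af_lo, af_hi = (attributable_fraction(v) for v in (rr, lo, hi))
    return AttributableResult(
        rr=rr, rr_lo=lo, rr_hi=hi,
        af=af, af_lo=af_lo, af_hi=af_hi,
        exposed_hospitalizations=float(exposed_hospitalizations),
        excess=af * exposed_hospitalizations,
        excess_lo=af_lo * exposed_hospitalizations,
        excess_hi=af_hi * exposed_hospitalizations,
        window=window,
    )


def exposed_window_count(
    daily: pd.DataFrame, outcome: str, window: str = "outage_day",
    exposure_col: str = "exposed",
) -> float:
    """Hospitalizations in the attributable-count window.

    "outage_day": sum of outcome counts on exposed county-days;
    "7_day": on county-days within 0-6 days after an exposed day.
    """
    ycol = outcome if outcome in daily.columns else f"{outcome}_count"
    df = daily.sort_values(["county_id", "date"])
    if window == "outage_day":
        mask = df[exposure_col].astype(bool)
    elif window == "7_day":
        g = df.groupby("county_id")[exposure_col]
        mask = pd.Series(False, index=df.index)
        for l in range(N_LAGS):
            mask |= g.shift(l).fillna(0).astype(bool)
    else:
        raise ValueError(f"unknown window {window!r}")
    return float(df.loc[mask, ycol].sum())


def run_sensitivity_suite(sim, outcome: str = "cvd", config: ModelConfig | None = None,
                          durations=(8,), thresholds=(0.01,)) -> dict:
    """Paired sensitivity runs on a fixture with injected missingness.

    Crosses {LOCF-then-zero, zero-fill} gap policies with {50%, 20%} county
    missingness exclusion and {with, without} smoke-day adjustment, refits
    the main model under each, and tabulates per-lag RR differences from
    the reference (LOCF, 50%, unadjusted) run.
    """
    from .design import assemble, flag_smoke
    from .exposure import ExposureSpec, build_exposure_table, estimate_customers

    if config is None:
        config = ModelConfig(outcome=outcome)
    base = estimate_customers(sim.county_units, sim.state_totals)
    results, curves = {}, {}
    for policy in ("locf_then_zero", "zero"):
        for cutoff in (0.50, 0.20):
            spec = ExposureSpec(gap_fill_policy=policy, county_missing_exclusion=cutoff)
            table = build_exposure_table(sim.hourly, base, spec,
                                         durations=durations, thresholds=thresholds)
            expo_col = f"exposed_{durations[0]}h_{int(round(thresholds[0] * 100))}pct"
            daily = sim.daily.merge(
                table[["county_id", "date", expo_col, "hours_out"]]
                .rename(columns={expo_col: "exposed_obs", "hours_out": "hours_obs"}),
                on=["county_id", "date"],
                how="inner",
            )
            daily["smoke_day"] = flag_smoke(daily["smoke_ugm3"])
            rows = assemble(daily, outcome, exposure_col="exposed_obs",
                            hours_col="hours_obs")
            for smoke in (False, True):
                key = (policy, cutoff, smoke)
                cfg = dc_replace(config, include_smoke=smoke)
                res = CaseCrossover(rows, cfg).fit()
                results[key] = res
                curves[key] = lag_rr(res).table
    ref = curves[("locf_then_zero", 0.50, False)]
    diffs = {
        str(key): tbl["rr"] - ref["rr"] for key, tbl in curves.items()
    }
    return {
        "results": results,
        "curves": curves,
        "difference_table": pd.concat(diffs, axis=1),
    }
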