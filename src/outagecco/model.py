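"""Conditional Poisson fitting for the time-stratified case-crossover design.

The conditional Poisson model eliminates the stratum-specific intercepts of
a Poisson regression by conditioning on each stratum's outcome total: given
``sum_i y_i = Y_s``, the within-stratum counts are multinomial with
probabilities ``softmax(x_i' beta)``, so the conditional log-likelihood is

    l(beta) = sum_i y_i eta_i - sum_s Y_s log sum_{i in s} exp(eta_i) + const

with ``eta = X beta``. Its maximizer agrees with the stratum-dummy Poisson
GLM (the dummy fit is kept as a test oracle), but conditioning scales to
thousands of strata. Fitting uses Newton-Raphson with step halving on the
exact gradient and Hessian; the model-based covariance is the inverse
observed information.

`ConditionalPoisson` is the low-level likelihood interface (endog, exog,
groups); `CaseCrossover` builds the full design (exposure cross-basis,
temperature cross-basis, precipitation, wind, optional smoke and
anomalous-day interaction terms) from assembled analysis rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .basis import (
    CrossBasisMeta,
    CrossBasisSpec,
    SplineSpec,
    cross_basis,
    natural_spline_basis,
)

__all__ = [
    "ModelConfig",
    "ConditionalPoisson",
    "ConditionalPoissonResults",
    "CaseCrossover",
    "CaseCrossoverResults",
    "build_design",
    "qaic",
    "select_model",
]

log = logging.getLogger(__name__)

N_LAGS = 7


def qaic(llf: float, c_hat: float, k: int) -> float:
    """Quasi-AIC: -2 * loglik / c_hat + 2 * k."""
    if c_hat <= 0:
        raise ValueError("dispersion must be positive")
    return -2.0 * llf / c_hat + 2.0 * k


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of one case-crossover model.

    Defaults follow the main analysis: binary 8h/1% exposure with a
    constrained lag basis (5 df for CVD, 3 for respiratory), temperature as
    a 3-df natural-spline cross-basis over lags 0-6, precipitation with
    2 df (CVD) or linear (respiratory), wind with 3 df.
    """

    outcome: str = "cvd"
    exposure_kind: str = "binary_run"  # or "hours"
    lag_df: int | None = None          # default 5 for cvd, 3 for resp
    exposure_var: str = "binary"       # "binary" | "linear" | "ns3" (hours only)
    temp_var_df: int = 3
    temp_lag_df: int = 3
    precip_df: int | None = None       # default 2 for cvd, 1 (linear) for resp
    wind_df: int = 3
    include_smoke: bool = False
    interaction: str | None = None     # "hot_day" | "cold_day"
    interaction_lag: int | None = None # default 2 for cvd, 0 for resp

    def __post_init__(self):
        if self.outcome not in ("cvd", "resp"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.exposure_kind not in ("binary_run", "hours"):
            raise ValueError(f"unknown exposure_kind {self.exposure_kind!r}")

    @property
    def resolved_lag_df(self) -> int:
        if self.lag_df is not None:
            return self.lag_df
        return 5 if self.outcome == "cvd" else 3

    @property
    def resolved_precip_df(self) -> int:
        if self.precip_df is not None:
            return self.precip_df
        return 2 if self.outcome == "cvd" else 1

    @property
    def resolved_interaction_lag(self) -> int:
        if self.interaction_lag is not None:
            return self.interaction_lag
        return 2 if self.outcome == "cvd" else 0


def _lag_spec(df: int) -> SplineSpec:
    # df == 2 yields [1, lag] (no interior knots); df == 7 the identity basis
    return SplineSpec(df=df)


def build_design(rows: pd.DataFrame, config: ModelConfig):
    """Response, named design matrix, stratum labels and basis metadata.

    Column blocks: exposure cross-basis | temperature cross-basis |
    precipitation | wind | optional smoke indicator | optional
    anomalous-day main effect + interaction (single-lag exposure models).
    """
    y = rows["y"].to_numpy(dtype=float)
    strata = rows["stratum"].to_numpy()
    blocks, names, meta = [], [], {}

    if config.interaction is None:
        if config.exposure_kind == "binary_run":
            hist = rows[[f"exp_lag{l}" for l in range(N_LAGS)]].to_numpy(float)
            var_spec = "binary"
        else:
            hist = rows[[f"hours_lag{l}" for l in range(N_LAGS)]].to_numpy(float)
            var_spec = (
                "linear" if config.exposure_var in ("binary", "linear")
                else SplineSpec(df=3, boundary_knots=(0.0, 24.0))
            )
        cb_spec = CrossBasisSpec(var_spec=var_spec, lag_spec=_lag_spec(config.resolved_lag_df))
        Z, cb_meta = cross_basis(hist, cb_spec, prefix="exp")
        blocks.append(Z)
        names.extend(cb_meta.names)
        meta["exposure"] = cb_meta

        tm_hist = rows[[f"tmax_lag{l}" for l in range(N_LAGS)]].to_numpy(float)
        t_spec = CrossBasisSpec(
            var_spec=SplineSpec(df=config.temp_var_df),
            lag_spec=_lag_spec(config.temp_lag_df),
        )
        Zt, t_meta = cross_basis(tm_hist, t_spec, prefix="tmax")
        blocks.append(Zt)
        names.extend(t_meta.names)
        meta["temperature"] = t_meta
    else:
        if config.interaction not in ("hot_day", "cold_day"):
            raise ValueError(f"unknown interaction modifier {config.interaction!r}")
        lag = config.resolved_interaction_lag
        col = (
            f"exp_lag{lag}" if config.exposure_kind == "binary_run" else f"hours_lag{lag}"
        )
        expv = rows[col].to_numpy(float)
        mod = rows[config.interaction].to_numpy(float)
        blocks.append(np.column_stack([expv, mod, expv * mod]))
        names.extend(["exposure", config.interaction, "exposure_x_modifier"])
        meta["interaction_lag"] = lag
        # same-day temperature spline replaces the lagged temperature
        # cross-basis, which would collinearly encode the modifier
        t_b = natural_spline_basis(
            rows["tmax_lag0"].to_numpy(float), SplineSpec(df=config.temp_var_df)
        )
        blocks.append(t_b)
        names.extend([f"tmax_s{i}" for i in range(t_b.shape[1])])

    p_df = config.resolved_precip_df
    if p_df > 1:
        p_b = natural_spline_basis(rows["precip"].to_numpy(float), SplineSpec(df=p_df))
    else:
        p_b = natural_spline_basis(
            rows["precip"].to_numpy(float), SplineSpec(kind="linear", df=1)
        )
    blocks.append(p_b)
    names.extend([f"precip_s{i}" for i in range(p_b.shape[1])])

    w_b = natural_spline_basis(rows["wind"].to_numpy(float), SplineSpec(df=config.wind_df))
    blocks.append(w_b)
    names.extend([f"wind_s{i}" for i in range(w_b.shape[1])])

    if config.include_smoke:
        smoke = rows["smoke_day"].to_numpy(float)
        if smoke.std() == 0:
            # a constant column is unidentified under stratum conditioning
            log.warning("smoke_day has no variation; adjustment column dropped")
            meta["smoke_dropped"] = True
        else:
            blocks.append(smoke[:, None])
            names.append("smoke_day")

    X = np.column_stack(blocks)
    return y, pd.DataFrame(X, columns=names), strata, meta


class ConditionalPoisson:
    """Stratum-conditioned Poisson likelihood (endog, exog, groups)."""

    def __init__(self, endog, exog, groups, exog_names=None):
        y = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            exog_names = exog_names or list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            exog_names = exog_names or [f"x{i}" for i in range(X.shape[1])]
        groups = np.asarray(groups)
        if not (len(y) == len(X) == len(groups)):
            raise ValueError("endog, exog and groups must align")
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("endog must be non-negative counts")

        codes, inv = np.unique(groups, return_inverse=True)
        order = np.argsort(inv, kind="stable")
        self._order = order
        y, X, inv = y[order], X[order], inv[order]

        totals = np.bincount(inv, weights=y)
        informative = totals > 0
        keep = informative[inv]
        self.n_dropped_strata = int((~informative).sum())
        if self.n_dropped_strata:
            log.info("%d zero-total strata contribute nothing; dropped",
                     self.n_dropped_strata)
        y, X, inv = y[keep], X[keep], inv[keep]
        # re-code to consecutive stratum ids
        _, inv = np.unique(inv, return_inverse=True)

        if len(y) == 0:
            raise ValueError("no informative strata")
        self.endog, self.exog, self._inv = y, X, inv
        self.exog_names = list(exog_names)
        self.n_strata = int(inv.max()) + 1
        self._starts = np.searchsorted(inv, np.arange(self.n_strata))
        self._totals = np.bincount(inv, weights=y)
        # beta-free multinomial constant: sum_s log Y_s! - sum_i log y_i!
        self._llf_const = float(
            gammaln(self._totals + 1).sum() - gammaln(y + 1).sum()
        )

    # -- likelihood machinery ------------------------------------------------

    def _eta_parts(self, beta):
        eta = self.exog @ beta
        m = np.maximum.reduceat(eta, self._starts)
        a = np.exp(eta - m[self._inv])
        S = np.add.reduceat(a, self._starts)
        p = a / S[self._inv]
        return eta, m, S, p

    def loglike(self, beta) -> float:
        eta, m, S, _ = self._eta_parts(beta)
        return float(
            self.endog @ eta - self._totals @ (np.log(S) + m) + self._llf_const
        )

    def score(self, beta) -> np.ndarray:
        *_, p = self._eta_parts(beta)
        mu = self._totals[self._inv] * p
        return self.exog.T @ (self.endog - mu)

    def _neg_hessian(self, p):
        mu = self._totals[self._inv] * p
        XtWX = self.exog.T @ (self.exog * mu[:, None])
        V = np.add.reduceat(self.exog * mu[:, None], self._starts, axis=0)
        return XtWX - (V / self._totals[:, None]).T @ V

    def fitted_means(self, beta) -> np.ndarray:
        """Conditional fitted values Y_s * p_i (equal to the stratum-dummy
        GLM fitted means), in the model's internal row order."""
        *_, p = self._eta_parts(beta)
        return self._totals[self._inv] * p

    def fit(self, start=None, maxiter: int = 200, tol: float = 1e-8):
        k = self.exog.shape[1]
        beta = np.zeros(k) if start is None else np.asarray(start, dtype=float)
        ll = self.loglike(beta)
        converged = False
        for _ in range(maxiter):
            *_, p = self._eta_parts(beta)
            grad = self.exog.T @ (self.endog - self._totals[self._inv] * p)
            H = self._neg_hessian(p)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # step halving keeps the likelihood monotone
            scale_f = 1.0
            for _ in range(40):
                cand = beta + scale_f * step
                ll_new = self.loglike(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                scale_f *= 0.5
            else:
                break
            improved = ll_new - ll
            beta, ll = cand, ll_new
            if abs(improved) <= tol * (abs(ll) + 1.0):
                converged = True
                break
        if not converged:
            log.warning("conditional Poisson fit did not converge")

        *_, p = self._eta_parts(beta)
        H = self._neg_hessian(p)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            converged = False
            log.warning("singular information matrix (possible separation)")
        cov = (cov + cov.T) / 2.0
        if converged and np.max(np.abs(self.score(beta))) > 1e-3 * (1 + abs(ll)):
            converged = False
            log.warning("gradient not small at the reported optimum")
        return ConditionalPoissonResults(self, beta, cov, ll, converged)


@dataclass
class ConditionalPoissonResults:
    """Estimates and diagnostics from a conditional Poisson fit."""

    model: ConditionalPoisson
    params_: np.ndarray
    cov_: np.ndarray
    llf: float
    converged: bool

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.params_, index=self.model.exog_names)

    @property
    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cov_, index=self.model.exog_names, columns=self.model.exog_names
        )

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.clip(np.diag(self.cov_), 0, None)), index=self.model.exog_names
        )

    @property
    def k_params(self) -> int:
        return len(self.params_)

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    @property
    def n_strata(self) -> int:
        return self.model.n_strata

    @property
    def df_resid(self) -> int:
        # stratum intercepts are absorbed but still consume degrees of freedom
        return self.nobs - self.n_strata - self.k_params

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        lo = self.params_ - z * self.bse.to_numpy()
        hi = self.params_ + z * self.bse.to_numpy()
        return pd.DataFrame(
            {"lower": lo, "upper": hi}, index=self.model.exog_names
        )

    def pearson_dispersion(self) -> float:
        """Pearson chi-square / residual df, with residual df counting the
        absorbed stratum parameters."""
        if self.df_resid <= 0:
            raise ValueError("non-positive residual degrees of freedom")
        mu = self.model.fitted_means(self.params_)
        ok = mu > 0
        chi2 = float(np.sum((self.model.endog[ok] - mu[ok]) ** 2 / mu[ok]))
        return chi2 / self.df_resid

    def qaic(self, c_hat: float | None = None) -> float:
        return qaic(self.llf, c_hat if c_hat is not None else self.pearson_dispersion(),
                    self.k_params)

    def summary(self) -> str:
        ci = self.conf_int()
        tbl = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "RR": np.exp(self.params),
                "RR 2.5%": np.exp(ci["lower"]),
                "RR 97.5%": np.exp(ci["upper"]),
            }
        )
        head = (
            "Conditional Poisson (time-stratified case-crossover)\n"
            f"  n rows: {self.nobs}   strata: {self.n_strata}   "
            f"params: {self.k_params}   converged: {self.converged}\n"
            f"  loglik (conditional): {self.llf:.3f}   "
            f"dispersion: {self.pearson_dispersion():.3f}   "
            f"qAIC: {self.qaic():.1f}\n"
        )
        return head + tbl.to_string(float_format=lambda v: f"{v: .4f}")


class CaseCrossover:
    """High-level case-crossover model built from assembled analysis rows.

    Parameters
    ----------
    rows : output of :func:`outagecco.design.assemble`.
    config : ModelConfig naming the outcome and design choices.
    """

    def __init__(self, rows: pd.DataFrame, config: ModelConfig):
        self.rows = rows
        self.config = config
        y, X, strata, meta = build_design(rows, config)
        self.meta = meta
        self._cond = ConditionalPoisson(y, X, strata)

    @classmethod
    def from_daily(cls, daily: pd.DataFrame, config: ModelConfig, **assemble_kw):
        from .design import assemble

        rows = assemble(daily, config.outcome, **assemble_kw)
        return cls(rows, config)

    def fit(self, **kw) -> "CaseCrossoverResults":
        res = self._cond.fit(**kw)
        return CaseCrossoverResults(self, res)


@dataclass
class CaseCrossoverResults:
    """Results wrapper exposing epidemiological summaries of the fit."""

    model: CaseCrossover
    cond: ConditionalPoissonResults

    def __getattr__(self, name):
        return getattr(self.cond, name)

    @property
    def exposure_meta(self) -> CrossBasisMeta:
        return self.model.meta["exposure"]

    def _exposure_block(self):
        names = list(self.exposure_meta.names)
        idx = [self.cond.model.exog_names.index(n) for n in names]
        beta = self.cond.params_[idx]
        cov = self.cond.cov_[np.ix_(idx, idx)]
        return beta, cov

    def lag_rr(self, contrast: float = 1.0, alpha: float = 0.05) -> pd.DataFrame:
        """Per-lag and cumulative rate ratios for an exposure contrast.

        For binary exposure the contrast is exposed vs unexposed; for
        continuous hours it is `contrast` hours vs 0.
        """
        from .inference import lag_rr

        return lag_rr(self, contrast=contrast, alpha=alpha).table

    def cumulative_rr(self, contrast: float = 1.0, alpha: float = 0.05):
        from .inference import lag_rr

        curve = lag_rr(self, contrast=contrast, alpha=alpha)
        return curve.cumulative

    def summary(self) -> str:
        out = self.cond.summary()
        if "exposure" in self.model.meta:
            out += "\n\nExposure lag response (contrast 1 vs 0):\n"
            out += self.lag_rr().to_string(float_format=lambda v: f"{v: .4f}")
        return out

    def plot_lag_rr(self, ax=None, contrast: float = 1.0):
        """Lag-RR curve with 95% CI bars (matplotlib)."""
        import matplotlib.pyplot as plt

        tbl = self.lag_rr(contrast=contrast)
        per_lag = tbl[tbl.index != "cumulative"]
        if ax is None:
            _, ax = plt.subplots()
        lags = np.arange(len(per_lag))
        ax.errorbar(
            lags,
            per_lag["rr"],
            yerr=[per_lag["rr"] - per_lag["rr_lo"], per_lag["rr_hi"] - per_lag["rr"]],
            fmt="o",
            capsize=3,
        )
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xlabel("lag (days)")
        ax.set_ylabel("rate ratio")
        return ax


def select_model(candidates, rows: pd.DataFrame, c_hat: float | None = None):
    """Fit every candidate ModelConfig and rank by qAIC.

    A common dispersion (from the candidate with the most parameters, the
    standard quasi-likelihood practice) scales every candidate's deviance;
    ties are broken by fewer parameters. Candidates that fail to fit are
    excluded with a warning; all failing is an error.

    Returns (best_config, table) where `table` has one row per candidate.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    fits = []
    for cfg in candidates:
        try:
            res = CaseCrossover(rows, cfg).fit()
            fits.append((cfg, res))
        except Exception as exc:  # noqa: BLE001 - candidate exclusion is the contract
            log.warning("candidate %s failed: %s", cfg, exc)
    if not fits:
        raise RuntimeError("all candidate models failed")
    if c_hat is None:
        richest = max(fits, key=lambda t: t[1].k_params)[1]
        c_hat = richest.pearson_dispersion()
    recs = []
    for cfg, res in fits:
        recs.append(
            {
                "exposure_var": getattr(cfg, "exposure_var", None),
                "lag_df": cfg.resolved_lag_df,
                "k": res.k_params,
                "llf": res.llf,
                "qaic": res.qaic(c_hat),
                "converged": res.converged,
            }
        )
    table = pd.DataFrame(recs)
    table["c_hat"] = c_hat
    order = np.lexsort((table["k"].to_numpy(), table["qaic"].to_numpy()))
    best_cfg = fits[order[0]][0]
    return best_cfg, table
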