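# Methods

This note documents the statistical machinery, the synthetic-data
generator, the numerical conventions, and the design choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design and likelihood

The analysis treats each county-day as a potential case day and compares
it to referent days from the same county, calendar year, month and day of
week (time-stratified referent selection; strata contain 4–5 days). With
Poisson daily counts and stratum-specific intercepts, conditioning on the
stratum outcome total Y_s turns the within-stratum counts into a
multinomial with probabilities softmax(x'β), so the conditional
log-likelihood is

    l(β) = Σ_i y_i η_i − Σ_s Y_s log Σ_{j∈s} exp(η_j) + Σ_s log( Y_s! / Π y_i! )

with η = Xβ. This conditioning removes all time-invariant county
confounding and seasonal/weekday structure by design. Strata whose
outcome total is zero, and strata with fewer than two assembled days,
contribute nothing and are dropped (counts logged). The maximizer equals
the stratum-dummy Poisson GLM estimate; the test suite verifies agreement
within 1e-6 against statsmodels' GLM on dozens of random datasets, keeping
the dummy fit as an independent oracle rather than the implementation.

**Optimization.** Newton–Raphson on the exact gradient X'(y − μ̃) and
observed information, where μ̃_i = Y_s·softmax_i; step-halving enforces a
monotone likelihood; convergence requires a relative log-likelihood change
≤ 1e-8 (max 200 iterations). Within-stratum log-sum-exp is max-shifted for
stability. The covariance is the inverse observed information
(model-based, matching the RR (95% CI) presentation; no sandwich
correction). Singular information (e.g., separation) falls back to a
pseudo-inverse and flags the fit as non-converged rather than failing
silently.

**Dispersion and qAIC.** ĉ is the Pearson statistic over the conditional
fitted means divided by residual df = n − (number of strata) − k, counting
the absorbed stratum intercepts. Model selection uses qAIC = −2·logL/ĉ +
2k with a common ĉ taken from the richest candidate (standard
quasi-likelihood practice; the source analyses do not state their
convention); ties break toward fewer parameters.

## Bases and the distributed lag structure

Natural cubic splines use the truncated-power construction with interior
knots at equally spaced quantiles and boundary knots at the data range;
the basis is linear beyond the boundaries. Two knot conventions coexist:

* **covariate use** (temperature value, precipitation, wind): no constant
  column, df columns, df − 1 interior knots — the R `splines::ns`
  convention;
* **lag use** (intercept included): df columns spanning the full natural
  spline space over lags 0–6 with df − 2 interior knots, so lag df 3/4/5
  corresponds to 1/2/3 interior knots.

Quantile knots that collide (zero-inflated precipitation, discrete hours)
are spread evenly over the data range instead. The cross-basis is the
tensor product Σ_l f_var(x_{t−l}) ⊗ f_lag(l); with lag df = 7 it reduces
exactly to the seven lagged exposure copies (verified in tests). Back-
transformation to per-lag effects uses the stored lag-basis rows and
value-basis knots: the log-RR at lag l for contrast x₁ vs x₀ is
(f(x₁) − f(x₀)) ⊗ C[l,·] · β, with delta-method variance from the fitted
covariance block; the cumulative log-RR sums the per-lag weights before
the quadratic form, so it is exactly the sum of per-lag log-RRs.

**Main-model design.** Binary 8-hour/≥1% exposure with lag df 5 (CVD) or
3 (respiratory); temperature as a 3-df value spline crossed with a 3-df
lag spline over lags 0–6 (the lag-dimension df for temperature is not
pinned down by the source design and is configurable); precipitation with
2 df (CVD) or linear (respiratory); wind with 3 df; optional smoke-day
indicator. A smoke column without variation is unidentified under
conditioning and is dropped with a warning.

**Interaction models.** Distributed-lag interactions are not attempted;
anomalous-temperature effect modification uses a single exposure lag (2
for CVD, 0 for respiratory — the lag with the largest main-analysis
effect), terms exposure + modifier + exposure×modifier, and replaces the
lagged temperature cross-basis (which would collinearly encode the
modifier) with a same-day 3-df temperature spline. Anomalous days require
both the county percentile threshold (85th/15th, linear-interpolation
percentiles over a reference series of at least 100 values) and the
absolute cutoff (strictly above 24 °C / strictly below 0 °C), so hot and
cold flags are mutually exclusive.

## Exposure construction

Customer denominators are proportional allocations of state customer
totals by county unit (households + establishments) shares, rounded;
zero-unit counties are flagged with estimate 0. Missingness handling:
missing runs of ≤ 4 hours are filled entirely by carrying the last
observation forward (leading gaps have no donor and become 0); longer
runs become 0 — the "no outage" value, the overwhelmingly most common
state — and a sensitivity mode zero-fills everything. Counties with more
than 50% of hours missing before imputation are excluded (20% in
sensitivity mode). An hour is "out" when customers_out / estimated
customers ≥ the threshold (closed comparison, ratio clamped at 1 so a
noisy denominator cannot crash the pipeline); a maximal run of ≥ 8 (or
4/12) consecutive out-hours marks every calendar day it touches as
exposed (run-start-only attribution is available). The continuous daily
hours-without-power metric always uses the 1% cut regardless of the
binary threshold in play. Timestamps are county-local clock hours; no
time-zone arithmetic is attempted.

## The synthetic generator

The generator emulates exactly the features the estimator relies on, with
all randomness drawn from per-component streams keyed off one seed:

* **Exposure occurrence** is a stationary two-state daily Markov chain
  solved from the target marginal prevalence p = 0.013 and lag-1
  autocorrelation ρ = 0.2 of the binary indicator: P(0→1) = p(1−ρ),
  P(1→1) = p + ρ(1−p); infeasible (p, ρ) pairs raise an error naming the
  feasible region ρ ∈ [−p/(1−p), 1]. The published autocorrelation does
  not state its scale; daily lag-1 is assumed. Each outage day carries one
  contiguous within-day run of 8 + capped-geometric (mean ≈ 12) hours with
  1.1–15% of customers out, so the 8h/1% rule recovers the chain state
  exactly; off-run hours hold occasional sub-threshold blips.
* **Missingness** arrives MCAR in blocks (start probability 0.02 per
  county-day, geometric mean 12 h ≈ 1% of hours), emulating
  utility-website downtime while keeping the null-bias behavior of
  zero-filling testable. Real retained feeds average ~7% missing hours;
  the default is kept light so the exposure-calibration targets describe
  the exposure process itself, with heavier missingness available as a
  config knob for sensitivity experiments.
* **Weather**: sinusoidal annual temperature cycle (county-specific mean
  and amplitude) plus AR(1) noise (φ = 0.6, σ = 3 °C); outage days are
  shifted −2 °C and +1.5 m/s wind, reproducing the observed
  colder-and-windier outage pattern; precipitation is zero-inflated
  exponential, wind gamma, smoke-days rare.
* **Counts** are Poisson with log-rate = county baseline (uniform log
  range ≈ 2–12 expected daily events; respiratory shifted down by the
  observed CVD/respiratory rate ratio) + county × month × weekday stratum
  effects (iid normal, σ = 0.15, centered within county — the calendar
  confounding the design must remove) + the distributed-lag exposure
  effect + a smooth lagged temperature effect. Lag histories before the
  window start are zero-padded (those days are dropped at assembly).
* **True effect curves** are projections of target shapes onto the fitted
  lag basis (anchored at lag 1 = 0.020 for CVD, lag 0 = 0.025 for
  respiratory), and the temperature effect uses a lag-weight profile in
  the lag-basis span — so the constrained model is correctly specified
  and recovery tests measure estimation error, not projection error.
  Claims expansion adds planned-type and position-6+ decoy records that
  the outcome filter must reject; tabulated claims round-trip to the
  original counts exactly.

What the generator does **not** emulate: spatial correlation between
counties, realistic ICD-10 code frequencies, enrollment dynamics,
planned-vs-unplanned outages, or exposure measurement error in the
customer denominators. Passing tests therefore demonstrate internal
statistical validity of the estimator under the assumed data-generating
structure, not robustness to those real-data features.

## Problem sizes and tolerances in the test battery

Chosen as the package's own balance of statistical resolution and
turnaround: calibration runs 500 counties × 365 days through the full
hourly pipeline (prevalence within ±0.2 percentage points of 1.3%, ρ
within ±0.05 of 0.2); type-I error uses 1,000 replicates of 60 counties ×
200 days (acceptance band 3.5–6.5% at the nominal 5%); recovery uses 500
replicates (mean lag-1 bias < 0.005, CI coverage 92–97%); run detection
is compared exhaustively with a brute-force window scan on 10,000 random
hourly series; the qAIC threshold test runs 200 replicates of the
8-candidate comparison. The continuous-hours scaling fixtures use
high-caseload counties (≈40–120 daily events) because a 0.1%-per-hour
effect is otherwise swamped by Poisson noise; the acceptance script runs
that check at 2,161 counties — the analysis's own county count — and its
reported 24-hour increases are Monte-Carlo estimates whose precision is
set by that size.

## Known limitations

* The attributable-count arithmetic exposes the hospitalization base and
  window ("outage_day" or "7_day") as explicit parameters; published
  excess-count figures are not reconstructible from printed inputs alone,
  so no specific base is hard-coded.
* Wald intervals throughout; no bootstrap or robust variance.
* Subgroup (age/sex/dual-eligibility/DME-quartile) analyses are fully
  stratified refits with their own dispersion, reusing the main-model lag
  df rather than re-selecting per subgroup.
* The conditional Poisson fit assumes within-stratum covariate variation;
  complete separation is flagged, not resolved.
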