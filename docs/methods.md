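# Methods

## The design and the estimator

`casecross` analyses short-term associations between daily ambient air
pollution and daily counts of emergency-department (ED) visits using a
time-stratified case-crossover design. Each calendar day is assigned to the
cluster of days sharing its year, month and day-of-week; within a calendar
month each weekday occurs 4 or 5 times, so clusters have size 4 or 5 and
never cross month boundaries. Comparing a day's exposure only with the other
days of its own cluster removes, by design, every confounder that is
constant within a cluster — long-term trends, seasonality at the monthly
scale, day-of-week patterns, and all time-invariant population
characteristics.

Counts `y_i` on day `i` in cluster `C` are modelled as Poisson with

    log mu_i = alpha_C + beta' x_i

where `x_i` holds the (lagged) exposure of interest and the weather terms.
Conditioning on the cluster total `N_C = sum_{i in C} y_i` eliminates the
`alpha_C` and yields a multinomial likelihood with cell probabilities

    pi_i = exp(beta' x_i) / sum_{j in C} exp(beta' x_j).

The package maximizes the resulting conditional log-likelihood

    l(beta) = sum_i y_i eta_i - sum_C N_C log sum_{j in C} exp(eta_j)

directly (analytic gradient and Hessian; the beta-free multinomial
coefficient is dropped). This conditional fit is numerically identical to an
unconditional Poisson fit with one fixed-effect indicator per cluster — the
test suite verifies the identity against an independent fixed-effects fit to
1e-6, including exhaustively over all two-cluster binary-exposure designs
with daily counts up to 3 (designs with separated or empty clusters have no
interior maximum and are excluded).

Overdispersion is handled quasi-Poisson style: the Pearson statistic over
days in clusters with a positive total, divided by `n - K - p` (days minus
clusters minus regression parameters — the residual degrees of freedom of
the equivalent fixed-effects fit), scales the model-based variance, so
standard errors are `sqrt(dispersion) ×` the information-based ones. Days in
clusters whose total count is zero contribute nothing to the conditional
likelihood; they are retained in the data but are inert.

Effect sizes are reported as relative risks per interquartile-range (IQR)
increment: `RR = exp(beta × IQR)` with Wald confidence limits
`exp((beta ± z·SE) × IQR)`, two-tailed at the 0.05 level. A model counts as
a *significant positive association* when the lower 95% limit exceeds 1. The
IQR is computed from the all-days exposure series (the study-period IQR),
not per stratum; a config switch (`per_stratum_iqr`) flips this.

## Exposure metrics

Eight exposure metrics enter the grid: CO (ppm), NO2, SO2, O3 (ppb), PM2.5
(µg/m³), O3H8 (daily maximum 8-hour ozone mean, ppb), and two composite
indices. The Air Quality Health Index is

    AQHI = 1000/10.4 × (e^{0.000537·O3} + e^{0.000871·NO2} + e^{0.000487·PM2.5} − 3)

with 24-h mean inputs; AQHI-x substitutes O3H8 for O3, weighting daytime
ozone peaks more heavily. The coefficients are the published
mortality-derived constants and are frozen (overridable only through
configuration). Models use the continuous index; the public 1–10+ reporting
scale is provided for presentation only. The index is strictly increasing in
each input, zero at the origin, and within typical operating ranges (means ±
one IQR) is nearly linear — within 0.05 index units of its tangent plane at
the mean conditions; near the extreme corners of the observed ranges the
curvature grows to roughly 0.13 units, so linearity is a local, not global,
approximation.

Aggregation conventions (all configurable):

* **24-h means** require at least 75% of hours (18 of 24) per station-day;
  days below threshold are missing, never zero-filled.
* **O3H8** is the maximum of complete forward-looking 8-h windows. Default
  policy confines windows to the day (start hours 0–16); a `cross_midnight`
  policy allows start hours 0–23 with next-day spillover. Monitoring
  guidance varies on this point; both are implemented and the choice is
  explicit.
* **Station averaging** is an unweighted mean over stations reporting that
  day, missing when fewer than `min_stations` report.
* **Percentiles** (for IQRs and spline knots) use linear interpolation
  between order statistics; pinned because IQR-scaled RRs inherit it.
* Negative measured concentrations (instrument noise near the detection
  limit) pass through unmodified.

## Strata, outcomes and lags

Eighteen analysis strata: 3 sex groups (all/M/F) crossed with either the
all-ages-all-seasons cell, 3 age groups (0–10, 11–60, >60 — the top group
taken as age ≥ 61; switching to ≥ 60 is a one-line change in `age_group`),
or 2 seasons (cold = October–March, warm = April–September). Age and season
never cross. Season strata restrict the analysis days themselves — safe
because clusters are month-bound and every month is wholly cold or warm.

Outcomes are ICD-10 chapter VI (G00–G99) visits, grouped into the 11
standard blocks; codes in the chapter's undefined gaps (e.g. G15–G19) are
outside every block. Episodic/paroxysmal sub-codes (G40/G41, G43, G44, G45,
G47) carry descriptive tags. Lags run 0–14 days, single-lag (no distributed
lag structure); day *t*'s outcome is paired with exposure *and weather* from
day *t − lag*.

With 8 exposures × 15 lags × 18 strata the grid holds 2,160 models per
outcome block. Grid failures (non-identifiable or non-converged cells) are
recorded as rows, never dropped. No multiple-testing adjustment is applied
by default, matching common practice in this literature; a
Benjamini–Hochberg column is available behind `bh_adjust=True`.

## Weather adjustment

Temperature and relative humidity each enter through a natural cubic spline
with 3 degrees of freedom: truncated-power natural basis, boundary knots at
the subset's min/max, interior knots at its 33.3rd/66.7th percentiles.
Bases are computed per fitted subset (so season strata get season-specific
knots); a `global_spline_basis` switch uses all-days quantiles instead. The
basis is exactly linear beyond the boundary knots and, with an intercept,
spans the natural cubic splines on its knots (verified against an
independent natural-boundary cubic interpolant).

## Numerical choices

* Newton iteration from `beta = 0` (the objective is concave, so the start
  is benign), with per-cluster log-sum-exp stabilization and step-halving;
  convergence at gradient max-norm < 1e-8.
* Design columns are rescaled to unit max-magnitude internally (spline
  columns are cubic-scale and reach thousands); estimates and covariances
  are mapped back afterwards. Without this the stated tolerance is not
  reachable in double precision.
* An exposure constant within every cluster raises a non-identifiability
  error rather than returning a silent zero.
* Dispersion is reported as NaN when the residual df is non-positive (tiny
  designs); the coefficient estimate is still valid.

The convergence tolerance and knot rule are implementation conventions,
documented here, not facts inherited from any particular study.

## The synthetic-data generator

Record-level ED surveillance data are confidential, so the pipeline is
exercised end-to-end on synthetic data with exactly the structure the
estimator assumes:

* **Exposure and weather series** — stationary mean + annual sinusoid
  (period 365.25 d) + AR(1) noise, optionally floor-clipped. Defaults
  emulate the Toronto 2004–2015 daily descriptives (e.g. CO mean 0.3 ppm,
  NO2 16.1 ppb, O3 23.5 ppb, PM2.5 8.9 µg/m³, temperature mean 9.5 °C with
  a ±12.5 °C seasonal swing). O3H8 is simulated as its own daily series
  (mean 43.7 ppb) rather than derived from hourly data — hourly simulation
  is deliberately out of scope, and daily resolution suffices to test the
  estimator. AQHI/AQHI-x are derived from the simulated components.
* **Counts** — per disjoint sex × age cell, negative binomial with mean
  `mu_t` and variance `overdispersion × mu_t` (exactly Poisson at 1),
  where `log mu_t` contains the cell baseline, an i.i.d. normal cluster
  intercept (sd 0.1 by default — present precisely so tests can verify the
  design ignores it), the configured lagged exposure effects, and a smooth
  quadratic of standardized temperature and humidity. Overdispersion
  defaults to 1.5, a mild, realistic inflation chosen once (published
  city-level analyses do not report their dispersion). The baseline rate
  defaults to 32.7 visits/day, the Toronto study-period average, split
  across cells by the published sex × age shares.
* **Records** — counts are disaggregated into individual visits with exact
  age uniform within the cell's range and ICD-10 codes drawn from weights
  following the published block frequencies. True effects are keyed by
  (exposure, lag) with an optional sex restriction; because counts live on
  disjoint cells, overlapping strata (all = M + F) stay consistent by
  construction.

What the generator does **not** emulate: station-level spatial structure,
hourly dynamics, exposure measurement error, weather–pollution dependence
(simulated weather is independent of pollutants, so weather is a precision
variable, not a confounder), long-term outcome trends beyond the seasonal
cycle, and within-day visit timing. Passing tests therefore demonstrate
estimator correctness under the assumed model — unbiased slope recovery,
honest CIs, correct dispersion — not robustness to the messiness of real
surveillance data.

## Calibration experiments (test suite)

The statistical tests run the complete pipeline (simulate → records →
counts → lagged design → conditional fit):

* **Recovery/coverage** — 200 replicates of 731 days at ~25 visits/day with
  a true CO slope of 0.19/ppm at lag 1 (RR ≈ 1.019 per 0.1 ppm, the scale
  of reported city-level findings), overdispersion 1.5: the mean estimate
  must sit within 3 Monte-Carlo SEs of the truth and 95% CI coverage within
  [92%, 98%].
* **Type-I error** — 400 null replicates of 500 days: the
  significant-positive rate must lie within a 3σ binomial band around 2.5%
  (and the negative rate likewise).
* **Dispersion** — 40 replicates each: Poisson data must give mean
  dispersion ≈ 1, variance-inflation-2 data ≈ 2.

Replicate counts and series lengths were chosen as the smallest sizes at
which the Monte-Carlo bands above are meaningful.

## Known limitations

* Single-lag models only; no distributed-lag nonlinear structures.
* Wald intervals with quasi-Poisson scaling; no sandwich or bootstrap
  alternatives.
* The public AQHI rounding scale is implemented for display but never
  modelled; modelling it would discard information.
* The exhaustive estimator-equivalence check covers two-cluster binary
  designs; larger designs are checked by random spot tests, not
  enumeration.
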