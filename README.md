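# casecross

Time-stratified case-crossover analysis of ambient air pollution and
emergency-department (ED) visits.

`casecross` is a Python library for epidemiologists analysing short-term
associations between daily pollutant concentrations and daily counts of
ED visits (here, nervous-system diagnoses, ICD-10 G00–G99). It implements
the full analytical chain of a single-city daily time-series study:

* **Exposure aggregation** — station-level hourly records → city-wide daily
  series: 24-h means with completeness rules, daily maximum 8-h ozone
  (O3H8), cross-station averaging, and the composite Air Quality Health
  Index
  `AQHI = 1000/10.4 × (e^{0.000537·O3} + e^{0.000871·NO2} + e^{0.000487·PM2.5} − 3)`
  plus its AQHI-x variant (O3H8 in place of 24-h O3).
* **Study design** — year × month × day-of-week referent clusters (size 4
  or 5), 18 sex × age / sex × season strata, ICD-10 block coding,
  zero-filled daily counts, and single-day lagged exposure assignment
  (lags 0–14).
* **Estimation** — conditional quasi-Poisson regression: cluster intercepts
  are eliminated by conditioning on cluster totals, giving the multinomial
  likelihood `π_i = exp(β'x_i) / Σ_{j∈C} exp(β'x_j)`; temperature and
  humidity enter as natural cubic splines (3 df); a Pearson dispersion
  factor scales the variance; effects are reported as `RR = exp(β × IQR)`
  with 95% Wald limits.
* **Model grid** — the full 8 exposures × 15 lags × 18 strata = 2,160-model
  array, summarized as counts of significant positive associations per
  stratum/exposure/lag.
* **Synthetic data** — a generator producing seasonal AR(1) exposure and
  weather series and overdispersed, cluster-structured visit records, so
  the whole pipeline is testable without confidential surveillance data.

See `docs/methods.md` for the statistical details and conventions.

## Worked example

Simulate three years with a known CO effect at lag 1 and recover it
(`examples/fit_single_model.py`):

```sh
$ python examples/fit_single_model.py
true slope 0.19/ppm; estimate 0.197 (SE 0.069), dispersion 1.41, 253 clusters
RR per IQR (0.138 ppm CO): 1.028 (95% CI 1.008-1.047)
```

The generator planted a log-rate slope of 0.19 per ppm of CO lagged one
day; the conditional fit recovers 0.197 with a standard error of 0.069 —
well within sampling error — and the Pearson dispersion (1.41) reflects the
generator's variance inflation of 1.5. The relative risk is scaled to this
dataset's CO interquartile range (0.138 ppm): a 1.028-fold visit-rate
increase per IQR, with a confidence interval excluding 1.

Other examples, one per capability, live in `examples/`: index
construction (`compute_aqhi_index.py`), hourly→daily aggregation
(`aggregate_hourly.py`), dataset simulation and descriptive summaries
(`simulate_and_describe.py`), and a reduced model grid with association
counts (`run_reduced_grid.py`).

A thin CLI mirrors the pipeline stages for shell use:

```sh
casecross simulate --seed 4 --outdir out
casecross design --visits out/visits.csv --out out/counts.csv
casecross grid --counts out/counts.csv --exposures out/daily_exposures.csv \
    --exposure CO --exposure AQHI --max-lag 5 --outdir out
casecross summarize --results out/grid_results.csv --outdir out
```

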