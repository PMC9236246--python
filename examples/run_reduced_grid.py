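"""Run a reduced model grid and count significant positive associations.

The full analysis runs 8 exposures x 15 lags x 18 strata = 2,160 models;
this example runs a 2 x 5 x 3 slice on three simulated years carrying one
true effect (CO at lag 1) and prints the association-count arrays that
the full analysis renders as heatmaps.
"""

import pandas as pd

import casecross as cc
from casecross.design import StratumSpec, build_counts
from casecross.grid import enumerate_models, run_grid, significance_counts

params = cc.SimulationParams(
    n_days=1096, seed=21, true_effects=(cc.Effect("CO", 1, 0.19),)
)
ds = cc.simulate(params)
end = pd.Timestamp(params.start_date) + pd.Timedelta(days=params.n_days - 1)
counts = build_counts(ds.visits, params.start_date, end)

strata = [StratumSpec(), StratumSpec(sex="F"), StratumSpec(sex="M")]
specs = enumerate_models(exposures=("CO", "NO2"), lags=range(5), strata=strata,
                         blocks=("G00-G99",))
results = run_grid(specs, counts, ds.combined_daily())

arrays = significance_counts(results)
print(f"ran {len(results)} models; {arrays.total} significant positive associations\n")
print("exposures x lags:")
print(arrays.by_exposure_lag.to_string())
print("\nstrata x exposures:")
print(arrays.by_stratum_exposure.to_string())
print("\nCells count models whose lower 95% CI (RR per IQR) exceeds 1; the")
print("simulated effect should concentrate the flags in the CO lag-1 column.")
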