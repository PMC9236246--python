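"""Aggregate station-level hourly measurements into city-wide daily values.

Builds a tiny two-station, two-day hourly ozone table in memory, computes
per-station 24-h means and the daily maximum 8-h average (O3H8), then the
unweighted cross-station daily mean — the chain that turns raw monitoring
records into the exposure series the models use.
"""

import numpy as np
import pandas as pd

from casecross.exposure import average_stations, daily_max_8h, daily_mean_24h

rng = np.random.default_rng(0)
rows = []
for station, level in (("S1", 25.0), ("S2", 31.0)):
    for day in ("2010-06-01", "2010-06-02"):
        ts = pd.date_range(day, periods=24, freq="h")
        diurnal = level + 12 * np.clip(np.sin(np.pi * (ts.hour.to_numpy() - 6) / 18), 0, None)
        rows.append(pd.DataFrame({
            "station_id": station, "timestamp": ts, "pollutant": "O3",
            "value": diurnal + rng.normal(0, 1, 24),
        }))
hourly = pd.concat(rows, ignore_index=True)

per_station = daily_mean_24h(hourly, completeness_min=0.75)
print("per-station 24-h means:")
print(per_station.round(2).to_string(index=False))

s1 = hourly[hourly["station_id"] == "S1"].set_index("timestamp")["value"]
o3h8 = daily_max_8h(s1, "2010-06-01")
print(f"\nS1 2010-06-01 daily max 8-h mean: {o3h8:.2f} ppb "
      "(>= the 24-h mean by construction)")

citywide = average_stations(per_station[per_station["pollutant"] == "O3"],
                            min_stations=2)
print("\ncity-wide daily O3 (mean of stations reporting, min 2):")
print(citywide.round(2).to_string())
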