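"""City-wide daily exposure metrics and composite air-quality indices.

Turns station-level hourly pollutant measurements into the daily exposure
series the case-crossover models consume: per-station 24-h means, the daily
maximum 8-h ozone average (O3H8), unweighted cross-station averages, the
Canadian Air Quality Health Index (AQHI, built from 24-h mean O3, NO2 and
PM2.5) and its AQHI-x variant (same formula fed O3H8), and seasonal
descriptive summaries with interquartile ranges.

Units are the monitoring network's native ones throughout: ppm for CO, ppb
for NO2, SO2 and O3, and ug/m3 for PM2.5. Negative measured concentrations
(instrument noise near the detection limit) are retained and pass through
means and the index exponentials unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

POLLUTANTS = ("CO", "NO2", "SO2", "PM2.5", "O3")
#: Exposure metrics entering the model grid (pollutants plus derived indices).
EXPOSURE_COLUMNS = ("CO", "NO2", "SO2", "PM2.5", "O3", "O3H8", "AQHI", "AQHI-x")


@dataclass(frozen=True)
class AqhiCoefficients:
    """Frozen constants of the published AQHI formula.

    index = scale * (exp(c_o3 * O3) + exp(c_no2 * NO2) + exp(c_pm25 * PM2.5) - offset)

    with O3 and NO2 in ppb and PM2.5 in ug/m3. The defaults are the published
    mortality-derived coefficients; override only through configuration.
    """

    scale: float = 1000.0 / 10.4
    c_o3: float = 0.000537
    c_no2: float = 0.000871
    c_pm25: float = 0.000487
    offset: float = 3.0


DEFAULT_AQHI = AqhiCoefficients()


def compute_aqhi(o3, no2, pm25, coef: AqhiCoefficients = DEFAULT_AQHI):
    """Continuous AQHI from 24-h mean O3 (ppb), NO2 (ppb) and PM2.5 (ug/m3).

    Vectorized; any missing input yields a missing output. The continuous
    value is what enters the regression models. Feeding the daily maximum
    8-h ozone average instead of the 24-h mean yields AQHI-x.

    The index is strictly increasing in each argument and equals 0 at
    (0, 0, 0).
    """
    o3 = np.asarray(o3, dtype=float)
    no2 = np.asarray(no2, dtype=float)
    pm25 = np.asarray(pm25, dtype=float)
    out = coef.scale * (
        np.exp(coef.c_o3 * o3)
        + np.exp(coef.c_no2 * no2)
        + np.exp(coef.c_pm25 * pm25)
        - coef.offset
    )
    if out.ndim == 0:
        return float(out)
    return out


def aqhi_presentation_scale(value):
    """Round a continuous AQHI to the public 1-10+ reporting scale.

    Values round to the nearest integer, floor 1; anything above 10 is
    reported as the single "10+" category, encoded here as 11. This scale
    is presentation-only and is never used in the models.
    """
    v = np.asarray(value, dtype=float)
    out = np.clip(np.rint(v), 1, 11)
    out = np.where(np.isnan(v), np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def daily_mean_24h(records: pd.DataFrame, completeness_min: float = 0.75) -> pd.DataFrame:
    """Per-station, per-pollutant daily means from hourly records.

    Parameters
    ----------
    records : DataFrame
        Columns ``station_id``, ``timestamp`` (datetime-like, local hour),
        ``pollutant``, ``value``. Missing hourly values may be absent rows
        or NaN values; both count as unavailable.
    completeness_min : float in (0, 1]
        Minimum fraction of the 24 hours that must be available for the day
        to be valid; with the 0.75 default a day needs at least 18 hourly
        values. Days below the threshold are returned as NaN, not dropped.

    Returns
    -------
    DataFrame with columns station_id, pollutant, date, value.

    Raises
    ------
    ValueError
        If (station_id, pollutant, timestamp) contains duplicates (listed
        in the message), or completeness_min is outside (0, 1].
    """
    if not 0 < completeness_min <= 1:
        raise ValueError(f"completeness_min must be in (0, 1], got {completeness_min}")
    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    dup = df.duplicated(subset=["station_id", "pollutant", "timestamp"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["station_id", "pollutant", "timestamp"]].drop_duplicates()
        raise ValueError(
            "duplicate hourly records for (station, pollutant, timestamp):\n"
            + offenders.to_string(index=False)
        )
    df["date"] = df["timestamp"].dt.normalize()
    grouped = df.groupby(["station_id", "pollutant", "date"], sort=True)["value"]
    agg = grouped.agg(value="mean", n_hours="count")
    agg.loc[agg["n_hours"] / 24.0 < completeness_min, "value"] = np.nan
    return agg.reset_index()[["station_id", "pollutant", "date", "value"]]


def daily_max_8h(
    hourly: pd.Series,
    date,
    window_policy: str = "within_day",
) -> float:
    """Daily maximum 8-hour mean ozone for one calendar day.

    Computes forward-looking 8-h running means and returns their maximum.
    Under the default ``"within_day"`` policy the window must lie entirely
    inside the day (start hours 0-16); under ``"cross_midnight"`` the start
    hour may be any of 0-23, drawing the spillover hours from the next day's
    data when present in ``hourly``. Only complete 8-hour windows count; if
    none is complete the value is missing (NaN), not an error.

    Parameters
    ----------
    hourly : Series
        Hourly concentrations indexed by timestamp; must cover the target
        day and, for the cross-midnight policy, the first 7 hours of the
        next day if available.
    date : date-like
        The calendar day whose O3H8 is wanted.
    """
    if window_policy not in ("within_day", "cross_midnight"):
        raise ValueError(f"unknown window_policy: {window_policy!r}")
    day = pd.Timestamp(date).normalize()
    start_hours = range(17) if window_policy == "within_day" else range(24)
    s = hourly.copy()
    s.index = pd.to_datetime(s.index)
    best = np.nan
    for h in start_hours:
        t0 = day + pd.Timedelta(hours=h)
        window = s.reindex(pd.date_range(t0, periods=8, freq="h"))
        if window.notna().sum() == 8:
            m = float(window.mean())
            if np.isnan(best) or m > best:
                best = m
    return best


def average_stations(per_station_daily: pd.DataFrame, min_stations: int = 1) -> pd.Series:
    """Unweighted cross-station mean per day.

    ``per_station_daily`` is wide (one column per station, one row per day)
    or the long output of :func:`daily_mean_24h` restricted to one pollutant
    (columns station_id, date, value). Days on which fewer than
    ``min_stations`` stations report are missing — missingness is data here,
    not an error.
    """
    if min_stations < 1:
        raise ValueError("min_stations must be >= 1")
    if {"station_id", "date", "value"}.issubset(per_station_daily.columns):
        wide = per_station_daily.pivot(index="date", columns="station_id", values="value")
    else:
        wide = per_station_daily
    mean = wide.mean(axis=1)
    n = wide.notna().sum(axis=1)
    return mean.where(n >= min_stations)


def compute_iqr(series) -> float:
    """Interquartile range (75th minus 25th percentile) of a daily series.

    Uses linear interpolation between order statistics — the convention is
    pinned because IQR-scaled relative risks depend on it. Missing values
    are ignored; fewer than 4 non-missing values is an error.
    """
    values = np.asarray(pd.Series(series).dropna(), dtype=float)
    if values.size < 4:
        raise ValueError(f"need >= 4 non-missing values for an IQR, got {values.size}")
    q25, q75 = np.percentile(values, [25, 75], method="linear")
    return float(q75 - q25)


def exposure_summary(daily: pd.DataFrame, season: pd.Series | None = None) -> pd.DataFrame:
    """Descriptive summary (mean, min, max, IQR) per exposure and season.

    ``daily`` holds one column per exposure metric, indexed by date. If
    ``season`` (a per-day cold/warm label) is given, per-season rows are
    added alongside the all-months rows.
    """
    frames = {"all": daily}
    if season is not None:
        for name in ("cold", "warm"):
            frames[name] = daily.loc[np.asarray(season) == name]
    rows = []
    for season_name, frame in frames.items():
        for col in frame.columns:
            s = frame[col].dropna()
            if s.empty:
                continue
            rows.append(
                {
                    "exposure": col,
                    "season": season_name,
                    "mean": s.mean(),
                    "min": s.min(),
                    "max": s.max(),
                    "iqr": compute_iqr(s) if s.size >= 4 else np.nan,
                }
            )
    return pd.DataFrame(rows)
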