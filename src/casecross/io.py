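"""Delimited-table readers and writers.

One interchange dialect everywhere: CSV with a header row, ISO-8601 dates,
UTF-8, empty cell = missing. Row-level validation failures are collected
and logged with line numbers rather than aborting the whole read; structural
problems (missing columns, duplicate hourly timestamps, unparseable dates)
are errors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exposure import POLLUTANTS

log = logging.getLogger(__name__)

VISIT_COLUMNS = ("date", "icd10", "sex", "age")

#: native measurement unit per pollutant column
POLLUTANT_UNITS = {
    "CO": "ppm",
    "NO2": "ppb",
    "SO2": "ppb",
    "O3": "ppb",
    "O3H8": "ppb",
    "PM2.5": "ug/m3",
}


class ValidationError(ValueError):
    """A structural problem in an input table."""


def read_visits(path, return_report: bool = False):
    """Read ED visit records from a delimited table.

    Required columns: date, icd10, sex (M/F), age. Rows failing row-level
    validation (bad date, sex outside {M, F}, negative or non-numeric age,
    empty code) are dropped with a logged warning naming their line
    numbers; a missing required column is an error.

    Returns the valid records as a DataFrame (date parsed, age float);
    with ``return_report=True`` also returns a DataFrame describing the
    rejected rows.
    """
    df = pd.read_csv(path, dtype={"icd10": str, "sex": str})
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"visit table {path} is missing column(s): {missing}")

    problems = []
    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    ages = pd.to_numeric(df["age"], errors="coerce")
    for idx in df.index:
        line = idx + 2  # header is line 1
        if pd.isna(dates[idx]):
            problems.append((line, f"unparseable date {df.at[idx, 'date']!r}"))
        elif df.at[idx, "sex"] not in ("M", "F"):
            problems.append((line, f"sex must be M or F, got {df.at[idx, 'sex']!r}"))
        elif pd.isna(ages[idx]) or ages[idx] < 0:
            problems.append((line, f"invalid age {df.at[idx, 'age']!r}"))
        elif not isinstance(df.at[idx, "icd10"], str) or not df.at[idx, "icd10"].strip():
            problems.append((line, "empty ICD-10 code"))
    bad_lines = {line for line, _ in problems}
    keep = ~df.index.isin({line - 2 for line in bad_lines})
    out = pd.DataFrame(
        {
            "date": dates[keep],
            "icd10": df.loc[keep, "icd10"].str.strip(),
            "sex": df.loc[keep, "sex"],
            "age": ages[keep],
        }
    ).reset_index(drop=True)
    if problems:
        log.warning(
            "%s: rejected %d of %d rows: %s",
            path,
            len(problems),
            len(df),
            "; ".join(f"line {line}: {msg}" for line, msg in problems[:10]),
        )
    report = pd.DataFrame(problems, columns=["line", "reason"])
    return (out, report) if return_report else out


def write_visits(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_exposures(path, kind: str, expected_units: dict | None = None):
    """Read an hourly or daily exposure table.

    ``kind="hourly"``: long table with columns station_id, timestamp,
    pollutant, value and optionally units; duplicate (station, pollutant,
    timestamp) rows and unparseable timestamps are errors; a units column
    that contradicts ``expected_units`` (defaulting to the native units) is
    an error.

    ``kind="daily"``: wide table with a date column and one column per
    exposure/weather metric; empty cells stay missing (NaN), never zero.
    Returned date-indexed.
    """
    if kind not in ("hourly", "daily"):
        raise ValueError(f"kind must be 'hourly' or 'daily', got {kind!r}")
    df = pd.read_csv(path)
    if kind == "hourly":
        required = ["station_id", "timestamp", "pollutant", "value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"hourly table {path} is missing column(s): {missing}")
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
        if ts.isna().any():
            bad = df.loc[ts.isna(), "timestamp"].head().tolist()
            lines = (np.flatnonzero(ts.isna()) + 2).tolist()
            raise ValidationError(
                f"{path}: unparseable timestamp(s) at line(s) {lines[:5]}: {bad}"
            )
        df["timestamp"] = ts
        dup = df.duplicated(subset=["station_id", "pollutant", "timestamp"], keep=False)
        if dup.any():
            raise ValidationError(
                f"{path}: duplicate (station, pollutant, timestamp) rows at lines "
                f"{(np.flatnonzero(dup) + 2).tolist()[:10]}"
            )
        units = expected_units or POLLUTANT_UNITS
        if "units" in df.columns:
            declared = df.drop_duplicates(["pollutant", "units"])[["pollutant", "units"]]
            for _, row in declared.iterrows():
                want = units.get(row["pollutant"])
                if want is not None and row["units"] != want:
                    raise ValidationError(
                        f"{path}: pollutant {row['pollutant']} declared in "
                        f"{row['units']!r}, expected {want!r}"
                    )
        return df[["station_id", "timestamp", "pollutant", "value"]]

    if "date" not in df.columns:
        raise ValidationError(f"daily table {path} is missing the 'date' column")
    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    if dates.isna().any():
        lines = (np.flatnonzero(dates.isna()) + 2).tolist()
        raise ValidationError(f"{path}: unparseable date(s) at line(s) {lines[:5]}")
    out = df.drop(columns=["date"]).apply(pd.to_numeric, errors="coerce")
    out.index = pd.DatetimeIndex(dates.to_numpy())
    return out


def write_daily_exposures(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.insert(0, "date", pd.DatetimeIndex(out.index).strftime("%Y-%m-%d"))
    out.to_csv(path, index=False)


def write_results(results: pd.DataFrame, path) -> None:
    """Write the long-format grid result table (one row per model)."""
    results.to_csv(path, index=False)
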