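"""Published Toronto 2004-2015 descriptive tables, bundled as reference data.

These are the printed summary statistics of the Toronto nervous-system ED
visit study period (April 1, 2004 - December 31, 2015): visit counts by
sex, age group, season and diagnostic block, and daily pollutant / weather
descriptives. They serve as fixed inputs for worked examples and for
checking the package's descriptive machinery against published arithmetic;
the underlying record-level surveillance data are confidential and are
emulated by :mod:`casecross.simulate`.

Note the printed block-frequency table totals 140,514 while the
sex/age/season table totals 140,511 (a 3-visit discrepancy in the source
tables); shares are computed against each table's own total.
"""

from __future__ import annotations

import pandas as pd

#: Visit counts by sex (totals row included).
VISITS_BY_SEX = {"all": 140_511, "M": 56_909, "F": 83_602}

#: Visit counts by sex x age group.
VISITS_BY_SEX_AGE = {
    ("M", "0-10"): 2_314,
    ("F", "0-10"): 1_978,
    ("M", "11-60"): 36_177,
    ("F", "11-60"): 57_456,
    ("M", ">60"): 18_418,
    ("F", ">60"): 24_168,
}

#: Visit counts by season.
VISITS_BY_SEASON = {"cold": 67_631, "warm": 72_880}

#: Visit counts per diagnostic block (with episodic/paroxysmal sub-codes).
VISITS_BY_BLOCK = {
    "G00-G09": 1_913,
    "G10-G14": 472,
    "G20-G26": 4_075,
    "G30-G32": 1_704,
    "G35-G37": 1_816,
    "G40-G47": 89_708,
    "G50-G59": 30_607,
    "G60-G64": 3_436,
    "G70-G73": 889,
    "G80-G83": 1_244,
    "G90-G99": 4_650,
}
BLOCK_TABLE_TOTAL = 140_514

VISITS_G40_G47_SUBCODES = {
    "epilepsy (G40-G41)": 18_670,
    "migraine (G43)": 34_864,
    "other headache syndromes (G44)": 8_159,
    "transient ischaemic attacks (G45)": 21_914,
    "sleep disorders (G47)": 6_101,
}

#: All-months daily means and IQRs for exposures and weather.
POLLUTANT_MEANS = {
    "PM2.5": 8.9,  # ug/m3
    "NO2": 16.1,  # ppb
    "O3": 23.5,  # ppb
    "O3H8": 43.7,  # ppb
    "SO2": 1.4,  # ppb
    "CO": 0.3,  # ppm
    "AQHI": 3.0,
    "AQHI-x": 4.4,
    "temperature": 9.5,  # degC
    "humidity": 70.7,  # %
}

POLLUTANT_IQRS = {
    "PM2.5": 6.5,
    "NO2": 8.8,
    "O3": 12.8,
    "O3H8": 19.0,
    "SO2": 1.2,
    "CO": 0.1,
    "AQHI": 1.0,
    "AQHI-x": 1.5,
    "temperature": 16.7,
    "humidity": 14.3,
}


def percent_share(part: float, whole: float, decimals: int = 1) -> float:
    """Percentage share rounded to the printed precision."""
    return round(100.0 * part / whole, decimals)


def visit_shares() -> dict:
    """Headline descriptive shares recomputed from the bundled counts."""
    return {
        "female_share": percent_share(VISITS_BY_SEX["F"], VISITS_BY_SEX["all"]),
        "cold_season_share": percent_share(
            VISITS_BY_SEASON["cold"], VISITS_BY_SEX["all"]
        ),
        "episodic_paroxysmal_share": percent_share(
            VISITS_BY_BLOCK["G40-G47"], BLOCK_TABLE_TOTAL
        ),
        "migraine_share_of_block": percent_share(
            VISITS_G40_G47_SUBCODES["migraine (G43)"], VISITS_BY_BLOCK["G40-G47"]
        ),
    }


def block_table() -> pd.DataFrame:
    """Diagnostic-block counts with percentage shares, as a DataFrame."""
    df = pd.DataFrame(
        {"block": list(VISITS_BY_BLOCK), "count": list(VISITS_BY_BLOCK.values())}
    )
    df["share_pct"] = [percent_share(c, BLOCK_TABLE_TOTAL) for c in df["count"]]
    return df
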