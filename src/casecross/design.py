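"""Case-crossover study skeleton.

The time-stratified case-crossover design compares each event day's exposure
with the exposure on referent days sharing its year, month and day-of-week.
Those referent sets partition the calendar into non-overlapping clusters of
4 or 5 days; conditioning on each cluster's total visit count later removes
every cluster-constant confounder.

This module builds that skeleton: season labels, ICD-10 outcome blocks for
nervous-system diagnoses (G00-G99), the 18 sex-by-age / sex-by-season
analysis strata, the calendar clusters, zero-filled daily count series per
stratum and outcome block, and lagged exposure assignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

COLD_MONTHS = frozenset({10, 11, 12, 1, 2, 3})

SEXES = ("all", "M", "F")
AGE_GROUPS = ("0-10", "11-60", ">60")
SEASONS = ("cold", "warm")

#: ICD-10 chapter-VI blocks: (low, high) numeric prefix ranges, inclusive.
ICD_BLOCKS = {
    "G00-G09": (0, 9),
    "G10-G14": (10, 14),
    "G20-G26": (20, 26),
    "G30-G32": (30, 32),
    "G35-G37": (35, 37),
    "G40-G47": (40, 47),
    "G50-G59": (50, 59),
    "G60-G64": (60, 64),
    "G70-G73": (70, 73),
    "G80-G83": (80, 83),
    "G90-G99": (90, 99),
}

WHOLE_CHAPTER = "G00-G99"

#: Episodic/paroxysmal sub-codes tagged individually in the descriptive tables.
SUBCODE_TAGS = {
    40: "epilepsy",
    41: "epilepsy",
    43: "migraine",
    44: "other headache syndromes",
    45: "transient ischaemic attacks",
    47: "sleep disorders",
}

_ICD_RE = re.compile(r"^([A-Z])(\d{2})(?:\.?\d+)?$")


def classify_season(date) -> str:
    """Dichotomous season: cold (October-March) or warm (April-September)."""
    month = pd.Timestamp(date).month
    return "cold" if month in COLD_MONTHS else "warm"


def season_labels(index: pd.DatetimeIndex) -> pd.Series:
    """Vectorized :func:`classify_season` over a calendar index."""
    cold = pd.Index(index).month.isin(list(COLD_MONTHS))
    return pd.Series(np.where(cold, "cold", "warm"), index=index)


class IcdBlockResult(NamedTuple):
    block: str
    tag: str | None


def icd_block(code: str) -> IcdBlockResult | None:
    """Map an ICD-10 code to its nervous-system outcome block.

    Codes outside chapter VI (not starting with G) or falling in the
    chapter's undefined gaps (e.g. G15-G19) map to ``None``. In-block
    episodic/paroxysmal sub-codes carry a descriptive tag (G40/G41
    epilepsy, G43 migraine, G44 other headaches, G45 transient ischaemic
    attacks, G47 sleep disorders).

    Raises
    ------
    ValueError
        For malformed codes (empty, wrong shape, non-numeric).
    """
    if not isinstance(code, str):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    m = _ICD_RE.match(code.strip().upper())
    if m is None:
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    letter, digits = m.group(1), int(m.group(2))
    if letter != "G":
        return None
    for block, (lo, hi) in ICD_BLOCKS.items():
        if lo <= digits <= hi:
            return IcdBlockResult(block, SUBCODE_TAGS.get(digits))
    return None


@dataclass(frozen=True, order=True)
class StratumSpec:
    """One of the 18 analysis strata.

    Sex crosses with age group OR season, never both: the design enumerates
    3 sexes x (all ages/seasons + 3 age groups + 2 seasons) = 18 strata.
    """

    sex: str = "all"
    age: str = "all"
    season: str = "all"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age != "all" and self.age not in AGE_GROUPS:
            raise ValueError(f"age must be 'all' or one of {AGE_GROUPS}, got {self.age!r}")
        if self.season != "all" and self.season not in SEASONS:
            raise ValueError(f"season must be 'all' or one of {SEASONS}, got {self.season!r}")
        if self.age != "all" and self.season != "all":
            raise ValueError("a stratum may restrict age or season, not both")

    @property
    def label(self) -> str:
        return f"sex={self.sex},age={self.age},season={self.season}"


def enumerate_strata() -> list[StratumSpec]:
    """The full 18-stratum enumeration, in deterministic order."""
    strata = []
    for sex in SEXES:
        strata.append(StratumSpec(sex=sex))
        for age in AGE_GROUPS:
            strata.append(StratumSpec(sex=sex, age=age))
        for season in SEASONS:
            strata.append(StratumSpec(sex=sex, season=season))
    return strata


def age_group(age_years) -> str:
    """Age-group label: 0-10, 11-60, or >60 (ages 61 and above)."""
    age = float(age_years)
    if age < 0:
        raise ValueError(f"negative age: {age}")
    if age <= 10:
        return "0-10"
    if age <= 60:
        return "11-60"
    return ">60"


@dataclass
class TimeStratifiedDesign:
    """Mapping of calendar days to year x month x day-of-week clusters."""

    days: pd.DataFrame  # index: date; columns: cluster (int id), year, month, weekday
    cluster_sizes: pd.Series  # index: cluster id

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def cluster_ids(self, dates) -> np.ndarray:
        return self.days.loc[pd.DatetimeIndex(dates), "cluster"].to_numpy()


def build_clusters(start_date, end_date) -> TimeStratifiedDesign:
    """Partition [start_date, end_date] into (year, month, weekday) clusters.

    Every day belongs to exactly one cluster; within a full calendar month a
    given weekday occurs 4 or 5 times, so full-month cluster sizes are 4 or
    5. Clusters never cross month boundaries. Weekdays follow the ISO
    convention (Monday = 1); any fixed convention yields the same partition.
    """
    start, end = pd.Timestamp(start_date), pd.Timestamp(end_date)
    if start > end:
        raise ValueError(f"start_date {start.date()} is after end_date {end.date()}")
    index = pd.date_range(start, end, freq="D")
    frame = pd.DataFrame(
        {
            "year": index.year,
            "month": index.month,
            "weekday": index.isocalendar().day.to_numpy(),
        },
        index=index,
    )
    keys = list(zip(frame["year"], frame["month"], frame["weekday"]))
    codes, _ = pd.factorize(pd.Index(keys), sort=True)
    frame["cluster"] = codes
    sizes = frame.groupby("cluster").size()
    return TimeStratifiedDesign(days=frame, cluster_sizes=sizes)


def _stratum_mask(visits: pd.DataFrame, stratum: StratumSpec) -> np.ndarray:
    mask = np.ones(len(visits), dtype=bool)
    if stratum.sex != "all":
        mask &= (visits["sex"] == stratum.sex).to_numpy()
    if stratum.age != "all":
        groups = visits["age"].map(age_group)
        mask &= (groups == stratum.age).to_numpy()
    if stratum.season != "all":
        seasons = visits["date"].map(classify_season)
        mask &= (seasons == stratum.season).to_numpy()
    return mask


def build_counts(
    visits: pd.DataFrame,
    start_date,
    end_date,
    strata: Iterable[StratumSpec] | None = None,
    blocks: Iterable[str] = (WHOLE_CHAPTER, "G40-G47"),
) -> pd.DataFrame:
    """Zero-filled daily visit counts per stratum and outcome block.

    Parameters
    ----------
    visits : DataFrame
        Columns ``date`` (datetime-like), ``icd10``, ``sex`` (M/F),
        ``age`` (years). Codes outside the requested blocks simply do not
        count; malformed codes raise through :func:`icd_block`.
    strata, blocks
        Default to the full 18 strata and the whole chapter plus the
        episodic/paroxysmal block.

    Returns
    -------
    Long DataFrame with columns date, stratum, block, count covering every
    day of the study period (zero-filled), where ``stratum`` is the
    :attr:`StratumSpec.label`.
    """
    if strata is None:
        strata = enumerate_strata()
    strata = list(strata)
    index = pd.date_range(pd.Timestamp(start_date), pd.Timestamp(end_date), freq="D")
    visits = visits.copy()
    visits["date"] = pd.to_datetime(visits["date"]).dt.normalize()

    block_of = visits["icd10"].map(lambda c: r.block if (r := icd_block(c)) else None)

    out = []
    for block in blocks:
        if block == WHOLE_CHAPTER:
            in_block = block_of.notna()
        elif block in ICD_BLOCKS:
            in_block = block_of == block
        else:
            raise ValueError(f"unknown outcome block: {block!r}")
        sub = visits.loc[in_block.to_numpy()]
        for stratum in strata:
            sel = sub.loc[_stratum_mask(sub, stratum)]
            counts = (
                sel.groupby("date").size().reindex(index, fill_value=0).astype(int)
            )
            out.append(
                pd.DataFrame(
                    {
                        "date": index,
                        "stratum": stratum.label,
                        "block": block,
                        "count": counts.to_numpy(),
                    }
                )
            )
    return pd.concat(out, ignore_index=True)


def get_count_series(counts: pd.DataFrame, stratum: StratumSpec, block: str) -> pd.Series:
    """Extract one stratum x block daily count series from build_counts output."""
    sel = counts[(counts["stratum"] == stratum.label) & (counts["block"] == block)]
    if sel.empty:
        raise KeyError(f"no counts for stratum {stratum.label!r}, block {block!r}")
    return pd.Series(sel["count"].to_numpy(), index=pd.DatetimeIndex(sel["date"]))


def attach_lags(
    count_series: pd.Series,
    exposures: pd.DataFrame,
    exposure: str,
    lag: int,
    weather_columns: tuple[str, str] = ("temperature", "humidity"),
) -> pd.DataFrame:
    """Model-ready table: day t's count with exposure and weather of day t - lag.

    Weather moves with the exposure so each row describes the conditions on
    the lagged day. Rows whose lagged exposure or weather is missing are
    dropped;
    the number dropped is recorded in ``frame.attrs["n_dropped"]``.

    Raises
    ------
    ValueError
        If lag is outside 0..14.
    """
    if not 0 <= int(lag) <= 14:
        raise ValueError(f"lag must be in 0..14, got {lag}")
    lag = int(lag)
    if exposure not in exposures.columns:
        raise KeyError(f"exposure column {exposure!r} not in exposure table")
    index = count_series.index
    lagged_dates = index - pd.Timedelta(days=lag)
    x = exposures[exposure].reindex(lagged_dates).to_numpy()
    frame = pd.DataFrame({"count": count_series.to_numpy(), "x": x}, index=index)
    for col in weather_columns:
        frame[col] = exposures[col].reindex(lagged_dates).to_numpy()
    n_before = len(frame)
    frame = frame.dropna()
    frame.attrs["n_dropped"] = n_before - len(frame)
    return frame
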