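"""Synthetic exposure, weather and ED-visit generation.

Every downstream stage of the pipeline — aggregation, design construction,
conditional estimation, the model grid — is exercised against data from
this module, which generates series with exactly the statistical structure
the estimator assumes:

* pollutant and weather series: stationary mean + annual sinusoid
  (period 365.25 d) + AR(1) noise, optionally clipped at a floor;
* daily visit counts per disjoint sex x age cell: negative binomial
  (variance = overdispersion x mean; exactly Poisson at overdispersion 1)
  around a log-rate containing a cluster intercept (year x month x weekday,
  i.i.d. normal on the log scale), lagged pollutant effects, and a smooth
  low-order polynomial of standardized temperature and humidity;
* individual visit records disaggregated from the counts, with exact age
  and ICD-10 code sampled from configurable category weights.

The defaults emulate the Toronto 2004-2015 surveillance setting: pollutant
means and seasonal swings near the published descriptive values, an overall
visit rate of about 33/day split across sex and age cells by the published
shares, and diagnosis weights following the published block frequencies.

Cluster intercepts are deliberately present by default: the case-crossover
design must be insensitive to them, and the test suite checks that it is.
True effects are keyed by (exposure, lag) with an optional sex restriction;
counts are simulated on disjoint sex x age cells, so overlapping analysis
strata (all = M + F) remain internally consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import build_clusters
from .exposure import compute_aqhi

__all__ = [
    "ArSeriesParams",
    "Effect",
    "SimulationParams",
    "SyntheticDataset",
    "simulate_exposures",
    "simulate_visits",
    "simulate",
]


@dataclass(frozen=True)
class ArSeriesParams:
    """Mean + seasonal sinusoid + AR(1) noise for one daily series.

    ``sd`` is the innovation standard deviation; the stationary noise
    variance is sd^2 / (1 - ar1^2). ``floor=None`` disables clipping
    (measured concentrations can be slightly negative near the detection
    limit, so pollutant floors are configurable).
    """

    mean: float
    amplitude: float = 0.0
    ar1: float = 0.0
    sd: float = 0.0
    floor: float | None = 0.0
    phase_days: float = 0.0

    def validate(self, name: str) -> None:
        for attr in ("mean", "amplitude", "ar1", "sd", "phase_days"):
            v = getattr(self, attr)
            if not np.isfinite(v):
                raise ValueError(f"{name}.{attr} must be finite, got {v}")
        if not -1 < self.ar1 < 1:
            raise ValueError(f"{name}.ar1 must be in (-1, 1), got {self.ar1}")
        if self.sd < 0:
            raise ValueError(f"{name}.sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class Effect:
    """One true log-rate slope: per-unit effect of ``exposure`` at ``lag``.

    ``sex`` restricts the effect to one sex's cells (None = both), which is
    how stratum-specific effects are expressed on the disjoint simulation
    cells.
    """

    exposure: str
    lag: int
    slope: float
    sex: str | None = None


# Toronto-like defaults: means/seasonal swings near the published all-month
# descriptive values for the 2004-2015 study period.
_DEFAULT_POLLUTANTS = {
    "CO": ArSeriesParams(mean=0.3, amplitude=0.05, ar1=0.6, sd=0.08),
    "NO2": ArSeriesParams(mean=16.1, amplitude=2.1, ar1=0.6, sd=4.5, phase_days=182.6),
    "SO2": ArSeriesParams(mean=1.4, amplitude=0.45, ar1=0.5, sd=0.8, phase_days=182.6),
    "PM2.5": ArSeriesParams(mean=8.9, amplitude=0.35, ar1=0.5, sd=4.0),
    "O3": ArSeriesParams(mean=23.5, amplitude=0.35, ar1=0.6, sd=7.0),
    "O3H8": ArSeriesParams(mean=43.7, amplitude=1.3, ar1=0.6, sd=10.0),
}

_DEFAULT_WEATHER = {
    "temperature": ArSeriesParams(mean=9.5, amplitude=12.5, ar1=0.7, sd=3.0, floor=None),
    "humidity": ArSeriesParams(mean=70.7, amplitude=-2.0, ar1=0.5, sd=7.0, floor=20.0),
}

# sex x age cell weights from the published Toronto visit breakdown
_DEFAULT_CELL_WEIGHTS = {
    ("M", "0-10"): 2314,
    ("F", "0-10"): 1978,
    ("M", "11-60"): 36177,
    ("F", "11-60"): 57456,
    ("M", ">60"): 18418,
    ("F", ">60"): 24168,
}

# representative ICD-10 codes with weights following the published block
# frequencies (episodic/paroxysmal sub-codes split by their printed shares)
_DEFAULT_ICD_WEIGHTS = {
    "G03": 1913,  # inflammatory CNS diseases
    "G12": 472,  # systemic atrophies
    "G20": 4075,  # extrapyramidal/movement
    "G30": 1704,  # degenerative
    "G35": 1816,  # demyelinating
    "G40": 18670,  # epilepsy/seizures
    "G43": 34864,  # migraine
    "G44": 8159,  # other headache syndromes
    "G45": 21914,  # transient ischaemic attacks
    "G47": 6101,  # sleep disorders
    "G56": 30607,  # nerve/root/plexus
    "G62": 3436,  # polyneuropathies
    "G70": 889,  # myoneural junction/muscle
    "G80": 1244,  # cerebral palsy/paralytic
    "G93": 4650,  # other disorders
}


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterization of one synthetic dataset."""

    n_days: int = 1096
    start_date: str = "2004-04-01"
    seed: int = 0
    pollutants: dict = field(default_factory=lambda: dict(_DEFAULT_POLLUTANTS))
    weather: dict = field(default_factory=lambda: dict(_DEFAULT_WEATHER))
    true_effects: tuple = ()
    baseline_rate: float = 32.7  # expected visits/day, all strata combined
    overdispersion: float = 1.5  # variance inflation; 1 = Poisson
    cluster_sd: float = 0.1  # sd of log-scale cluster intercepts
    weather_effect: dict = field(
        default_factory=lambda: {"temp": 0.02, "temp2": 0.03, "rh": 0.01}
    )
    cell_weights: dict = field(default_factory=lambda: dict(_DEFAULT_CELL_WEIGHTS))
    icd_weights: dict = field(default_factory=lambda: dict(_DEFAULT_ICD_WEIGHTS))
    age_ranges: dict = field(
        default_factory=lambda: {"0-10": (0, 10), "11-60": (11, 60), ">60": (61, 95)}
    )

    def validate(self) -> None:
        if self.n_days < 1:
            raise ValueError(f"n_days must be >= 1, got {self.n_days}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.overdispersion < 1:
            raise ValueError(f"overdispersion must be >= 1, got {self.overdispersion}")
        if self.cluster_sd < 0:
            raise ValueError("cluster_sd must be >= 0")
        for name, p in {**self.pollutants, **self.weather}.items():
            p.validate(name)
        for eff in self.true_effects:
            if eff.exposure not in self.pollutants and eff.exposure not in (
                "AQHI",
                "AQHI-x",
            ):
                raise ValueError(f"true effect names unknown exposure {eff.exposure!r}")
            if not 0 <= eff.lag <= 14:
                raise ValueError(f"effect lag must be in 0..14, got {eff.lag}")
            if eff.sex not in (None, "M", "F"):
                raise ValueError(f"effect sex must be None, 'M' or 'F', got {eff.sex!r}")

    @property
    def max_lag(self) -> int:
        return max((e.lag for e in self.true_effects), default=0)

    def with_(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


@dataclass
class SyntheticDataset:
    """Exposure/weather series plus individual visit records.

    ``exposures`` covers a lead-in of ``max_lag`` days before
    ``start_date`` so that lagged assignment never loses study days;
    visits all fall within [start_date, start_date + n_days).
    """

    exposures: pd.DataFrame  # pollutant + index columns, date-indexed
    weather: pd.DataFrame  # temperature / humidity, same index
    visits: pd.DataFrame  # date, icd10, sex, age
    params: SimulationParams

    def combined_daily(self) -> pd.DataFrame:
        """Exposure and weather merged into the daily table the models read."""
        return self.exposures.join(self.weather)


def _ar1_series(rng: np.random.Generator, p: ArSeriesParams, n: int) -> np.ndarray:
    t = np.arange(n)
    seasonal = p.mean + p.amplitude * np.sin(2 * np.pi * (t + p.phase_days) / 365.25)
    if p.sd > 0:
        innov = rng.normal(0.0, p.sd, size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, p.sd / np.sqrt(1 - p.ar1**2)) if p.ar1 else innov[0]
        for i in range(1, n):
            noise[i] = p.ar1 * noise[i - 1] + innov[i]
    else:
        noise = np.zeros(n)
    out = seasonal + noise
    if p.floor is not None:
        out = np.clip(out, p.floor, None)
    return out


def simulate_exposures(params: SimulationParams) -> pd.DataFrame:
    """Daily pollutant series plus derived AQHI / AQHI-x columns.

    Covers ``max_lag`` lead-in days before ``start_date``. Identical
    params (seed included) give bit-identical output.
    """
    params.validate()
    n = params.n_days + params.max_lag
    start = pd.Timestamp(params.start_date) - pd.Timedelta(days=params.max_lag)
    index = pd.date_range(start, periods=n, freq="D")
    streams = np.random.SeedSequence(params.seed).spawn(len(params.pollutants))
    data = {}
    for (name, p), ss in zip(sorted(params.pollutants.items()), streams):
        data[name] = _ar1_series(np.random.default_rng(ss), p, n)
    frame = pd.DataFrame(data, index=index)
    if {"O3", "NO2", "PM2.5"}.issubset(frame.columns):
        frame["AQHI"] = compute_aqhi(frame["O3"], frame["NO2"], frame["PM2.5"])
        if "O3H8" in frame.columns:
            frame["AQHI-x"] = compute_aqhi(frame["O3H8"], frame["NO2"], frame["PM2.5"])
    return frame


def simulate_weather(params: SimulationParams) -> pd.DataFrame:
    """Daily temperature (degC) and relative humidity (%) series."""
    params.validate()
    n = params.n_days + params.max_lag
    start = pd.Timestamp(params.start_date) - pd.Timedelta(days=params.max_lag)
    index = pd.date_range(start, periods=n, freq="D")
    # distinct fixed offset keeps weather streams independent of pollutants
    streams = np.random.SeedSequence((params.seed, 7)).spawn(len(params.weather))
    data = {}
    for (name, p), ss in zip(sorted(params.weather.items()), streams):
        data[name] = _ar1_series(np.random.default_rng(ss), p, n)
    return pd.DataFrame(data, index=index)


def _smooth_weather_term(params: SimulationParams, weather: pd.DataFrame) -> np.ndarray:
    zt = (weather["temperature"] - weather["temperature"].mean()) / (
        weather["temperature"].std() or 1.0
    )
    zh = (weather["humidity"] - weather["humidity"].mean()) / (
        weather["humidity"].std() or 1.0
    )
    c = params.weather_effect
    return (
        c.get("temp", 0.0) * zt
        + c.get("temp2", 0.0) * zt**2
        + c.get("rh", 0.0) * zh
        + c.get("rh2", 0.0) * zh**2
    ).to_numpy()


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    counts = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if phi == 1:
        counts[pos] = rng.poisson(mu[pos])
    else:
        # NB with variance phi*mu: size mu/(phi-1), success prob 1/phi
        size = mu[pos] / (phi - 1.0)
        counts[pos] = rng.negative_binomial(size, 1.0 / phi)
    return counts


def simulate_visits(
    params: SimulationParams,
    exposures: pd.DataFrame,
    weather: pd.DataFrame,
) -> pd.DataFrame:
    """Individual visit records from the cluster/lag/weather log-rate model.

    For each disjoint sex x age cell, daily counts are negative binomial
    (Poisson at overdispersion 1) with

        log mu_t = log(baseline_cell) + alpha_{cluster(t)}
                   + sum_effects slope * exposure_{t - lag}
                   + smooth(temperature_t, humidity_t)

    and are then disaggregated into records with exact age uniform within
    the cell's range and ICD-10 code drawn from the configured weights.
    """
    params.validate()
    start = pd.Timestamp(params.start_date)
    index = pd.date_range(start, periods=params.n_days, freq="D")
    needed = index - pd.Timedelta(days=params.max_lag)
    if not needed.isin(exposures.index).all() or not index.isin(weather.index).all():
        raise ValueError(
            "exposures/weather must cover the study period plus the maximum "
            "lag of the true effects"
        )

    design = build_clusters(index[0], index[-1])
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 13)))
    alpha = rng.normal(0.0, params.cluster_sd, size=design.n_clusters)
    cluster_term = alpha[design.cluster_ids(index)]

    effect_term = {"M": np.zeros(len(index)), "F": np.zeros(len(index))}
    for eff in params.true_effects:
        lagged = exposures[eff.exposure].reindex(index - pd.Timedelta(days=eff.lag))
        contrib = eff.slope * lagged.to_numpy()
        for sex in ("M", "F"):
            if eff.sex in (None, sex):
                effect_term[sex] += contrib

    weather_term = _smooth_weather_term(params, weather.loc[index])

    total_weight = float(sum(params.cell_weights.values()))
    codes = sorted(params.icd_weights)
    code_p = np.array([params.icd_weights[c] for c in codes], dtype=float)
    code_p /= code_p.sum()

    records = []
    for (sex, age_grp), w in sorted(params.cell_weights.items()):
        base = params.baseline_rate * w / total_weight
        if base == 0:
            continue
        log_mu = (
            np.log(base) + cluster_term + effect_term[sex] + weather_term
        )
        counts = _draw_counts(rng, np.exp(log_mu), params.overdispersion)
        total = int(counts.sum())
        if total == 0:
            continue
        dates = np.repeat(index.to_numpy(), counts)
        lo, hi = params.age_ranges[age_grp]
        ages = rng.integers(lo, hi + 1, size=total)
        icd = rng.choice(codes, size=total, p=code_p)
        records.append(
            pd.DataFrame({"date": dates, "icd10": icd, "sex": sex, "age": ages})
        )
    if not records:
        return pd.DataFrame(columns=["date", "icd10", "sex", "age"])
    out = pd.concat(records, ignore_index=True)
    return out.sort_values(["date", "sex", "age"], kind="stable").reset_index(drop=True)


def simulate(params: SimulationParams) -> SyntheticDataset:
    """Generate a complete synthetic dataset (exposures, weather, visits)."""
    exposures = simulate_exposures(params)
    weather = simulate_weather(params)
    visits = simulate_visits(params, exposures, weather)
    return SyntheticDataset(
        exposures=exposures, weather=weather, visits=visits, params=params
    )
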