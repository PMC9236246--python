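"""Pipeline configuration: a YAML block that round-trips losslessly.

Unknown keys are rejected rather than ignored — a typo in a threshold name
should fail loudly, not silently run with the default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class SimulateConfig:
    n_days: int = 1096
    start_date: str = "2004-04-01"
    seed: int = 0
    baseline_rate: float = 32.7
    overdispersion: float = 1.5
    cluster_sd: float = 0.1


@dataclass
class PipelineConfig:
    start_date: str = "2004-04-01"
    end_date: str = "2007-03-31"
    visits_path: str = "visits.csv"
    exposures_path: str = "daily_exposures.csv"
    outdir: str = "out"
    completeness_min: float = 0.75
    min_stations: int = 1
    window_policy: str = "within_day"  # or cross_midnight
    percentile_method: str = "linear"
    spline_df: int = 3
    global_spline_basis: bool = False  # per-subset quantile knots by default
    per_stratum_iqr: bool = False
    blocks: list = field(default_factory=lambda: ["G00-G99", "G40-G47"])
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sim = data.pop("simulate", {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        sim_known = {f.name for f in fields(SimulateConfig)}
        sim_unknown = set(sim) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulate config key(s): {sorted(sim_unknown)}")
        return cls(**data, simulate=SimulateConfig(**sim))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
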