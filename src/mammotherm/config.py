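"""Configuration objects for the simulator and the pipeline driver.

Both configs are plain dataclasses with eager validation: a bad value fails
at construction, not three stages into a run. The YAML loader rejects unknown
keys so a typo in a config file cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Any

import yaml

GROUPS = ("control", "survivor", "non-survivor")

#: Luteal-window group mean vascularity (breast − oral, °C), days −11…−1.
DEFAULT_GROUP_LUTEAL_MEAN = {
    "control": -1.42,
    "survivor": -1.65,
    "non-survivor": -1.25,
}

#: Group acrophase of the vascularity rhythm, in days after menses onset [0, 28).
DEFAULT_GROUP_ACROPHASE = {
    "control": 27.4,
    "survivor": 21.5,
    "non-survivor": 20.1,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic-cohort generator.

    The defaults encode the study conditions the pipeline is designed for:
    cycle lengths uniform on 19–39 d with a 12–14 d luteal phase, a ~1 °C
    luteal breast-temperature rise of which 0.33 °C is the post-ovulatory
    basal (oral) rise and 0.67 °C is the vascularity component, a 2.36 °C
    between-subject spread of the body-temperature set point, 15 % of
    subject-days missing at random, and group-specific luteal vascularity
    levels and acrophases.
    """

    n_per_group: int = 18
    seed: int = 0
    cycle_length_range: tuple[int, int] = (19, 39)
    luteal_length_range: tuple[int, int] = (12, 14)
    group_luteal_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_LUTEAL_MEAN)
    )
    group_acrophase: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_ACROPHASE)
    )
    breast_rise: float = 0.67  # °C, vascularity component of the luteal rise
    oral_rise: float = 0.33  # °C, post-ovulatory basal-body step
    baseline_spread: float = 2.36  # °C, between-subject set-point range
    subject_level_sd: float = 0.15  # °C, between-subject luteal-level SD
    missing_fraction: float = 0.15
    daily_noise_sd: float = 0.15  # °C, per-day measurement noise (each channel)
    oral_basal: float = 36.4  # °C, follicular oral temperature
    asymmetric: bool = False  # saw-tooth rise instead of a pure cosine
    progesterone_baseline: float = 30.0  # pM/L
    progesterone_peak: float = 300.0  # pM/L, mid-luteal peak
    progesterone_noise_sd: float = 25.0  # pM/L
    # per-minute trace parameters
    trace_start_C: float = 32.0
    trace_tau_min: float = 8.0  # equilibration time constant, minutes
    trace_noise_sd: float = 0.05  # °C per minute sample
    trace_duration_min: int = 90
    start_date: date = date(2000, 3, 1)  # first subject's previous menses onset

    def __post_init__(self) -> None:
        lo, hi = self.cycle_length_range
        if not (19 <= lo <= hi <= 39):
            raise ValueError(f"cycle_length_range must lie within [19, 39], got {self.cycle_length_range}")
        llo, lhi = self.luteal_length_range
        if not (0 < llo <= lhi <= lo):
            raise ValueError("luteal length range must be positive and fit inside the shortest cycle")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError(f"missing_fraction must be in [0, 1), got {self.missing_fraction}")
        for name in ("subject_level_sd", "daily_noise_sd", "progesterone_noise_sd", "trace_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_per_group <= 0:
            raise ValueError(f"n_per_group must be positive, got {self.n_per_group}")
        for g in GROUPS:
            if g not in self.group_luteal_mean or g not in self.group_acrophase:
                raise ValueError(f"group '{g}' missing from group_luteal_mean/group_acrophase")
        if self.trace_duration_min < 30:
            raise ValueError("trace_duration_min must be at least 30 minutes")

    def replace(self, **changes: Any) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["start_date"] = self.start_date.isoformat()
        d["cycle_length_range"] = list(self.cycle_length_range)
        d["luteal_length_range"] = list(self.luteal_length_range)
        return d


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Stage toggles select which stages run; parameters for each stage live
    here so a single YAML file fully reproduces a run.
    """

    out_dir: Path = Path("mammotherm_out")
    seed: int = 0
    log_level: str = "INFO"
    # stage toggles
    simulate: bool = True
    emit_traces: bool = False
    extract: bool = False
    sync: bool = True
    cosinor: bool = True
    compare: bool = True
    npi: bool = True
    # inputs when simulate is off
    daily_log: Path | None = None
    pathology: Path | None = None
    traces: Path | None = None
    # stage parameters
    sim: SimConfig = field(default_factory=SimConfig)
    smooth_window: int = 5
    slope_tol: float = 0.02
    min_duration: int = 10
    discard_initial: int = 30
    luteal_window: tuple[int, int] = (-11, -1)
    welch: bool = False
    cosinor_on_moving_average: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        lo, hi = self.luteal_window
        if not (lo <= hi < 0):
            raise ValueError(f"luteal_window must satisfy lower <= upper < 0, got {self.luteal_window}")
        if self.slope_tol <= 0 or self.min_duration <= 0 or self.smooth_window <= 0:
            raise ValueError("plateau parameters must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "sim" in kwargs and isinstance(kwargs["sim"], dict):
            sim_raw = dict(kwargs["sim"])
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(sim_raw) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            if "start_date" in sim_raw and isinstance(sim_raw["start_date"], str):
                sim_raw["start_date"] = date.fromisoformat(sim_raw["start_date"])
            for key in ("cycle_length_range", "luteal_length_range"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            kwargs["sim"] = SimConfig(**sim_raw)
        for key in ("out_dir", "daily_log", "pathology", "traces"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        if "luteal_window" in kwargs:
            kwargs["luteal_window"] = tuple(kwargs["luteal_window"])
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        for key in ("out_dir", "daily_log", "pathology", "traces"):
            if d[key] is not None:
                d[key] = str(d[key])
        d["luteal_window"] = list(self.luteal_window)
        return d
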