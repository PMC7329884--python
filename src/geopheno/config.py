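"""Pipeline configuration.

All tunable thresholds of the preprocessing framework live in one
:class:`PipelineConfig`, loadable from a YAML file and overridable from the
command line.  Defaults equal the published operating point of the framework:
a stay point is a run of fixes remaining within ``theta_d_m`` = 350 m of its
anchor for at least ``theta_t_min`` = 60 min, and recurrent places are merged
with a density-based clustering radius ``epsilon_m`` = 150 m.
"""

from __future__ import annotations

import dataclasses
import zoneinfo
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is missing, unknown or out of range."""


@dataclass
class PipelineConfig:
    """Every threshold used by the pipeline, with validated defaults.

    Parameters
    ----------
    timezone:
        IANA zone used for local-day and night-window computation.
    max_confidence_m:
        Fixes whose 68%-containment radius exceeds this are discarded.
    missing_confidence:
        ``"keep"`` or ``"drop"`` fixes with no reported confidence.
    max_gap_min:
        A hole longer than this splits the trace into separate segments.
    theta_t_min, theta_d_m:
        Stay-point duration (minutes) and distance (meters) thresholds.
    epsilon_m, min_points:
        Density-clustering radius (meters) and core-point minimum.
    night_window:
        Local clock hours ``(start, end)`` whose dwell votes for home.
    grid_interval_min:
        Resampling step for the diurnal-movement location series.
    period_band_h:
        Period band (hours) whose spectral energy defines diurnal movement.
    homestay_denominator:
        ``"dwell"`` (total stay-point time) or ``"elapsed"`` (clock time).
    seed:
        Master seed for every source of randomness.
    """

    timezone: str = "UTC"
    max_confidence_m: float = 200.0
    missing_confidence: str = "keep"
    max_gap_min: float = 60.0
    theta_t_min: float = 60.0
    theta_d_m: float = 350.0
    epsilon_m: float = 150.0
    min_points: int = 1
    night_window: tuple[float, float] = (0.0, 6.0)
    grid_interval_min: float = 10.0
    period_band_h: tuple[float, float] = (23.5, 24.5)
    homestay_denominator: str = "dwell"
    seed: int = 0

    def __post_init__(self) -> None:
        try:
            zoneinfo.ZoneInfo(self.timezone)
        except (zoneinfo.ZoneInfoNotFoundError, ValueError) as exc:
            raise ConfigError(f"invalid timezone {self.timezone!r}") from exc
        if self.max_confidence_m <= 0:
            raise ConfigError("max_confidence_m must be > 0")
        if self.missing_confidence not in ("keep", "drop"):
            raise ConfigError("missing_confidence must be 'keep' or 'drop'")
        if self.max_gap_min <= 0:
            raise ConfigError("max_gap_min must be > 0")
        if self.theta_t_min <= 0 or self.theta_d_m <= 0:
            raise ConfigError("theta_t_min and theta_d_m must be > 0")
        if self.epsilon_m <= 0:
            raise ConfigError("epsilon_m must be > 0")
        if self.min_points < 1:
            raise ConfigError("min_points must be >= 1")
        self.night_window = tuple(self.night_window)  # type: ignore[assignment]
        lo, hi = self.night_window
        if not (0 <= lo < hi <= 24):
            raise ConfigError("night_window must satisfy 0 <= start < end <= 24")
        self.period_band_h = tuple(self.period_band_h)  # type: ignore[assignment]
        if not (0 < self.period_band_h[0] < self.period_band_h[1]):
            raise ConfigError("period_band_h must be an increasing positive pair")
        if self.homestay_denominator not in ("dwell", "elapsed"):
            raise ConfigError("homestay_denominator must be 'dwell' or 'elapsed'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["night_window"] = list(self.night_window)
        d["period_band_h"] = list(self.period_band_h)
        return d

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
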