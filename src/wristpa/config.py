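"""Study configuration.

Every processing knob that the underlying validation protocol leaves open
(cut-points, Choi parameters, epoch lengths, coverage tolerances, the
valid-day rule, the CI level and equivalence-zone granularity) lives here,
so that changing a reference value is an explicit configuration change and
never a silent edit to analysis logic.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys or invalid parameter values."""


@dataclass(frozen=True)
class CutPoints:
    """ENMO intensity cut-points in milli-g.

    Defaults are the adult non-dominant-wrist thresholds of the
    Hildebrand regression equations (44.8 mg separates sedentary from
    light, 100.6 mg separates light from moderate-to-vigorous).
    Boundaries are half-open with the upper class winning at the
    threshold (ENMO equal to a cut-point classifies into the higher
    class).
    """

    sed_lpa: float = 44.8
    lpa_mvpa: float = 100.6
    source_label: str = "hildebrand-adult-nondominant-wrist"

    def __post_init__(self) -> None:
        if not (0 < self.sed_lpa < self.lpa_mvpa):
            raise ConfigError(
                f"cut-points must satisfy 0 < sed_lpa < lpa_mvpa, "
                f"got {self.sed_lpa}, {self.lpa_mvpa}"
            )


@dataclass(frozen=True)
class ChoiParams:
    """Parameters of the Choi non-wear detection rule (minutes)."""

    window_min: int = 90
    spike_tol_min: int = 2
    spike_win_min: int = 30

    def __post_init__(self) -> None:
        if self.window_min <= 0 or self.spike_win_min <= 0 or self.spike_tol_min < 0:
            raise ConfigError("Choi parameters must be positive (spike_tol >= 0)")


@dataclass(frozen=True)
class StudyConfig:
    """Top-level analysis configuration with documented defaults."""

    cut_points: CutPoints = field(default_factory=CutPoints)
    choi: ChoiParams = field(default_factory=ChoiParams)
    # MET class breakpoints: <=1.5 SED, (1.5,3.0) LPA, [3.0,6.0) MPA, >=6.0 VPA.
    met_breakpoints: tuple[float, float, float] = (1.5, 3.0, 6.0)
    epoch_len_s: int = 60
    breath_bin_s: int = 10
    # a 60-s calorimetry epoch needs at least this many 10-s bins present
    min_bins_per_min: int = 3
    # fraction of expected samples a second needs to yield an ENMO value
    second_coverage_min: float = 0.5
    # missing seconds tolerated before a 60-s accelerometer epoch is invalid
    epoch_missing_tol_s: int = 0
    # per-minute movement proxy: mean ENMO below this is treated as a zero count
    stillness_floor_mg: float = 1.0
    # autocalibration (static-window least squares)
    calib_still_sd_g: float = 0.004
    calib_window_s: int = 10
    calib_min_windows: int = 20
    calib_sphere_crit_g: float = 0.3
    # valid-day rule: minimum analysis minutes for a day to count (0 = any)
    min_valid_day_min: float = 0.0
    ci_level: float = 0.90
    ez_granularity_pct: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epoch_len_s <= 0 or 3600 % self.epoch_len_s:
            raise ConfigError("epoch_len_s must be a positive divisor of 3600")
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level must lie in (0, 1)")
        if self.ez_granularity_pct <= 0:
            raise ConfigError("ez_granularity_pct must be positive")
        lo, mid, hi = self.met_breakpoints
        if not lo < mid < hi:
            raise ConfigError("met_breakpoints must be strictly increasing")


def _build(cls: type, data: dict[str, Any], path: str) -> Any:
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"unknown config key(s) under '{path}': {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        ftype = names[key].type
        if isinstance(value, dict):
            sub = {"cut_points": CutPoints, "choi": ChoiParams}.get(key)
            if sub is None:
                raise ConfigError(f"'{path}.{key}' does not accept a mapping")
            value = _build(sub, value, f"{path}.{key}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    del ftype
    return cls(**kwargs)


def load_config(path: str | Path | None) -> StudyConfig:
    """Load a YAML config file; ``None`` returns the documented defaults.

    Unknown keys are rejected rather than ignored, so typos cannot
    silently fall back to defaults.
    """
    if path is None:
        return StudyConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return _build(StudyConfig, raw, "config")


def dump_config(config: StudyConfig, path: str | Path) -> None:
    """Write the configuration back out as YAML (round-trips load_config)."""
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=False)
    )
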