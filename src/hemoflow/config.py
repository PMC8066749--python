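"""Structured run configuration (YAML) with the instrument defaults.

One human-readable file carries every physical constant of the pipeline
— geometry, flow rates, optical constants, population distributions,
filter banks, counting factors — so a run is reproducible from
(config, seed) alone and no stage hides a magic number.  Unknown keys
fail loudly with their field path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import ChannelGeometry, FlowConfig
from .optics import OpticalConstants
from .simulate import DefocusSpec, NoiseSpec, PopulationParams

__all__ = ["RunConfig", "load_config", "default_config_yaml"]


@dataclass(frozen=True)
class SimulationSettings:
    """Generator settings that are not physical constants."""

    mode: str = "laminar"  # laminar | focused | analyte
    truth_cells_per_ul: float = 5.0e6
    n_cells: int = 300  # analyte mode only
    pixel_size_um: float = 0.688
    analyte_pixel_size_um: float = 0.344
    sheath_width_um: float = 1801.0
    delta: float = 0.79
    seed: int = 0


@dataclass(frozen=True)
class CountingSettings:
    cv_threshold: float = 0.25
    window_s: float | None = None
    threshold_floor_frac: float = 0.25


@dataclass(frozen=True)
class RunConfig:
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    flow: FlowConfig = field(default_factory=FlowConfig)
    optics: OpticalConstants = field(default_factory=OpticalConstants)
    population: PopulationParams = field(default_factory=PopulationParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    defocus: DefocusSpec = field(default_factory=DefocusSpec)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    counting: CountingSettings = field(default_factory=CountingSettings)


_SECTIONS = {
    "geometry": ChannelGeometry,
    "flow": FlowConfig,
    "optics": OpticalConstants,
    "population": PopulationParams,
    "noise": NoiseSpec,
    "defocus": DefocusSpec,
    "simulation": SimulationSettings,
    "counting": CountingSettings,
}


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config field(s) {sorted(unknown)} under '{path}'")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section(s) {sorted(unknown)}")
    kwargs = {
        name: _build(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(**kwargs)


def default_config_yaml() -> str:
    """The full default configuration, serialized."""
    cfg = RunConfig()
    out = {
        name: dataclasses.asdict(getattr(cfg, name)) for name in _SECTIONS
    }
    return yaml.safe_dump(out, sort_keys=False)
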