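"""YAML/JSON run-configuration loading.

A run config names or spells out the schedule and overrides any engine or
astrocyte parameter, e.g.::

    schedule: timeline          # or glio:chronic, mode:acute:2, or a
    seed: 7                     # segments: [...] mapping (Schedule.to_dict)
    n_exc: 800
    n_inh: 200
    astro:
      k_glio: 2.0
    astro_targets: all
    noise_shared: false
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .astrocyte import AstroParameters
from .engine import SimulationConfig
from .protocol import ConfigurationError, Schedule

__all__ = ["load_config", "config_from_dict"]


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    schedule = data.pop("schedule", "timeline")
    if isinstance(schedule, dict):
        schedule = Schedule.from_dict(schedule)
    astro_over = data.pop("astro", {}) or {}
    unknown = set(astro_over) - set(AstroParameters.__dataclass_fields__)
    if unknown:
        raise ConfigurationError(f"unknown astrocyte parameters: {sorted(unknown)}")
    astro = replace(AstroParameters(), **astro_over)
    seed = data.pop("seed", data.pop("master_seed", 0))
    allowed = {"n_exc", "n_inh", "dt_ms", "astro_targets", "noise_shared",
               "record_astro"}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(schedule=schedule, master_seed=int(seed),
                            astro=astro, **data)


def load_config(path) -> SimulationConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("run config must be a mapping")
    return config_from_dict(data)
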