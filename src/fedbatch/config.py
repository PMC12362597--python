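"""Run configuration: schema, YAML loading/validation, unit conversions.

A run configuration is a single YAML file with the sections ``process``,
``stage1``, ``stage2`` and optionally ``grid`` and ``options``. All values
use g, L, h — there is no unit inference. Unknown keys are rejected and
validation reports every failure at once, not just the first.

Schema (defaults in brackets; keys without a default are required)::

    process:
      v0: reactor volume at feed start, L
      x0: total biomass at feed start, g
      p0: total product at feed start, g           [0.0]
      s_f: substrate concentration of the feed, g/L
      v_max: final reactor volume, L
      f_min: lower feasible feed rate, L/h         [0.0]
      f_max: upper feasible feed rate, L/h         [inf]
    stage1:                  # growth stage physiology
      y_xs: biomass yield on substrate, g/g
      y_ps: product yield on substrate, g/g
      m_s: maintenance coefficient, g/g/h          [0.0]
      alpha: growth-associated productivity, g/g   [0.0]
      beta: non-growth productivity, g/g/h         [0.0]
      mu_max: cap on specific growth rate, 1/h     [null = uncapped]
    stage2:                  # growth-arrested stage physiology (same keys)
    grid:                    # optional; needed for grid searches
      strategy: constant | linear | exponential    [constant]
      param_min, param_max: stage-1 parameter bounds
          (L/h for constant, L/h^2 for linear ramp, 1/h for exponential)
      n_param: grid points on the parameter axis   [50]
      frac_min, frac_max: feed-volume fraction axis [0.05, 1.0]
      n_frac: grid points on the fraction axis     [50]
      log_spacing: log-spaced parameter axis       [false]
    options:
      objective: rate | titer                      [rate]
      batch_time_h: fixed batch-phase duration added to the rate
          denominator for reporting, h             [0.0]
      samples_per_stage: trajectory resolution     [200]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import ConfigError
from .grid import GridSpec, STRATEGY_TYPES
from .model import ProcessSetup, StagePhysiology

__all__ = [
    "GridConfig",
    "RunOptions",
    "RunConfig",
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "dump_config",
    "convert_atp_maintenance",
]


@dataclass(frozen=True)
class GridConfig:
    """Grid-search axes in config form (bounds + resolutions)."""

    param_min: float
    param_max: float
    strategy: str = "constant"
    n_param: int = 50
    frac_min: float = 0.05
    frac_max: float = 1.0
    n_frac: int = 50
    log_spacing: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGY_TYPES:
            raise ValueError(f"grid.strategy must be one of {STRATEGY_TYPES}, "
                             f"got {self.strategy!r}")
        if not self.param_min < self.param_max:
            raise ValueError("grid.param_min must be < grid.param_max")
        if not (0 <= self.frac_min < self.frac_max <= 1):
            raise ValueError("need 0 <= grid.frac_min < grid.frac_max <= 1")
        if self.n_param < 2 or self.n_frac < 2:
            raise ValueError("grid resolutions n_param and n_frac must be >= 2")

    def to_spec(self) -> GridSpec:
        return GridSpec.from_bounds(
            self.strategy, self.param_min, self.param_max, self.n_param,
            self.frac_min, self.frac_max, self.n_frac, self.log_spacing)


@dataclass(frozen=True)
class RunOptions:
    objective: str = "rate"
    batch_time_h: float = 0.0
    samples_per_stage: int = 200

    def __post_init__(self) -> None:
        if self.objective not in ("rate", "titer"):
            raise ValueError(f"options.objective must be 'rate' or 'titer', "
                             f"got {self.objective!r}")
        if self.batch_time_h < 0:
            raise ValueError("options.batch_time_h must be >= 0")
        if self.samples_per_stage < 2:
            raise ValueError("options.samples_per_stage must be >= 2")


@dataclass(frozen=True)
class RunConfig:
    """Fully validated inputs for a simulation or grid run."""

    setup: ProcessSetup
    stage1: StagePhysiology
    stage2: StagePhysiology
    grid: Optional[GridConfig] = None
    options: RunOptions = field(default_factory=RunOptions)


_SECTION_FIELDS = {
    "process": {
        "required": ("v0", "x0", "s_f", "v_max"),
        "optional": {"p0": 0.0, "f_min": 0.0, "f_max": math.inf},
    },
    "stage1": {
        "required": ("y_xs", "y_ps"),
        "optional": {"m_s": 0.0, "alpha": 0.0, "beta": 0.0, "mu_max": None},
    },
    "stage2": {
        "required": ("y_xs", "y_ps"),
        "optional": {"m_s": 0.0, "alpha": 0.0, "beta": 0.0, "mu_max": None},
    },
    "grid": {
        "required": ("param_min", "param_max"),
        "optional": {"strategy": "constant", "n_param": 50, "frac_min": 0.05,
                     "frac_max": 1.0, "n_frac": 50, "log_spacing": False},
    },
    "options": {
        "required": (),
        "optional": {"objective": "rate", "batch_time_h": 0.0,
                     "samples_per_stage": 200},
    },
}


def _parse_section(raw: dict, section: str, errors: list) -> Optional[dict]:
    schema = _SECTION_FIELDS[section]
    data = raw.get(section)
    if data is None:
        if schema["required"]:
            errors.append(f"missing required section '{section}'")
        data = {}
    if not isinstance(data, dict):
        errors.append(f"section '{section}' must be a mapping")
        return None
    allowed = set(schema["required"]) | set(schema["optional"])
    for key in data:
        if key not in allowed:
            errors.append(f"unknown key '{section}.{key}' "
                          f"(allowed: {', '.join(sorted(allowed))})")
    kwargs = dict(schema["optional"])
    ok = True
    for key in schema["required"]:
        if key not in data:
            errors.append(f"missing required key '{section}.{key}'")
            ok = False
    for key, value in data.items():
        if key in allowed:
            kwargs[key] = value
    return kwargs if ok else None


def config_from_dict(raw: dict) -> RunConfig:
    """Build and validate a :class:`RunConfig` from a plain mapping.

    Collects *all* problems (unknown keys, missing keys, invariant
    violations) into a single :class:`~fedbatch.errors.ConfigError`.
    """
    if not isinstance(raw, dict):
        raise ConfigError(["configuration root must be a mapping"])
    errors: list = []
    known = set(_SECTION_FIELDS)
    for key in raw:
        if key not in known:
            errors.append(f"unknown section '{key}' (allowed: {', '.join(sorted(known))})")

    parts = {}
    builders = {
        "process": ProcessSetup,
        "stage1": StagePhysiology,
        "stage2": StagePhysiology,
        "grid": GridConfig,
        "options": RunOptions,
    }
    for section, builder in builders.items():
        if section == "grid" and "grid" not in raw:
            parts["grid"] = None
            continue
        kwargs = _parse_section(raw, section, errors)
        if kwargs is None:
            parts[section] = None
            continue
        try:
            parts[section] = builder(**kwargs)
        except (ValueError, TypeError) as exc:
            errors.append(f"{section}: {exc}")
            parts[section] = None
    if errors:
        raise ConfigError(errors)
    return RunConfig(setup=parts["process"], stage1=parts["stage1"],
                     stage2=parts["stage2"], grid=parts["grid"],
                     options=parts["options"])


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def _phys_dict(phys: StagePhysiology) -> dict:
    d = {"y_xs": phys.y_xs, "y_ps": phys.y_ps, "m_s": phys.m_s,
         "alpha": phys.alpha, "beta": phys.beta}
    if phys.mu_max is not None:
        d["mu_max"] = phys.mu_max
    return d


def config_to_dict(cfg: RunConfig) -> dict:
    """Normalized plain-mapping form (defaults filled in, units g/L/h)."""
    out = {
        "process": {
            "v0": cfg.setup.v0, "x0": cfg.setup.x0, "p0": cfg.setup.p0,
            "s_f": cfg.setup.s_f, "v_max": cfg.setup.v_max,
            "f_min": cfg.setup.f_min, "f_max": cfg.setup.f_max,
        },
        "stage1": _phys_dict(cfg.stage1),
        "stage2": _phys_dict(cfg.stage2),
        "options": {
            "objective": cfg.options.objective,
            "batch_time_h": cfg.options.batch_time_h,
            "samples_per_stage": cfg.options.samples_per_stage,
        },
    }
    if cfg.grid is not None:
        out["grid"] = {
            "strategy": cfg.grid.strategy,
            "param_min": cfg.grid.param_min,
            "param_max": cfg.grid.param_max,
            "n_param": cfg.grid.n_param,
            "frac_min": cfg.grid.frac_min,
            "frac_max": cfg.grid.frac_max,
            "n_frac": cfg.grid.n_frac,
            "log_spacing": cfg.grid.log_spacing,
        }
    return out


def dump_config(cfg: RunConfig, path=None) -> str:
    """Serialize a config back to YAML (normalized; round-trips losslessly)."""
    text = yaml.safe_dump(config_to_dict(cfg), sort_keys=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def convert_atp_maintenance(m_atp: float, y_atp_s: float) -> float:
    """Maintenance coefficient from an ATP maintenance requirement.

    ``m_atp`` (mmol ATP / g biomass / h) divided by the ATP yield on the
    substrate ``y_atp_s`` (mmol ATP / g substrate) gives ``m_s`` in
    g substrate / g biomass / h — convenient because ATP maintenance demands
    and ATP yields on glucose are tabulated in the literature.
    """
    if not y_atp_s > 0:
        raise ValueError(f"y_atp_s must be > 0, got {y_atp_s}")
    if m_atp < 0:
        raise ValueError(f"m_atp must be >= 0, got {m_atp}")
    return m_atp / y_atp_s
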