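"""Flat key = value control files.

One key per line, ``#`` starts a comment, values are strings until typed by
the consumer.  This mirrors the single control input file that drives a
simulation: time step, temperature, ionic strength, boundary, seeds, file
locations and the flexibility schedule.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .model import BoundarySpec, SimulationConfig, SwitchSchedule

__all__ = ["parse_config_file", "parse_overrides", "build_simulation_config", "ConfigError"]


class ConfigError(ValueError):
    pass


def parse_config_file(path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{ln}: expected 'key = value', got {line!r}")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def parse_overrides(pairs) -> dict[str, str]:
    """--set key=value overrides from the command line."""
    out = {}
    for p in pairs:
        if "=" not in p:
            raise ConfigError(f"override {p!r} is not of the form key=value")
        k, v = p.split("=", 1)
        out[k.strip()] = v.strip()
    return out


_FLOAT_KEYS = {
    "dt", "temperature", "ionic_strength", "solvent_dielectric", "cutoff",
    "dt_far", "near_radius", "phi_max", "kappa",
}
_INT_KEYS = {"master_seed", "n_trajectories", "n_steps", "n_retry"}


def build_simulation_config(kv: dict[str, str]) -> SimulationConfig:
    """Typed :class:`SimulationConfig` from a flat key/value mapping."""
    kwargs = {}
    for key in _FLOAT_KEYS & kv.keys():
        kwargs[key] = float(kv[key])
    for key in _INT_KEYS & kv.keys():
        kwargs[key] = int(kv[key])
    if "boundary" in kv:
        dims = [float(v) for v in kv.get("boundary_dimensions", "100").split()]
        surf = kv.get("planar_surface_z")
        kwargs["boundary"] = BoundarySpec(
            kind=kv["boundary"],
            dimensions=np.asarray(dims),
            planar_surface_z=None if surf is None else float(surf),
        )
    if "flex_mode" in kv:
        kwargs["switch_schedule"] = SwitchSchedule(
            mode=kv.get("flex_mode", "fixed"),
            mean_interval=float(kv.get("flex_mean_interval", 1000.0)),
            sd_interval=float(kv.get("flex_sd_interval", 0.0)),
            nearest=kv.get("flex_nearest", "no").lower() in ("1", "yes", "true"),
            criterion=kv.get("flex_criterion", "metropolis"),
        )
    try:
        return SimulationConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
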