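"""Configuration files (YAML or JSON) for sweeps.

Schema, all keys optional (defaults are the quarter-scale demonstration
setup)::

    flight: {T: 8, D: 7, H: 20, h: 3, w: 10, tether_length: 25}
    animal: {length: 1.410, speed: 1.8}
    kite:   {span: 3.0, chord: 0.75, thickness: 0.15}
    tether_radius: 0.02
    grid:
      z: {start: 0, step: 1, stop: 20}     # or an explicit list
      y: {start: -7, step: 1, stop: 7}
    n_delays: 50
    dt: 0.1
    collision_threshold: 0.001

Grid ranges are inclusive of the stop value (start:step:stop).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .kinematics import ConfigurationError, FlightPathParams
from .simulation import SimulationConfig

__all__ = ["load_config", "config_to_dict"]


def _parse_grid(spec, name: str) -> tuple:
    if isinstance(spec, (list, tuple)):
        return tuple(float(v) for v in spec)
    if isinstance(spec, dict):
        try:
            start, step, stop = spec["start"], spec["step"], spec["stop"]
        except KeyError as exc:
            raise ConfigurationError(
                f"grid.{name}: range form needs start/step/stop"
            ) from exc
        if step <= 0 or stop < start:
            raise ConfigurationError(f"grid.{name}: need step > 0 and stop >= start")
        n = int(round((stop - start) / step))
        return tuple(float(v) for v in (start + step * np.arange(n + 1)))
    raise ConfigurationError(f"grid.{name} must be a list or a start/step/stop map")


def load_config(path) -> SimulationConfig:
    """Read a sweep configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration root must be a mapping")

    kwargs: dict = {}
    if "flight" in raw:
        f = raw["flight"]
        kwargs["flight"] = FlightPathParams(
            T=f.get("T", 8.0),
            D=f.get("D", 7.0),
            H=f.get("H", 20.0),
            h=f.get("h", 3.0),
            w=f.get("w", 10.0),
            tether_length=f.get("tether_length", 25.0),
        )
    if "animal" in raw:
        a = raw["animal"]
        if "length" in a:
            kwargs["animal_length"] = float(a["length"])
        if "speed" in a:
            kwargs["animal_speed"] = float(a["speed"])
    if "kite" in raw:
        k = raw["kite"]
        for src, dst in (("span", "kite_span"), ("chord", "kite_chord"), ("thickness", "kite_thickness")):
            if src in k:
                kwargs[dst] = float(k[src])
    if "grid" in raw:
        g = raw["grid"]
        if "z" in g:
            kwargs["z_grid"] = _parse_grid(g["z"], "z")
        if "y" in g:
            kwargs["y_grid"] = _parse_grid(g["y"], "y")
    for key in (
        "tether_radius",
        "n_delays",
        "dt",
        "collision_threshold",
        "include_kite",
        "include_tether",
        "prune_dead_positions",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    try:
        return SimulationConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid configuration {path}: {exc}") from exc


def config_to_dict(cfg: SimulationConfig) -> dict:
    """JSON-serialisable snapshot of a configuration (for manifests)."""
    return {
        "flight": {
            "T": cfg.flight.T,
            "D": cfg.flight.D,
            "H": cfg.flight.H,
            "h": cfg.flight.h,
            "w": cfg.flight.w,
            "tether_length": cfg.flight.tether_length,
        },
        "animal": {"length": cfg.animal_length, "speed": cfg.animal_speed},
        "kite": {
            "span": cfg.kite_span,
            "chord": cfg.kite_chord,
            "thickness": cfg.kite_thickness,
        },
        "tether_radius": cfg.tether_radius,
        "grid": {"z": list(cfg.z_grid), "y": list(cfg.y_grid)},
        "n_delays": cfg.n_delays,
        "dt": cfg.dt,
        "collision_threshold": cfg.collision_threshold,
        "include_kite": cfg.include_kite,
        "include_tether": cfg.include_tether,
        "prune_dead_positions": cfg.prune_dead_positions,
    }
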