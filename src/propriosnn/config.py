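"""Run configuration: defaults, YAML round-trip, and encoder construction.

Precedence when assembling a run: explicit function/CLI arguments beat
values from a config file, which beat the built-in defaults below.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .hair_field import build_plate
from .network import (
    DEFAULT_DT,
    JointEncoderConfig,
    POSITION_LIF,
    VELOCITY_HP_LIF,
    VELOCITY_OUT_LIF,
)
from .neurons import AdExParams, LIFParams

__all__ = ["default_run_config", "load_config", "save_config", "encoder_from_config"]


def default_run_config() -> dict[str, Any]:
    """Built-in defaults as a plain, YAML-serializable mapping."""
    return {
        "dt": DEFAULT_DT,
        "plate": {
            "N_h": 50,
            "theta_ol": 0.1,
            "gain": 50.0,
            "extended": True,
        },
        "adex": asdict(AdExParams()),
        "pos_lif": {"tau": POSITION_LIF.tau, "omega": POSITION_LIF.omega},
        "hp_lif": {"tau": VELOCITY_HP_LIF.tau, "omega": VELOCITY_HP_LIF.omega},
        "vel_out_lif": {"tau": VELOCITY_OUT_LIF.tau, "omega": VELOCITY_OUT_LIF.omega},
        "seed": 0,
    }


def _merge(base: dict, override: Mapping | None) -> dict:
    if not override:
        return base
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Defaults, optionally updated from a YAML file, then from overrides."""
    cfg = default_run_config()
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides)


def save_config(path: str | Path, cfg: Mapping) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


def encoder_from_config(
    cfg: Mapping,
    working_range: tuple[float, float],
    joint_label: str = "alpha",
    leg_label: str = "R1",
) -> JointEncoderConfig:
    """Build a per-joint encoder from a run-config mapping."""
    plate_cfg = cfg["plate"]
    plate = build_plate(
        working_range,
        N_h=int(plate_cfg["N_h"]),
        theta_ol=float(plate_cfg["theta_ol"]),
        gain=float(plate_cfg["gain"]),
        extended=bool(plate_cfg["extended"]),
    )
    adex_cfg = {k: v for k, v in cfg["adex"].items()}
    return JointEncoderConfig(
        plate=plate,
        adex=AdExParams(**adex_cfg),
        pos_lif=LIFParams(**cfg["pos_lif"]),
        hp_lif=LIFParams(**cfg["hp_lif"]),
        vel_out_lif=LIFParams(**cfg["vel_out_lif"]),
        dt=float(cfg["dt"]),
        joint_label=joint_label,
        leg_label=leg_label,
    )
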