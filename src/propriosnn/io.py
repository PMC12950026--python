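"""Serialization of spike trains, rate/voltage traces and run bundles."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

from .neurons import SpikeTrain
from .network import LayerOutputs

__all__ = [
    "write_spike_csv",
    "read_spike_csv",
    "write_voltage_csv",
    "save_outputs_h5",
    "load_outputs_h5",
    "config_hash",
    "write_manifest",
]


def write_spike_csv(path: str | Path, trains: Iterable[SpikeTrain]) -> None:
    """Two-column CSV of (neuron_id, spike_time_ms), one row per spike."""
    rows = []
    for tr in trains:
        for t in tr.spike_times:
            rows.append((tr.neuron_id, t))
    pd.DataFrame(rows, columns=["neuron_id", "spike_time_ms"]).to_csv(
        path, index=False
    )


def read_spike_csv(path: str | Path, duration: float) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(grp["spike_time_ms"].to_numpy(), duration, str(nid))
        for nid, grp in df.groupby("neuron_id", sort=False)
    ]


def write_voltage_csv(
    path: str | Path, t: np.ndarray, V: np.ndarray, w: np.ndarray | None = None
) -> None:
    cols = {"t_ms": t, "V_mV": V}
    if w is not None:
        cols["w_pA"] = w
    pd.DataFrame(cols).to_csv(path, index=False)


def _write_train(group: h5py.Group, name: str, train: SpikeTrain) -> None:
    ds = group.create_dataset(name, data=train.spike_times)
    ds.attrs["duration_ms"] = train.duration
    ds.attrs["neuron_id"] = train.neuron_id


def save_outputs_h5(
    path: str | Path, outputs: Mapping[tuple[str, str], LayerOutputs]
) -> None:
    """Hierarchical bundle keyed leg/joint/neuron of all spike trains."""
    with h5py.File(path, "w") as f:
        for (leg, joint), out in outputs.items():
            grp = f.require_group(f"{leg}/{joint}")
            sens = grp.create_group("sensory")
            for tr in out.sensory:
                _write_train(sens, tr.neuron_id, tr)
            for name in ("pos_plus", "pos_minus", "vel_plus", "vel_minus"):
                _write_train(grp, name, getattr(out, name))


def load_outputs_h5(path: str | Path) -> dict[tuple[str, str], LayerOutputs]:
    out: dict[tuple[str, str], LayerOutputs] = {}
    with h5py.File(path, "r") as f:
        for leg in f:
            for joint in f[leg]:
                grp = f[leg][joint]

                def read(ds) -> SpikeTrain:
                    return SpikeTrain(
                        ds[()],
                        float(ds.attrs["duration_ms"]),
                        str(ds.attrs["neuron_id"]),
                    )

                sensory = [read(grp["sensory"][k]) for k in sorted(
                    grp["sensory"], key=lambda s: (len(s), s)
                )]
                out[(leg, joint)] = LayerOutputs(
                    sensory,
                    read(grp["pos_plus"]),
                    read(grp["pos_minus"]),
                    read(grp["vel_plus"]),
                    read(grp["vel_minus"]),
                )
    return out


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, config: Mapping, seed: int | None = None) -> None:
    """Run manifest: full config, its hash, and the seed, for reproduction."""
    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
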