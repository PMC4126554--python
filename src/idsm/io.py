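"""Plain-text persistence: node snapshots and trajectory records.

Node snapshots are flat CSV files (one row per node: id, t_created, w,
p_0..p_{D-1}, v_0..v_{D-1}) with a JSON sidecar carrying the medium
parameters, dimensionality, motor indices and normalization ranges.
Floats are written with shortest round-trip precision so a save/load
cycle is bit-exact.  Trajectory records are CSV with a JSON sidecar of
body/arena metadata.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import IDSMParams, IDSMState

__all__ = [
    "save_nodes",
    "load_nodes",
    "save_trajectory",
    "load_trajectory",
    "sidecar_path",
]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".meta.json")


def _fmt(x: float) -> str:
    return repr(float(x))


def save_nodes(idsm: IDSMState, path, extra_meta: dict | None = None,
               normalization=None) -> None:
    """Write the node collection as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    d = idsm.dim
    cols = (["id", "t_created", "w"]
            + [f"p_{j}" for j in range(d)] + [f"v_{j}" for j in range(d)])
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for i in range(idsm.n_nodes):
            row = ([str(i), _fmt(idsm.t_created[i]), _fmt(idsm.w[i])]
                   + [_fmt(x) for x in idsm.p[i]]
                   + [_fmt(x) for x in idsm.v[i]])
            fh.write(",".join(row) + "\n")
    meta = {
        "dim": d,
        "motor_indices": list(idsm.motor_indices),
        "t": idsm.t,
        "params": dataclasses.asdict(idsm.params),
    }
    if normalization is not None:
        meta["normalization"] = {"raw_min": list(map(float, normalization.raw_min)),
                                 "raw_max": list(map(float, normalization.raw_max))}
    if extra_meta:
        meta.update(extra_meta)
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_nodes(path) -> IDSMState:
    """Rebuild a medium from a node snapshot and its sidecar (bit-exact)."""
    path = Path(path)
    meta = json.loads(sidecar_path(path).read_text())
    params = IDSMParams(**meta["params"])
    idsm = IDSMState(meta["dim"], params, meta["motor_indices"], t=meta["t"])
    df = pd.read_csv(path, float_precision="round_trip")
    d = idsm.dim
    for _, row in df.iterrows():
        idsm.add_node(np.array([row[f"p_{j}"] for j in range(d)]),
                      np.array([row[f"v_{j}"] for j in range(d)]),
                      w=row["w"], t_created=row["t_created"])
    return idsm


def save_trajectory(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    df.to_csv(path, index=False)
    if meta is not None:
        sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), float_precision="round_trip")
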