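"""Run archives: self-contained HDF5 records of an evolution run.

An archive stores the experiment configuration (as YAML text), the
per-generation best fitness, the best genome's parameter values, the
final directional tuning and any derived metrics, together with the
master seed — enough to reproduce the run's summary numbers exactly
with a deterministic backend.
"""

from __future__ import annotations

import json
from typing import Any

import h5py
import numpy as np
import yaml

__all__ = ["save_archive", "load_archive", "summary_json",
           "save_population", "load_population",
           "save_traces", "load_traces", "save_voltage_csv",
           "export_tuning_csv", "export_primitives_csv"]


def _write_group(grp: h5py.Group, data: dict) -> None:
    for key, val in data.items():
        if isinstance(val, dict):
            _write_group(grp.create_group(key), val)
        elif isinstance(val, (list, tuple)) and val and isinstance(val[0], str):
            grp.create_dataset(key, data=np.array(val, dtype=h5py.string_dtype()))
        elif isinstance(val, (np.ndarray, list, tuple)):
            grp.create_dataset(key, data=np.asarray(val, dtype=float))
        elif isinstance(val, str):
            grp.attrs[key] = val
        elif isinstance(val, (bool, int, float, np.integer, np.floating)):
            grp.attrs[key] = val
        elif val is None:
            grp.attrs[key] = "__none__"
        else:
            raise TypeError(f"cannot serialize {key!r} of type {type(val)}")


def _read_group(grp: h5py.Group) -> dict:
    out: dict[str, Any] = {}
    for key, val in grp.attrs.items():
        out[key] = None if (isinstance(val, str) and val == "__none__") else \
            (val.item() if isinstance(val, np.generic) else val)
    for key, val in grp.items():
        if isinstance(val, h5py.Group):
            out[key] = _read_group(val)
        else:
            arr = val[...]
            if arr.dtype.kind in ("S", "O"):
                out[key] = [x.decode() if isinstance(x, bytes) else str(x) for x in arr]
            else:
                out[key] = arr
    return out


def save_archive(archive: dict, path) -> None:
    """Write a run archive (nested dict of arrays/scalars/strings) to HDF5."""
    with h5py.File(path, "w") as f:
        _write_group(f, archive)


def load_archive(path) -> dict:
    with h5py.File(path, "r") as f:
        return _read_group(f)


_POPULATION_UNITS = {
    "center_x": "um", "center_y": "um", "size_x": "um", "size_y": "um",
    "orientation": "rad", "rise_time": "ms", "decay_time": "ms",
    "response_delay": "ms", "syn_weight": "dimensionless",
    "surround_strength": "dimensionless", "dep_tau": "ms", "fac_tau": "ms",
    "dep_amp": "dimensionless", "fac_amp": "dimensionless",
}


def save_population(cells, path) -> None:
    """Serialize a presynaptic population as YAML, one record per cell."""
    import dataclasses

    def _plain(d: dict) -> dict:
        return {k: (float(v) if isinstance(v, (np.floating, float))
                    else bool(v) if isinstance(v, (np.bool_, bool))
                    else int(v) if isinstance(v, (np.integer, int)) else v)
                for k, v in d.items()}

    records = []
    for cell in cells:
        rec = {
            "cell_id": int(cell.cell_id), "group_id": int(cell.group_id),
            "polarity": cell.polarity, "mode": cell.mode,
            "syn_weight": float(cell.syn_weight),
            "surround_strength": float(cell.surround_strength),
            "center": _plain(dataclasses.asdict(cell.center)),
            "plasticity": _plain(dataclasses.asdict(cell.plasticity)),
        }
        if cell.surround is not None:
            rec["surround"] = _plain(dataclasses.asdict(cell.surround))
        records.append(rec)
    with open(path, "w") as fh:
        yaml.safe_dump({"units": _POPULATION_UNITS, "cells": records}, fh,
                       sort_keys=False)


def load_population(path):
    from .receptive_fields import PlasticityParams, PresynapticCell, RFComponent

    with open(path) as fh:
        data = yaml.safe_load(fh)
    cells = []
    for rec in data["cells"]:
        cells.append(PresynapticCell(
            center=RFComponent(**rec["center"]),
            surround=RFComponent(**rec["surround"]) if "surround" in rec else None,
            syn_weight=rec["syn_weight"],
            surround_strength=rec["surround_strength"],
            plasticity=PlasticityParams(**rec["plasticity"]),
            polarity=rec["polarity"], group_id=rec["group_id"],
            mode=rec["mode"], cell_id=rec["cell_id"]))
    return cells


def save_traces(values: np.ndarray, dt: float, path, name: str = "traces") -> None:
    """Write a (time, cells) trace matrix to HDF5 with dt (ms) metadata."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset(name, data=np.asarray(values, dtype=float),
                             compression="gzip")
        d.attrs["dt"] = dt


def load_traces(path, name: str = "traces"):
    with h5py.File(path, "r") as f:
        d = f[name]
        return d[...], float(d.attrs["dt"])


def save_voltage_csv(trace, path) -> None:
    """Somatic voltage trace as two-column CSV (time ms, V mV)."""
    data = np.column_stack([trace.times, trace.v])
    np.savetxt(path, data, delimiter=",", header="time_ms,v_mV", comments="")


def export_tuning_csv(directions, responses_per_speed: dict, path) -> None:
    """Per-direction responses, one column per speed, as CSV."""
    speeds = sorted(responses_per_speed)
    cols = [np.asarray(directions, dtype=float)]
    cols += [np.asarray(responses_per_speed[s], dtype=float) for s in speeds]
    header = "direction_rad," + ",".join(f"R_speed_{s}" for s in speeds)
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header,
               comments="")


def export_primitives_csv(coords_list, path) -> None:
    """Primitive-space coordinates of a set of circuits as CSV."""
    with open(path, "w") as fh:
        fh.write("x,y,x_inh,y_inh,dsi,present\n")
        for c in coords_list:
            fh.write(f"{c.x},{c.y},{'' if c.x_inh is None else c.x_inh},"
                     f"{'' if c.y_inh is None else c.y_inh},"
                     f"{'' if c.dsi is None else c.dsi},"
                     f"{'|'.join(sorted(c.present))}\n")


def summary_json(archive: dict, path=None) -> str:
    """Flat JSON summary of an archive (config + headline numbers)."""

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    text = json.dumps(_clean(archive), indent=2, default=str)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
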