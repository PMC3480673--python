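"""Readers/writers: VTK legacy ASCII, CSV tables, HDF5 mesh container, JSON."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .electrics import ActivationMap
from .indices import RingStrainSeries
from .synthetic_heart import SEGMENTS_LV, HeartMesh

_SEG_CODES = {name: i for i, name in enumerate(SEGMENTS_LV + ("rv_free_wall",))}


def write_vtk_mesh(mesh: HeartMesh, path: str | Path,
                   point_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK unstructured grid (hexahedron cells) with cell data.

    Cell data: fiber components, layer index, integer-coded segment label.
    Point data: surface tag indicators plus any user-supplied scalars.
    """
    lines = ["# vtk DataFile Version 3.0", "cardiosync biventricular mesh",
             "ASCII", "DATASET UNSTRUCTURED_GRID"]
    lines.append(f"POINTS {mesh.n_nodes} float")
    lines.extend(" ".join(f"{v:.6g}" for v in p) for p in mesh.nodes)
    E = mesh.n_elements
    lines.append(f"CELLS {E} {E * 9}")
    lines.extend("8 " + " ".join(str(i) for i in conn) for conn in mesh.elements)
    lines.append(f"CELL_TYPES {E}")
    lines.extend(["12"] * E)

    lines.append(f"CELL_DATA {E}")
    if mesh.fibers is not None:
        for ax, name in enumerate(("fiber_x", "fiber_y", "fiber_z")):
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.6g}" for v in mesh.fibers[:, ax])
    lines.append("SCALARS layer int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(v) for v in mesh.layer)
    if mesh.segment is not None:
        lines.append("SCALARS segment int 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(str(_SEG_CODES.get(s, -1)) for s in mesh.segment)

    pdata = dict(point_data or {})
    for tag, quads in mesh.surfaces.items():
        ind = np.zeros(mesh.n_nodes, dtype=int)
        if len(quads):
            ind[np.unique(quads.ravel())] = 1
        pdata[f"tag_{tag}"] = ind
    lines.append(f"POINT_DATA {mesh.n_nodes}")
    for name, arr in pdata.items():
        arr = np.asarray(arr)
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{float(v):.6g}" for v in arr)
    Path(path).write_text("\n".join(lines) + "\n")


def write_activation_csv(amap: ActivationMap, path: str | Path) -> None:
    pd.DataFrame({"node_id": np.arange(len(amap.times)),
                  "t_act_ms": amap.times}).to_csv(path, index=False)


def write_ring_series_csv(series: RingStrainSeries, path: str | Path) -> None:
    """Long-format CSV: (frame_ms, layer, sample_index, angle_rad, ecc)."""
    rows = []
    n_sl, n_fr, n_sm = series.values.shape
    times = series.times if series.times is not None else np.arange(n_fr, dtype=float)
    layers = series.layers or tuple(range(n_sl))
    for li in range(n_sl):
        for fi in range(n_fr):
            for si in range(n_sm):
                rows.append((times[fi], layers[li], si, series.angles[si],
                             series.values[li, fi, si]))
    pd.DataFrame(rows, columns=["frame_ms", "layer", "sample_index",
                                "angle_rad", "ecc"]).to_csv(path, index=False)


def save_mesh_h5(mesh: HeartMesh, path: str | Path) -> None:
    """Compact binary mesh container for pipeline reuse."""
    with h5py.File(path, "w") as f:
        f["nodes"] = mesh.nodes
        f["elements"] = mesh.elements
        f["layer"] = mesh.layer
        f["grid_index"] = mesh.grid_index
        f["part"] = np.array([s.encode() for s in mesh.part])
        if mesh.segment is not None:
            f["segment"] = np.array([s.encode() for s in mesh.segment])
        if mesh.fibers is not None:
            f["fibers"] = mesh.fibers
        g = f.create_group("surfaces")
        for tag, quads in mesh.surfaces.items():
            g[tag] = quads


def write_report_json(report_dict: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(report_dict, indent=2, default=default) + "\n")
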