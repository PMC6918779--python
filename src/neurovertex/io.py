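"""Snapshot and table serialisation.

Meshes are stored as JSON (box, vertex array, cell loops as vertex-index
lists, optional per-cell state) and per-cell summaries as flat CSV, one
row per cell: id, area, perimeter, n_sides, centroid coordinates, clone id,
domain and cycle phase.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import CellState, DOMAIN_NAMES
from .mesh import Mesh

__all__ = ["mesh_to_json", "mesh_from_json", "cells_dataframe", "save_snapshot", "load_snapshot"]


def mesh_to_json(mesh: Mesh, state: CellState | None = None) -> dict:
    doc = {
        "box": mesh.box.tolist(),
        "vertices": mesh.vertices.tolist(),
        "cells": [list(map(int, c)) for c in mesh.cells],
    }
    if state is not None:
        doc["state"] = {
            "t0": state.t0.tolist(),
            "g": state.g.tolist(),
            "t_T": state.t_T.tolist(),
            "differentiating": state.differentiating.astype(int).tolist(),
            "clone_id": state.clone.tolist(),
            "domain": state.domain.tolist(),
        }
    return doc


def mesh_from_json(doc: dict) -> tuple[Mesh, CellState | None]:
    mesh = Mesh(np.asarray(doc["vertices"], dtype=float), doc["cells"], doc["box"])
    state = None
    if "state" in doc:
        s = doc["state"]
        state = CellState(len(mesh.cells))
        state.t0 = np.asarray(s["t0"], dtype=float)
        state.g = np.asarray(s["g"], dtype=float)
        state.t_T = np.asarray(s["t_T"], dtype=float)
        state.differentiating = np.asarray(s["differentiating"], dtype=bool)
        state.clone = np.asarray(s["clone_id"], dtype=np.int64)
        state.domain = np.asarray(s["domain"], dtype=np.int8)
    return mesh, state


def save_snapshot(path: str | Path, mesh: Mesh, state: CellState | None = None) -> None:
    Path(path).write_text(json.dumps(mesh_to_json(mesh, state)))


def load_snapshot(path: str | Path) -> tuple[Mesh, CellState | None]:
    return mesh_from_json(json.loads(Path(path).read_text()))


def _phase_name(t_tilde: float, t_T: float) -> str:
    u = t_tilde / t_T
    if u < 0.55:
        return "G1"
    if u < 0.55 + 0.40 / 3:
        return "S"
    if u < 0.95:
        return "G2"
    return "M"


def cells_dataframe(mesh: Mesh, state: CellState | None = None, t: float = 0.0) -> pd.DataFrame:
    """Flat per-cell export (id, geometry, lineage, domain, phase)."""
    from .engine import _centroids

    f = mesh.flat()
    _, _, _, areas, perims = mesh.edge_geometry()
    cents = _centroids(mesh)
    out = pd.DataFrame(
        {
            "id": np.arange(mesh.n_cells),
            "area": areas,
            "perimeter": perims,
            "n_sides": f.nsides,
            "centroid_x": cents[:, 0],
            "centroid_y": cents[:, 1],
        }
    )
    if state is not None:
        out["clone_id"] = state.clone
        out["domain"] = [DOMAIN_NAMES[d] for d in state.domain]
        out["phase"] = [
            "diff" if d else _phase_name(t - t0, tt)
            for d, t0, tt in zip(state.differentiating, state.t0, state.t_T)
        ]
    return out
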