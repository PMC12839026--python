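"""Serialization helpers: YAML chamber specs, CSV tables, VTK grids.

VTK output uses the legacy ASCII structured-points format, which every
common viewer (ParaView, VisIt, pyvista) reads; fields are written as
CELL_DATA on the rasterized grid.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .geometry import ChamberSpec, DomainGrid, PillarSpec

__all__ = [
    "spec_to_yaml",
    "spec_from_yaml",
    "polygons_to_csv",
    "write_vtk_cells",
]


def spec_to_yaml(spec: ChamberSpec, path) -> None:
    """Write a chamber spec as a human-editable YAML document."""
    doc = {k: float(v) if isinstance(v, (int, float, np.floating)) else v
           for k, v in asdict(spec).items() if k != "pillars"}
    doc["pillars"] = []
    for p in spec.pillars:
        d = {k: (list(map(float, v)) if k == "anchor_position" else float(v))
             for k, v in asdict(p).items()}
        doc["pillars"].append(d)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def spec_from_yaml(path) -> ChamberSpec:
    doc = yaml.safe_load(Path(path).read_text())
    pillars = tuple(
        PillarSpec(**{**p, "anchor_position": tuple(p["anchor_position"])})
        for p in doc.pop("pillars", []))
    return ChamberSpec(pillars=pillars, **doc)


def polygons_to_csv(polygons: list[np.ndarray], path) -> None:
    """Vertex lists as CSV rows (polygon_id, vertex_id, x_mm, y_mm)."""
    import pandas as pd

    rows = []
    for k, poly in enumerate(polygons):
        for j, (x, y) in enumerate(poly):
            rows.append((k, j, x, y))
    pd.DataFrame(rows, columns=["polygon_id", "vertex_id", "x_mm", "y_mm"]
                 ).to_csv(path, index=False)


def write_vtk_cells(path, grid: DomainGrid, fields: dict[str, np.ndarray],
                    title: str = "chipflow field") -> None:
    """Legacy ASCII VTK structured-points file with per-cell scalar fields.

    Each field must be shaped (n_y, n_x); values on solid cells are written
    as stored (typically 0 or NaN-free fill).
    """
    ny, nx = grid.n_y, grid.n_x
    d = grid.cell_size
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 1",
        f"ORIGIN {grid.x0} {grid.y0} 0.0",
        f"SPACING {d} {d} {d}",
        f"CELL_DATA {nx * ny}",
    ]
    for name, arr in fields.items():
        a = np.asarray(arr)
        if a.shape != (ny, nx):
            raise ValueError(f"field {name!r} has shape {a.shape}, "
                             f"expected {(ny, nx)}")
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(" ".join(f"{v:.6e}" for v in row) for row in a)
    Path(path).write_text("\n".join(lines) + "\n")
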