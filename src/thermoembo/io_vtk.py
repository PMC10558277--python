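"""Minimal legacy-VTK (ASCII) writer for structured cell fields.

Checkpoints are written as ``STRUCTURED_POINTS`` datasets with CELL_DATA,
readable by ParaView/VisIt and by any VTK-aware library. Meshes of
dimension below 3 are padded with unit-size singleton axes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import StructuredMesh

__all__ = ["write_vtk"]


def write_vtk(path, mesh: StructuredMesh, fields: dict[str, np.ndarray]) -> None:
    """Write cell-centered scalar fields on a structured mesh.

    Field arrays are flat cell vectors in the mesh's C (row-major) cell
    ordering; VTK expects x-fastest ordering, so axes are transposed on
    output.
    """
    shape = tuple(mesh.shape) + (1,) * (3 - mesh.dim)
    spacing = tuple(mesh.spacing) + (1.0,) * (3 - mesh.dim)
    npts = tuple(s + 1 for s in shape)
    lines = [
        "# vtk DataFile Version 3.0",
        "thermoembo checkpoint",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {npts[0]} {npts[1]} {npts[2]}",
        "ORIGIN 0 0 0",
        f"SPACING {spacing[0]:g} {spacing[1]:g} {spacing[2]:g}",
        f"CELL_DATA {mesh.n_cells}",
    ]
    for name, values in fields.items():
        arr = np.asarray(values, dtype=float).reshape(shape)
        flat = arr.transpose(2, 1, 0).ravel()  # z slowest -> VTK x-fastest
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(" ".join(f"{v:.8g}" for v in flat[i:i + 6])
                     for i in range(0, len(flat), 6))
    Path(path).write_text("\n".join(lines) + "\n")
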