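"""Field export, sweep tables and run manifests.

Fields are written as legacy-ASCII VTK structured-points files (cell data on
the uniform grids both models use), sweep tables as CSV with deterministic
row ordering, and every output can be accompanied by a JSON run manifest
recording the config snapshot, seeds, solver modes and per-stage timings so
a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np


def write_vtk_structured(path, origin, spacing, cell_arrays: dict,
                         title: str = "chainlfa field") -> Path:
    """Write 2D cell-centred arrays as a legacy VTK STRUCTURED_POINTS file.

    ``cell_arrays`` maps names to (nx, ny) arrays; NaNs (masked solid
    cells) are written as-is, which standard viewers blank out.
    """
    path = Path(path)
    arrays = {k: np.asarray(v, dtype=float) for k, v in cell_arrays.items()}
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent array shapes: {shapes}")
    nx, ny = shapes.pop()
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 1",
        f"ORIGIN {origin[0]:.9e} {origin[1]:.9e} 0.0",
        f"SPACING {spacing[0]:.9e} {spacing[1]:.9e} 1.0",
        f"CELL_DATA {nx * ny}",
    ]
    for name, arr in arrays.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK cell ordering: x fastest
        lines.extend(" ".join(f"{v:.9e}" for v in arr[:, j])
                     for j in range(ny))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_flow_vtk(flow, path) -> Path:
    """Export a microscale flow field (cell-centred u, v, speed, pressure)."""
    grid = flow.grid
    uc = 0.5 * (flow.u[:-1, :] + flow.u[1:, :])
    vc = 0.5 * (flow.v[:, :-1] + flow.v[:, 1:])
    h = grid.geometry.half_width
    return write_vtk_structured(
        path, origin=(-h, -h), spacing=(grid.dx, grid.dx),
        cell_arrays={"u": uc, "v": vc, "speed": np.hypot(uc, vc),
                     "pressure": flow.p,
                     "solid_fraction": grid.solid_frac},
        title=f"stokes flow omega={flow.omega:.6g} rad/s")


def write_concentration_vtk(history, index, path, params) -> Path:
    """Export one concentration snapshot (mol/m^3 and ng/mL)."""
    grid = history.grid
    c = history.fields[index]
    h = grid.geometry.half_width
    return write_vtk_structured(
        path, origin=(-h, -h), spacing=(grid.dx, grid.dx),
        cell_arrays={"c": c, "c_ng_ml": c * params.M_analyte * 1000.0},
        title=f"antigen concentration t={history.times[index]:.6g} s")


def write_membrane_vtk(state, grid, path) -> Path:
    """Export a membrane species snapshot (c, c2, c3)."""
    return write_vtk_structured(
        path, origin=(0.0, 0.0), spacing=(grid.dx, grid.dy),
        cell_arrays={"c": state.c, "c2": state.c2, "c3": state.c3},
        title=f"membrane species t={state.time:.6g} s")


@dataclass
class RunManifest:
    """Reproducibility record attached to every CLI output."""

    command: str
    config: dict
    seeds: dict
    modes: dict
    outputs: list = dc_field(default_factory=list)
    timings_s: dict = dc_field(default_factory=dict)
    software: dict = dc_field(default_factory=lambda: {
        "package": "chainlfa 0.1.0",
        "python": platform.python_version(),
    })
    created_unix: float = dc_field(default_factory=time.time)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def time_stage(self, name: str, seconds: float) -> None:
        self.timings_s[name] = round(seconds, 3)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True))
        return path


def manifest_for(command: str, micro=None, membrane=None, seeds=None,
                 modes=None) -> RunManifest:
    config = {}
    if micro is not None:
        config["micro"] = dataclasses.asdict(micro)
    if membrane is not None:
        config["membrane"] = dataclasses.asdict(membrane)
    return RunManifest(command=command, config=config, seeds=seeds or {},
                       modes=modes or {})
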