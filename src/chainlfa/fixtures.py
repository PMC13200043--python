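"""Scale presets: CI-sized fixtures versus the full desk configuration.

The ``desk`` scale is the study configuration itself (full 360 s runs,
medium grids).  The ``ci`` scale shortens the simulated time to 36 s and
coarsens the grids so that every invariant of the model can be exercised in
seconds; it changes problem *size*, never physics or parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import MicroGeometry, build_chain_grid
from .grid import MicroGrid, generate_grid
from .membrane import MembraneGrid
from .parameters import MembraneModelParams, MicroModelParams

DEFAULT_FIXTURE_SEED = 20260305


@dataclass
class FixtureBundle:
    """Pre-built parameter sets, geometry and grids at one scale."""

    scale: str
    seed: int
    micro: MicroModelParams
    membrane: MembraneModelParams
    geometry: MicroGeometry
    micro_grid: MicroGrid
    membrane_grid: MembraneGrid
    micro_dt: float          # static-run time step (s)
    membrane_dt: float


def generate_fixtures(scale: str = "ci",
                      seed: int = DEFAULT_FIXTURE_SEED) -> FixtureBundle:
    """Build the fixture bundle for ``scale`` in {'ci', 'desk'}.

    Identical seeds give byte-identical geometry (chain orientations are
    the only randomness).
    """
    if scale == "ci":
        micro = MicroModelParams(t_end=36.0)
        membrane = MembraneModelParams()
        geometry = build_chain_grid(micro, "seeded_random", seed=seed)
        return FixtureBundle(
            scale=scale, seed=seed, micro=micro, membrane=membrane,
            geometry=geometry,
            micro_grid=generate_grid(geometry, "coarse"),
            membrane_grid=MembraneGrid(params=membrane, nx=140, ny=4),
            micro_dt=1.0, membrane_dt=0.5)
    if scale == "desk":
        micro = MicroModelParams()          # t_end = 360 s
        membrane = MembraneModelParams()
        geometry = build_chain_grid(micro, "seeded_random", seed=seed)
        return FixtureBundle(
            scale=scale, seed=seed, micro=micro, membrane=membrane,
            geometry=geometry,
            micro_grid=generate_grid(geometry, "medium"),
            membrane_grid=MembraneGrid(params=membrane, nx=560, ny=6),
            micro_dt=1.0, membrane_dt=0.125)
    raise ValueError(f"unknown scale {scale!r}; choose 'ci' or 'desk'")
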