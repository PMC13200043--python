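"""Chain-stirred Stokes flow and the removal-vs-frequency sweep.

Solves the creeping flow driven by the rotating chain walls at 3 Hz (tip
speed omega*L/2 ~ 1e-5 m/s), exports the field to VTK, then sweeps the
rotation frequency.  With the tabulated diffusivity of a 15 kDa protein
the domain is already well mixed at 0 Hz, so the removal stays at the
reaction-limited ceiling across the sweep — rotation changes the flow
field dramatically but not the capture, under a strictly mass-conserving
wall flux.
"""

import numpy as np

from chainlfa import (MicroModelParams, build_chain_grid, frequency_sweep,
                      generate_grid, solve_flow)
from chainlfa.io import write_flow_vtk

params = MicroModelParams(freq=3.0)
geometry = build_chain_grid(params, "seeded_random")
grid = generate_grid(geometry, "coarse")
flow = solve_flow(grid, params, params.omega)
print(f"3 Hz flow: max speed {flow.max_speed():.3e} m/s "
      f"(rigid tip speed {params.omega * params.L_chain / 2:.3e} m/s), "
      f"divergence residual {flow.div_residual:.2e}")
write_flow_vtk(flow, "flow_3hz.vtk")
print("wrote flow_3hz.vtk (velocity, speed, pressure cell data)")

df = frequency_sweep(params, [0.0, 1.0, 3.0, 10.0], resolution="coarse")
print("\n", df[["freq_hz", "removal_pct", "residual_ng_ml"]].to_string(index=False))
print("\nRemoval is flat in frequency: stirring cannot beat a capture")
print("process that is already reaction-limited at this diffusivity.")
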