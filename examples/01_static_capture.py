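"""Static antigen capture by nine nanochains in a 15 um drop of buffer.

Builds the default chain geometry, solves the pure-diffusion uptake problem
for 360 s and compares the removal percentage against the well-mixed
exponential bound.  Because a 15 um domain homogenizes by diffusion in
about a second, the computed removal sits essentially at that bound: the
process is limited by the chains' binding capacity, not by transport.
"""

import numpy as np

from chainlfa import (MicroModelParams, build_chain_grid, generate_grid,
                      removal_percentage, residual_ng_per_ml,
                      simulate_binding, solve_flow)

params = MicroModelParams()
geometry = build_chain_grid(params, "seeded_random")
grid = generate_grid(geometry, "coarse")
flow = solve_flow(grid, params, omega=0.0)
history = simulate_binding(flow, params, output_times=[0.0, 180.0, 360.0])

print("time (s)  removal (%)  residual (ng/mL)")
for t, field in zip(history.times, history.fields):
    print(f"{t:7.0f}   {removal_percentage(field, grid, params):10.2f}"
          f"   {residual_ng_per_ml(field, grid, params):14.4f}")

P_tot = 9 * 2 * (params.L_chain + params.W_chain)
rate = params.k_on * params.Gamma_max * P_tot / params.fluid_area
c_wm = params.C_bulk * np.exp(-rate * 360.0)
bound = (1 - c_wm * params.fluid_area
         / (params.C_bulk * params.domain_size**2)) * 100
print(f"\nwell-mixed (reaction-limited) bound at 360 s: {bound:.2f} %")
print("The simulated removal approaches this bound from below: capture is")
print("reaction-limited, so the chains' surface capacity sets the ceiling.")
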