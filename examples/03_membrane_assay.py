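"""Lateral-flow membrane run: wetting, transport and cooperative capture.

Simulates the 7 mm strip at N_Abs = 600 with cooperative recruitment on and
off.  The Lucas-Washburn front crosses the strip in ~25 s; until then the
dry region throttles the Darcy flux, so the nanochain front reaches the
middle of the membrane only around t = 31 s.  Switching the recruitment
term on shifts captured complexes toward the upstream test-line edge,
which the asymmetry index quantifies.
"""

from chainlfa import (MembraneGrid, MembraneModelParams, asymmetry_index,
                      front_position, min_free_antibody,
                      simulate_membrane_assay, testline_complex_integral)

params = MembraneModelParams()
grid = MembraneGrid(params=params, nx=280, ny=4)

for t in (0.0, 22.0, 31.0):
    print(f"wetting front at t={t:5.1f} s: {front_position(t, params) * 1e3:6.3f} mm")

for kr in (0.0, 7e4):
    hist = simulate_membrane_assay(params, N_Abs=600.0, k_recruit=kr,
                                   grid=grid, dt=0.25,
                                   output_times=[0.0, 31.0, 360.0])
    mid = hist.state_at(31.0)
    wetted = mid.c[:, 0] > 0.5 * params.C0_mol
    front_mm = (wetted.nonzero()[0].max() + 1) * grid.dx * 1e3 if wetted.any() else 0.0
    final = hist.states[-1]
    print(f"\nk_recruit = {kr:g}:")
    print(f"  nanochain front at 31 s:      {front_mm:.2f} mm")
    print(f"  test-line complex at 360 s:   "
          f"{testline_complex_integral(final, grid):.3e} mol/m")
    print(f"  min free antibody at 360 s:   "
          f"{min_free_antibody(final, grid):.3e} mol/m^3 (>= 5e-6: non-saturating)")
    print(f"  asymmetry index at 360 s:     {asymmetry_index(final, grid):+.3f}")

print("\nRecruitment leaves the antibody pool non-saturated but pulls the")
print("captured complexes toward the upstream edge (positive asymmetry).")
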