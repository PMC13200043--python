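# chainlfa

Simulation toolkit for **rotating magnetic nanochain-enhanced lateral flow
immunoassays** (LFAs).  Magnetic nanochains — micron-scale chains of
magnetic nanoparticles functionalized with antibodies — rotate synchronously
with an external rotating magnetic field and act as micro-stirrers that are
meant to accelerate antigen capture.  `chainlfa` implements the two
reaction–transport models used to analyse this system, for researchers in
biosensing and microfluidic assay design:

1. **Microscale model** — steady Stokes flow in a 15 µm square stirred by
   nine rotating rectangular nanochains (rigid-rotation wall velocities
   `u = (−ω(y−y_c), ω(x−x_c))`), coupled to transient antigen
   advection–diffusion with Langmuir-type wall uptake
   `J = k_on·c·Γ_max·(1 − c/K_D)`, and the removal metric
   `removal = (1 − ∫c dA / (C_bulk·S²))·100 %`.
2. **Membrane model** — a 7 mm nitrocellulose strip wetted by a
   Lucas–Washburn front `x_f = √(2 k P_cap (t+0.1)/(η ε))`, Darcy flow on
   wetness-modulated permeability, and three-species cooperative capture at
   the test line with rates `R_c3 = kon·c·c2 − koff·c3 + k_recruit·c·c3`,
   where the `k_recruit` term models magnetic recruitment of flowing chains
   by already-captured complexes.

It also ships the capture-efficiency data-analysis formulas of the
companion supernatant-depletion experiment
(`efficiency = (C0 − Cs)/C0 · 100 %`, fold improvement as the plain ratio).

Solvers are hand-written on structured staggered grids (volume-penalized
MAC Stokes with a Schur-complement CG, conservative finite-volume
transport) over `numpy`/`scipy` sparse linear algebra; see
`docs/methods.md` for the numerics and their verification against closed
forms.

## Worked example

```bash
python examples/01_static_capture.py
```

```
time (s)  removal (%)  residual (ng/mL)
      0         0.63           0.9942
    180        16.47           0.8357
    360        29.80           0.7024

well-mixed (reaction-limited) bound at 360 s: 29.82 %
```

A 1 ng/mL solution of a 15 kDa antigen loses ~30 % of its free antigen to
the nine chains in six minutes.  The removal at `t = 0` is 0.63 % because
the metric normalizes by the full square while the chains occupy 0.63 % of
it; the residual column is the domain-average concentration in ng/mL.  The
final value sits at the *well-mixed bound*: with the tabulated diffusivity
the 15 µm domain mixes in under a second, so capture is limited by the
chains' binding kinetics, not by transport — which is why the simulated
removal stays near 29.8 % at every rotation frequency under a
mass-conserving wall flux (see `examples/02_rotating_flow_and_sweep.py`
and the discussion in `docs/methods.md`).

The membrane example prints the wetting/transport timeline and the effect
of cooperative recruitment:

```bash
python examples/03_membrane_assay.py
```

```
k_recruit = 70000:
  nanochain front at 31 s:      3.70 mm
  test-line complex at 360 s:   5.798e-12 mol/m
  min free antibody at 360 s:   8.742e-06 mol/m^3 (>= 5e-6: non-saturating)
  asymmetry index at 360 s:     +0.145
```

The test line never saturates (free antibody stays above half its initial
value), and switching recruitment on shifts complexes toward the upstream
test-line edge — the asymmetry index quantifies the spatial signature of
cooperative capture.

## Command line

A thin CLI wraps the library:

```bash
chainlfa micro sweep --freqs 0:20:1 --csv sweep.csv
chainlfa membrane run --n-abs 600 --k-recruit 7e4 --out species.vtk
chainlfa metrics capture --csv measurements.csv
```

Outputs are CSV tables and legacy-ASCII VTK fields, each with a JSON run
manifest (config snapshot, seeds, solver modes, timings) for bit-exact
reruns.

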