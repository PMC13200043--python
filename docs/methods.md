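# Methods

`chainlfa` simulates the two transport problems behind rotating
magnetic-nanochain enhancement of lateral flow immunoassays (LFAs): the
microscale stirring of an antigen solution by rotating nanochains, and the
capillary-driven migration of nanochains through a nitrocellulose strip
with cooperative capture at the test line.  This note documents the models,
the numerical choices, and what the results do and do not show.

## Microscale model: chain-stirred antigen capture

### Physics

A 15 µm square of buffer contains nine rigid rectangular nanochains
(1.05 µm x 0.15 µm) on a 3x3 grid with 5 µm pitch.  Each chain rotates
about its grid node; the geometry stays fixed and the rotation enters only
through the wall velocity

    u_wall = (-omega (y - y_c), omega (x - x_c)),    omega = 2 pi f,

which is the standard rotating-wall idealization of a synchronously
rotating stirrer.  The chain Reynolds number is ~1e-5 at 3 Hz, so the flow
is steady Stokes flow; the solver exposes the full linearity in omega (one
solve per geometry, exact rescaling per frequency).

Antigen (a 15 kDa protein at 1 ng/mL = 6.67e-8 mol/m³, diffusivity
1.1e-10 m²/s from Stokes–Einstein) is advected and diffuses in the fluid,
with uptake on antibody-coated chain walls at flux magnitude

    J = k_on c Gamma_max (1 - c / K_D),      K_D = k_off / k_on.

Two bookkeeping conventions deserve comment:

* The saturation factor compares the *bulk* concentration with K_D rather
  than tracking surface occupancy.  This is replicated deliberately: with
  the default parameters K_D = 0.1 mol/m³ >> C_bulk, so the factor is
  1 - 7e-7 and numerically irrelevant, but it is the model as defined.
* The prescribed rigid-rotation wall velocity has a nonzero component
  normal to the flat rectangle faces, so a species boundary condition must
  decide whether that normal velocity carries antigen through the wall.
  `wall_mode='prescribed'` (default) lets only the uptake flux cross the
  wall — mass is conserved up to uptake.  `wall_mode='advective'` adds the
  boundary-trace advective exchange (u·n)c, emulating the semantics of
  general-purpose FEM tools in which a flux boundary condition constrains
  only the diffusive flux.  Both are first-class and reported by the
  sweep tools.

### The well-mixed ceiling

Two scales decide the regime.  The uptake velocity k_on Gamma_max is
1e-8 m/s; the diffusive conductance D/L over inter-chain distances is
~4e-5 m/s.  Uptake is therefore reaction-limited by more than three orders
of magnitude, and the domain homogenizes by diffusion in well under a
second.  A well-mixed bath with the same wall area obeys

    c(t) = C_bulk exp(-k_on Gamma_max P_tot / A_fluid t),

with P_tot = 9·2(L+W) the total chain perimeter and A_fluid the fluid
area; at 360 s this gives ~29.8 % removal (normalized over the full
square).  Any simulation whose only sink is the uptake flux is bounded by
this ceiling regardless of stirring — and since the static case already
sits within 0.1 pp of the ceiling, rotation cannot measurably change the
removal under the default (mass-conserving) wall convention.  The
simulated removal is flat at ~29.8 % across 0–10 Hz.  The 'advective'
convention does not change this materially: the net trace exchange around
a rotating chain nearly cancels.  Only a convention in which fluid
re-entering through a chain wall carries zero concentration breaks the
ceiling, and it overshoots to ~100 % removal at any frequency.  Removal
figures substantially above the ceiling therefore cannot be reproduced
from the tabulated physics; this package reports the honestly computed
values.

### Discretization

Structured staggered (MAC) grids at named resolutions (96/192/320 cells
per side).  Chains are represented by solid volume fractions
(supersampled 4x4 per cell) feeding an Angot-type volume penalization of
the Stokes operator with drag K = mu/(1e-4 dx²) (penetration depth 1 % of
a cell).  The saddle-point system is solved by conjugate gradients on the
pressure Schur complement with the two penalized vector-Laplacian blocks
factorized once (sparse LU); divergence is driven to 1e-10 of the forcing
scale.  A rotating-disk benchmark (closed form u_theta = omega R²/r)
reproduces the azimuthal speed within 2 % at r ≤ 3R on a 480² grid.

Transport uses conservative finite volumes with central face
interpolation — the cell Péclet number is u dx/D ≲ 0.02 even at 10 Hz, so
no upwinding or stabilization is needed and the static oracle is not
polluted by numerical diffusion.  Time stepping is Crank–Nicolson with a
sparse LU factorized per step size; the default step is 1 s for static
runs and min(0.25, 0.5/f) s under rotation (halving the step at 10 Hz
changes removal by <0.01 pp).  The wall uptake enters per interface face
with a per-chain correction factor P_true/P_stair so that the integrated
uptake matches the exact rectangle perimeter instead of the stair-step
boundary length; this makes the removal essentially grid-independent
(coarse vs medium differ by <0.1 pp).

The removal metric normalizes by the full domain square,

    removal = (1 - ∫c dA / (C_bulk S²)) · 100 %,

so a uniform field at C_bulk reports 0.63 % (the chain-occupied area
fraction), and the residual concentration in ng/mL maps C_bulk to
~1.0 ng/mL through the 15 kDa molar mass.  The integral weights each cell
by its fluid fraction, with boundary-cell slivers taken at the
neighbouring fluid concentration.

### Chain orientations

The nine rotation angles are not part of the tabulated configuration
("varies by chain"); the default draws them uniformly on [0, pi) from a
documented seed (20260305), and an `aligned` mode (all angles zero) exists
for analytic checks.  Removal depends only weakly on orientation
(≲0.1 pp between seeds) because capture is reaction-limited.  A `corner`
pivot option reproduces the behaviour of drawing tools that rotate a
corner-based rectangle about its base point, which moves the geometric
centre off the grid node and roughly doubles the wall speeds; it is not
the default.

## Membrane model: capillary transport and cooperative capture

### Physics

The strip is a 7 mm x 2.5 mm rectangle: 3 mm inlet segment, 1 mm test
line, 3 mm outlet segment, porosity 0.75, permeability 1e-13 m².  Wetting
is not solved as two-phase flow; the front advances analytically as

    x_front(t) = sqrt(2 k_perm P_cap (t + 0.1) / (eta porosity)),

with P_cap = 2 gamma/pore = 7200 Pa, and a tanh profile of width 100 µm
grades wetness from 1 (wet) to 0 (dry).  Wetness modulates the effective
permeability k_eff = k_perm (k_min + (1-k_min) w²) and nanochain
diffusivity D_eff = D0 max(w, 0.01).  Single-phase Darcy flow with inlet
pressure 25 kPa and zero outlet pressure is solved on the heterogeneous
k_eff; while any dry region remains, its k_min = 0.01 floor throttles the
flux, so the superficial velocity rises from ~4e-6 m/s to its fully-wet
value k_perm P_inlet/(eta L) = 3.6e-4 m/s when the front breaks through
at t ≈ 25 s.

This choking is what reconciles the parameter table with the published
field snapshots: although the Lucas–Washburn *moisture* front crosses the
strip by 25 s, the *nanochain* front — advected by the choked Darcy
velocity — reaches mid-membrane only near t = 31 s, exactly the reported
timing.  For this reason the default coupling is quasi-static (wetness
and Darcy flow refreshed every second); a `frozen` mode that evaluates the
flow once at a configurable wetness time exists for study-literal
replication, but freezing at t = 0 starves the test line of nanochains
entirely and cannot produce the published binding patterns.

Three species react everywhere on the strip (outside the test line the
immobile pools are zero, so the reactions are inert there):

    R_c  = -kon c c2 + koff c3 - k_recruit c c3
    R_c2 = -kon c c2 + koff c3
    R_c3 = +kon c c2 - koff c3 + k_recruit c c3

c is the mobile nanochain concentration (inflow 7e-8 mol/m³), c2 the
immobile free antibody (1e-5 mol/m³ on the test line initially), c3 the
immobile complex.  kon = N_Abs·1e4 M⁻¹s⁻¹ (N_Abs is the dimensionless
binding-efficiency sweep parameter; the M⁻¹s⁻¹ → m³ mol⁻¹ s⁻¹ conversion
is a single audited ÷1000) and k_recruit c c3 is the phenomenological
cooperative pathway: captured complexes magnetically attract flowing
chains.  With k_recruit = 0 the algebra gives d(c2+c3)/dt = 0 pointwise,
which the integrator preserves to machine precision.  The tabulated
V_chain and c3_max are stored but no printed rate law consumes them; the
config loader logs a warning when they are supplied.

### Discretization

Cell-centred finite volumes (default 560 x 6 cells; the strip is uniform
in the cross direction, the 2D grid simply keeps the geometry explicit).
Darcy: harmonic-mean face mobilities, Dirichlet inlet/outlet via half-cell
ghosts, sparse direct solve; the cross-section flux is uniform to ~1e-12.
Nanochain transport: implicit first-order upwind advection (the face
Péclet number is ~1e7, so upwinding is mandatory) with porosity-weighted
storage and porosity-weighted effective diffusion; inflow enters at C0
through the advective and half-cell diffusive flux, the outlet is a pure
upwind outflow.  Reactions are Lie-split after each transport step and
advanced with one vectorized RK4 step (largest local rate ~0.1 1/s — far
from stiff at the 0.125 s default step).  The volumetric rates are per
total membrane volume, so the mobile species sees R_c/porosity.  A
discrete mass audit (inflow − outflow − reacted − storage change) closes
to ~1e-14 relative per interval.  Halving dx and dt changes the sweep
outputs by <0.5 %.

### Asymmetry index

The published evidence for cooperativity is a spatial pattern, quantified
here as

    A = (∫ c3 upstream half − ∫ c3 downstream half) / ∫ c3

over the test line, split at its 3.5 mm midline; A = 0 for uniform
capture, +1 for capture confined upstream, and None (flagged) when no
complex exists.  Under the default conditions A rises from ~0.02–0.06
(k_recruit = 0; the small positive residue is physical depletion of c
along the line at high kon) to ~0.09–0.21 when recruitment is active.
Note that with the tabulated rate constants the recruitment pathway
(k_recruit·c3 ~ 0.08 1/s once complexes accumulate) is comparable to the
primary pathway (kon·c2 ~ 0.05–0.1 1/s), so switching it on also raises
the *total* captured complex by roughly a factor of two — the spatial
redistribution does not come for free in this parameter regime.

## Problem sizes and tolerances

Default study sizes, chosen as the package's production configuration:
microscale medium mesh (192² cells, ~37k fluid unknowns) with the
frequency-dependent step above; membrane 560 x 6 cells at dt = 0.125 s
with Darcy refreshed every 1 s.  The CI fixture scale (`generate_fixtures('ci')`)
shortens the microscale run to 36 s and coarsens both grids so the entire
invariant suite runs in minutes; it never changes physical parameters.
Stokes convergence tolerance 1e-10 (relative, Schur residual); transport
tolerances are set by the unconditionally stable implicit schemes and the
step-size studies quoted above.  Degenerate inputs are rejected with
descriptive errors: non-positive parameters, overlapping or out-of-domain
chain placements, grids too coarse to resolve the chain width,
non-positive permeability fields, zero static efficiency in the fold
ratio, and zero-complex asymmetry (flagged None rather than NaN).

## What the defaults emulate, and limitations

The defaults are the tabulated study conditions of the method (chain and
domain geometry, kinetics, sweep grids: 21 frequencies 0–20 Hz; 8 N_Abs
values x 2 k_recruit values).  The models are 2D idealizations: the
microscale model overstates surface-to-volume ratio relative to 3D and
treats chains as rigid, monodisperse and hydrodynamically independent; the
membrane model replaces the fibrous pore network by effective continuum
properties, models wetting analytically rather than as two-phase flow, and
represents magnetic recruitment as a single phenomenological rate constant
rather than resolved dipole–dipole forces.  Mechanisms that end the
validity of the rotating-wall picture above ~3 Hz (loss of synchronous
rotation, contact-time limits, shear destabilization of immunocomplexes)
are deliberately outside the model.  Passing tests therefore demonstrate
faithful implementation of these idealized models and their internal
conservation laws — not that the idealizations capture every feature of
the laboratory assay.
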