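"""Transient antigen transport and surface binding in the stirred microdomain.

Solves, in the fluid region of the chain-perforated square,

    dc/dt + u . grad c = D laplacian(c),

with initial condition c = C_bulk, no-flux outer walls, and an
antibody-uptake flux on the chain walls of magnitude

    J = k_on * c * Gamma_max * (1 - c / K_D),        K_D = k_off / k_on,

removing antigen (the printed inward-flux expression is the negative of
this).  The saturation factor uses the bulk concentration against K_D
exactly as printed — an unconventional Langmuir bookkeeping that the method
prescribes; with the default parameters K_D = 0.1 mol/m^3 >> C_bulk so the
factor is ~1 - 7e-7.

Two chain-wall flux conventions are provided (``wall_mode``):

* ``'prescribed'`` (default) — the wall exchanges antigen only through the
  uptake flux above; the rigid-rotation normal velocity on flat faces does
  not carry any species across the wall.  Mass is conserved up to the
  uptake sink.
* ``'advective'`` — in addition to the uptake flux, the advective flux
  (u . n) c crosses the chain wall with the local boundary-trace
  concentration, emulating the semantics of flux boundary conditions in
  tools that prescribe the full rigid-rotation wall velocity (whose normal
  component then advects species through the wall).  This deliberately
  breaks the mass audit: it is the identified lever behind the published
  high-frequency removal values.

Space: conservative finite volumes on the MAC grid with central face
interpolation (cell Peclet << 1 at all frequencies of interest, so no
upwinding or stabilization is needed and the static oracle is untouched).
Time: theta-scheme (Crank-Nicolson by default) with a sparse LU factorized
once per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import MicroGeometry, build_chain_grid, DEFAULT_ORIENTATION_SEED
from .grid import MicroGrid, generate_grid
from .stokes import FlowField, solve_flow

WALL_MODES = ("prescribed", "advective")


class TransportError(RuntimeError):
    """Transport solve failed (divergence or negative-concentration blowup)."""


@dataclass
class ConcentrationHistory:
    """Concentration snapshots on the grid plus integral audit series."""

    grid: MicroGrid
    times: np.ndarray                 # (nt,) output times (s)
    fields: list[np.ndarray]          # (n, n) arrays; NaN inside chains
    total_mass: np.ndarray            # (nt,) integral of c over fluid (mol/m)
    wall_uptake: np.ndarray           # (nt,) cumulative uptake (mol/m)
    wall_mode: str

    def field_at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        return self.fields[i]


@dataclass
class RemovalResult:
    """Removal metrics of one microscale run at a single frequency."""

    freq: float                       # Hz
    removal_pct: float                # at t_end
    residual_ng_ml: float             # at t_end
    times: np.ndarray
    removal_series: np.ndarray        # removal percent at each output time
    wall_mode: str
    mesh: int
    seed: int


def integrate_concentration(c: np.ndarray, grid: MicroGrid) -> float:
    """Integral of c over the fluid region (mol/m), fraction-weighted.

    Every cell contributes its fluid fraction (1 - solid_frac); cells on the
    solid side of the sharp mask still hold a sliver of fluid, whose
    concentration is taken as the mean of the neighbouring fluid cells so
    that a uniform field integrates to exactly C * fluid_area.
    """
    fluid = grid.fluid_mask
    cc = np.where(fluid, np.nan_to_num(c), 0.0)
    cnt = fluid.astype(float)
    num = np.zeros_like(cc)
    den = np.zeros_like(cc)
    for sl_to, sl_from in (((slice(1, None), slice(None)), (slice(None, -1), slice(None))),
                           ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
                           ((slice(None), slice(1, None)), (slice(None), slice(None, -1))),
                           ((slice(None), slice(None, -1)), (slice(None), slice(1, None)))):
        num[sl_to] += cc[sl_from]
        den[sl_to] += cnt[sl_from]
    with np.errstate(invalid="ignore"):
        c_ext = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    c_eff = np.where(fluid, cc, c_ext)
    w = 1.0 - grid.solid_frac
    return float((c_eff * w).sum() * grid.cell_area)


def removal_percentage(c: np.ndarray, grid: MicroGrid, params) -> float:
    """Antigen removal percent at one time.

    Follows the method's normalization by the full domain square:
    removal = (C_bulk - int(c)/domain_size^2) / C_bulk * 100.  A uniform
    field c == C_bulk therefore reports ~0.63 %, the chain-occupied area
    fraction, not zero.
    """
    S2 = params.domain_size**2
    return float((1.0 - integrate_concentration(c, grid) / (params.C_bulk * S2)) * 100.0)


def residual_ng_per_ml(c: np.ndarray, grid: MicroGrid, params) -> float:
    """Domain-average residual concentration in ng/mL.

    1 g/m^3 = 1000 ng/mL, so C_bulk (6.67e-8 mol/m^3 of a 15 kDa analyte)
    maps to ~1.0 ng/mL.
    """
    mean_c = integrate_concentration(c, grid) / params.domain_size**2
    return float(mean_c * params.M_analyte * 1000.0)


def _assemble_operator(flow: FlowField, params, wall_mode: str):
    """Sparse dc/dt operator M (1/s) on compact fluid-cell vectors, plus the
    uptake extraction row used for the mass audit."""
    grid = flow.grid
    n, dx = grid.n, grid.dx
    fluid = grid.fluid_mask
    nf = int(fluid.sum())
    compact = -np.ones(n * n, dtype=np.int64)
    compact[np.flatnonzero(fluid.ravel())] = np.arange(nf)
    cell_id = np.arange(n * n).reshape(n, n)

    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r); cols.append(c); vals.append(v)

    D = params.D_analyte
    # fluid-fluid faces, x direction: between (i, j) and (i+1, j)
    for axis in (0, 1):
        if axis == 0:
            pair = fluid[:-1, :] & fluid[1:, :]
            ii, jj = np.nonzero(pair)
            left = compact[cell_id[ii, jj]]
            right = compact[cell_id[ii + 1, jj]]
            uf = flow.u[ii + 1, jj]
        else:
            pair = fluid[:, :-1] & fluid[:, 1:]
            ii, jj = np.nonzero(pair)
            left = compact[cell_id[ii, jj]]
            right = compact[cell_id[ii, jj + 1]]
            uf = flow.v[ii, jj + 1]
        dcoef = D / dx**2
        add(left, right, np.full(len(ii), dcoef))
        add(left, left, np.full(len(ii), -dcoef))
        add(right, left, np.full(len(ii), dcoef))
        add(right, right, np.full(len(ii), -dcoef))
        # central advection: flux = uf * (cL + cR)/2 out of L into R
        a = uf / (2.0 * dx)
        add(left, left, -a)
        add(left, right, -a)
        add(right, left, a)
        add(right, right, a)

    # chain-wall faces: linear uptake sink (saturation handled explicitly)
    k_up = params.uptake_velocity
    uptake_rows, uptake_coefs = [], []
    for iface, varr in ((grid.interfaces_x, flow.u), (grid.interfaces_y, flow.v)):
        if iface.cell.size == 0:
            continue
        cells = compact[iface.cell]
        corr = grid.perimeter_correction[iface.chain]
        gamma = corr * k_up / dx            # 1/s per unit c
        add(cells, cells, -gamma)
        uptake_rows.append(cells)
        uptake_coefs.append(gamma)
        if wall_mode == "advective":
            un = iface.sign * varr[iface.face_i, iface.face_j]  # outward normal vel
            add(cells, cells, -un / dx)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(nf, nf))
    uptake_rows = np.concatenate(uptake_rows)
    uptake_coefs = np.concatenate(uptake_coefs)
    return M, compact, uptake_rows, uptake_coefs


def default_dt(freq: float) -> float:
    """Output-accurate default time step: coarse for static runs, refined as
    the rotation (and hence the advective turnover) speeds up."""
    if freq <= 0:
        return 1.0
    return float(min(0.25, 0.5 / freq))


def simulate_binding(flow: FlowField, params, output_times=None,
                     wall_mode: str = "prescribed", dt: float | None = None,
                     theta: float = 0.5) -> ConcentrationHistory:
    """Integrate the antigen field under the given steady flow.

    Returns snapshots at ``output_times`` (default: every 10 s up to
    t_end, the method's output schedule).
    """
    if wall_mode not in WALL_MODES:
        raise ValueError(f"unknown wall_mode {wall_mode!r}; choose from {WALL_MODES}")
    grid = flow.grid
    if output_times is None:
        output_times = np.arange(0.0, params.t_end + 1e-9, 10.0)
    output_times = np.asarray(sorted(set(float(t) for t in output_times)))
    if output_times[-1] > params.t_end + 1e-9:
        raise ValueError("output times must lie within [0, t_end]")
    if dt is None:
        dt = default_dt(flow.omega / (2.0 * np.pi))

    M, compact, up_rows, up_coefs = _assemble_operator(flow, params, wall_mode)
    nf = M.shape[0]
    ident = sp.identity(nf, format="csr")
    lhs = (ident - dt * theta * M).tocsc()
    rhs_op = ident + dt * (1.0 - theta) * M
    lu = spla.splu(lhs)

    c = np.full(nf, params.C_bulk)
    K_D = params.K_D
    sat_coef = np.zeros(nf)
    np.add.at(sat_coef, up_rows, up_coefs)   # total linear uptake rate per cell

    fields, masses, uptakes = [], [], []
    cum_uptake = 0.0

    def snapshot():
        full = np.full((grid.n, grid.n), np.nan)
        full[grid.fluid_mask] = c
        fields.append(full)
        masses.append(integrate_concentration(full, grid))
        uptakes.append(cum_uptake)

    t = 0.0
    out_iter = iter(output_times)
    next_out = next(out_iter)
    if abs(next_out - t) < 1e-12:
        snapshot()
        next_out = next(out_iter, None)

    undershoot_tol = 1e-6 * params.C_bulk
    while next_out is not None:
        step = min(dt, next_out - t)
        if step < dt - 1e-12:
            lhs_s = (ident - step * theta * M).tocsc()
            lu_s = spla.splu(lhs_s)
            rhs = (ident + step * (1.0 - theta) * M) @ c
            rhs += step * sat_coef * c**2 / K_D   # explicit saturation relief
            c_new = lu_s.solve(rhs)
        else:
            rhs = rhs_op @ c
            rhs += step * sat_coef * c**2 / K_D
            c_new = lu.solve(rhs)
        if not np.all(np.isfinite(c_new)):
            raise TransportError(f"transport solve diverged at t={t:.2f}s")
        if c_new.min() < -undershoot_tol * 10:
            raise TransportError(
                f"negative concentration {c_new.min():.3e} beyond tolerance "
                f"at t={t:.2f}s")
        # uptake over the step (trapezoidal in c), for the mass audit
        c_mid = 0.5 * (c + c_new)
        cum_uptake += step * float(
            np.sum(sat_coef * (c_mid - c_mid**2 / K_D))) * grid.cell_area
        c = c_new
        t += step
        if abs(t - next_out) < 1e-9:
            snapshot()
            next_out = next(out_iter, None)

    return ConcentrationHistory(grid=grid, times=output_times, fields=fields,
                                total_mass=np.asarray(masses),
                                wall_uptake=np.asarray(uptakes),
                                wall_mode=wall_mode)


def run_removal(params, freq: float, geometry: MicroGeometry | None = None,
                resolution: str | int = "medium",
                seed: int = DEFAULT_ORIENTATION_SEED,
                orientation_mode: str = "seeded_random",
                wall_mode: str = "prescribed", dt: float | None = None,
                base_flow: FlowField | None = None,
                output_times=None) -> tuple[RemovalResult, ConcentrationHistory]:
    """One full microscale run: geometry -> flow -> transport -> removal."""
    params = params.replace(freq=freq)
    if geometry is None:
        geometry = build_chain_grid(params, orientation_mode, seed=seed)
    if base_flow is not None:
        grid = base_flow.grid
        flow = base_flow.scaled(params.omega) if params.omega > 0 else \
            solve_flow(grid, params, 0.0, wall_bc=base_flow.wall_bc)
    else:
        grid = generate_grid(geometry, resolution)
        flow = solve_flow(grid, params, params.omega)
    hist = simulate_binding(flow, params, output_times=output_times,
                            wall_mode=wall_mode, dt=dt)
    removal_series = np.array([removal_percentage(f, grid, params)
                               for f in hist.fields])
    final = hist.fields[-1]
    result = RemovalResult(
        freq=freq,
        removal_pct=removal_percentage(final, grid, params),
        residual_ng_ml=residual_ng_per_ml(final, grid, params),
        times=hist.times, removal_series=removal_series,
        wall_mode=wall_mode, mesh=grid.n, seed=seed)
    return result, hist


def frequency_sweep(params, freqs, seed: int = DEFAULT_ORIENTATION_SEED,
                    resolution: str | int = "medium",
                    wall_mode: str = "prescribed",
                    orientation_mode: str = "seeded_random",
                    dt: float | None = None) -> pd.DataFrame:
    """Removal vs rotation frequency on a fixed geometry and grid.

    The Stokes problem is solved once and rescaled by linearity for every
    nonzero frequency.  Per-frequency failures are recorded in the
    ``status`` column and do not abort the sweep.
    """
    freqs = list(freqs)
    if not freqs:
        raise ValueError("frequency list must be non-empty")
    geometry = build_chain_grid(params, orientation_mode, seed=seed)
    grid = generate_grid(geometry, resolution)
    base = solve_flow(grid, params, 1.0)   # omega = 1 rad/s reference
    rows = []
    for f in freqs:
        row = {"freq_hz": f, "removal_pct": np.nan, "residual_ng_ml": np.nan,
               "wall_mode": wall_mode, "mesh": grid.n, "seed": seed,
               "status": "ok"}
        try:
            pf = params.replace(freq=f)
            flow = base.scaled(pf.omega) if pf.omega > 0 else \
                solve_flow(grid, pf, 0.0)
            hist = simulate_binding(flow, pf, wall_mode=wall_mode, dt=dt)
            final = hist.fields[-1]
            row["removal_pct"] = removal_percentage(final, grid, pf)
            row["residual_ng_ml"] = residual_ng_per_ml(final, grid, pf)
        except Exception as exc:   # per-row failure propagation
            row["status"] = f"failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows, columns=["freq_hz", "removal_pct",
                                       "residual_ng_ml", "wall_mode", "mesh",
                                       "seed", "status"])
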