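"""Wetting front, effective transport properties and Darcy flow of the strip.

The lateral-flow membrane is a 7 mm x 2.5 mm rectangle (3 mm inlet segment,
1 mm test line, 3 mm outlet segment).  Capillary imbibition is not solved as
two-phase flow; instead the wetting front advances analytically with the
Lucas-Washburn law

    x_front(t) = sqrt(2 k_perm P_cap (t + 0.1) / (eta porosity)),

a smooth wetness field 0.5*(1 + tanh((x_front - x)/delta_smooth)) grades the
dry->wet transition, and the wetness modulates the effective permeability
k_eff = k_perm*(k_min + (1-k_min)*wetness^power_contrast) and nanochain
diffusivity D_eff = D0*max(wetness, 0.01).  Single-phase Darcy flow with
inlet pressure P_inlet and zero outlet pressure is then solved on the
heterogeneous k_eff field; while the strip is partially wet the dry region's
k_min floor throttles the flux, so the superficial velocity rises by two
orders of magnitude once the front breaks through (~25 s with defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .parameters import MembraneModelParams


def front_position(t, params: MembraneModelParams):
    """Lucas-Washburn wetting-front position (m) at time t (s)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < -0.1):
        raise ValueError("front_position requires t >= -0.1 s")
    x = np.sqrt(2.0 * params.k_perm * params.P_cap * (t + 0.1)
                / (params.eta_fluid * params.porosity))
    return float(x) if x.ndim == 0 else x


def wetness(x, t, params: MembraneModelParams):
    """Smooth wetting indicator in [0, 1] at position x (m), time t (s)."""
    xf = front_position(t, params)
    return 0.5 * (1.0 + np.tanh((xf - np.asarray(x, dtype=float))
                                / params.delta_smooth))


def effective_permeability(w, params: MembraneModelParams):
    """k_eff = k_perm * (k_min + (1 - k_min) * wetness^power_contrast)."""
    w = np.asarray(w, dtype=float)
    return params.k_perm * (params.k_min
                            + (1.0 - params.k_min) * w**params.power_contrast)


def effective_diffusivity(w, params: MembraneModelParams):
    """D_eff = D0 * max(wetness, 0.01)."""
    return params.D0 * np.maximum(np.asarray(w, dtype=float), 0.01)


def effective_properties(w, params: MembraneModelParams):
    """Elementwise (k_eff, D_eff) from a wetness field."""
    return effective_permeability(w, params), effective_diffusivity(w, params)


def testline_indicator(x, params: MembraneModelParams):
    """1 inside the test line [x_testline, x_testline + w_testline], else 0."""
    x = np.asarray(x, dtype=float)
    ind = ((x >= params.x_testline)
           & (x <= params.x_testline + params.w_testline)).astype(float)
    return float(ind) if ind.ndim == 0 else ind


@dataclass(frozen=True)
class MembraneGrid:
    """Structured cell-centred grid on the 7 mm x H_membrane rectangle."""

    params: MembraneModelParams
    nx: int = 560
    ny: int = 6
    Lx: float = field(init=False)
    Ly: float = field(init=False)
    dx: float = field(init=False)
    dy: float = field(init=False)
    x_centers: np.ndarray = field(init=False)
    y_centers: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "Lx", self.params.domain_length)
        object.__setattr__(self, "Ly", self.params.H_membrane)
        object.__setattr__(self, "dx", self.Lx / self.nx)
        object.__setattr__(self, "dy", self.Ly / self.ny)
        object.__setattr__(self, "x_centers",
                           (np.arange(self.nx) + 0.5) * self.dx)
        object.__setattr__(self, "y_centers",
                           (np.arange(self.ny) + 0.5) * self.dy)

    def testline_mask(self) -> np.ndarray:
        """(nx,) cell mask of the test-line region."""
        return testline_indicator(self.x_centers, self.params) > 0


@dataclass
class WettingState:
    """Wetting snapshot: front, wetness and effective properties on a grid."""

    time: float
    front: float
    wetness: np.ndarray     # (nx,)
    k_eff: np.ndarray       # (nx,)
    D_eff: np.ndarray       # (nx,)


def wetting_state(t: float, grid: MembraneGrid) -> WettingState:
    w = wetness(grid.x_centers, t, grid.params)
    k, D = effective_properties(w, grid.params)
    return WettingState(time=float(t), front=front_position(t, grid.params),
                        wetness=w, k_eff=k, D_eff=D)


@dataclass
class DarcyField:
    """Pressure and superficial velocity on a :class:`MembraneGrid`."""

    grid: MembraneGrid
    p: np.ndarray           # (nx, ny) Pa
    ux: np.ndarray          # (nx+1, ny) m/s, x-faces
    uy: np.ndarray          # (nx, ny+1) m/s, y-faces
    flux_imbalance: float   # max relative cross-section flux deviation

    def cross_section_flux(self) -> np.ndarray:
        """Volumetric flux through each x-face column (m^2/s in 2D)."""
        return self.ux.sum(axis=1) * self.grid.dy


class DarcySolverError(RuntimeError):
    pass


def solve_darcy(k_eff: np.ndarray, grid: MembraneGrid) -> DarcyField:
    """Solve div((k_eff/eta) grad p) = 0 with p = P_inlet at x=0, p = 0 at
    x = Lx and no-flow lateral walls; returns the superficial velocity
    u = -(k_eff/eta) grad p.

    ``k_eff`` may be (nx,) (uniform in y) or (nx, ny).
    """
    params = grid.params
    nx, ny, dx, dy = grid.nx, grid.ny, grid.dx, grid.dy
    k = np.asarray(k_eff, dtype=float)
    if k.ndim == 1:
        k = np.repeat(k[:, None], ny, axis=1)
    if np.any(k <= 0):
        raise DarcySolverError("permeability field must be strictly positive")
    mob = k / params.eta_fluid

    # harmonic-mean face mobilities
    mx = np.zeros((nx + 1, ny))
    mx[1:-1, :] = 2.0 * mob[:-1, :] * mob[1:, :] / (mob[:-1, :] + mob[1:, :])
    mx[0, :] = mob[0, :]      # half-cell to the Dirichlet inlet
    mx[-1, :] = mob[-1, :]
    my = np.zeros((nx, ny + 1))
    my[:, 1:-1] = 2.0 * mob[:, :-1] * mob[:, 1:] / (mob[:, :-1] + mob[:, 1:])

    idx = np.arange(nx * ny).reshape(nx, ny)
    rows, cols, vals = [], [], []
    rhs = np.zeros(nx * ny)
    diag = np.zeros((nx, ny))

    # x-direction interior couplings
    w = mx[1:-1, :] / dx**2
    rows += [idx[:-1, :].ravel(), idx[1:, :].ravel(),
             idx[:-1, :].ravel(), idx[1:, :].ravel()]
    cols += [idx[1:, :].ravel(), idx[:-1, :].ravel(),
             idx[:-1, :].ravel(), idx[1:, :].ravel()]
    vals += [w.ravel(), w.ravel(), -w.ravel(), -w.ravel()]
    # y-direction
    w = my[:, 1:-1] / dy**2
    rows += [idx[:, :-1].ravel(), idx[:, 1:].ravel(),
             idx[:, :-1].ravel(), idx[:, 1:].ravel()]
    cols += [idx[:, 1:].ravel(), idx[:, :-1].ravel(),
             idx[:, :-1].ravel(), idx[:, 1:].ravel()]
    vals += [w.ravel(), w.ravel(), -w.ravel(), -w.ravel()]
    # Dirichlet boundaries via half-cell ghosts
    wl = 2.0 * mx[0, :] / dx**2
    diag[0, :] -= wl
    rhs[idx[0, :]] -= wl * params.P_inlet
    wr = 2.0 * mx[-1, :] / dx**2
    diag[-1, :] -= wr

    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(diag.ravel())

    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(nx * ny, nx * ny))
    p = spla.spsolve(A.tocsc(), rhs).reshape(nx, ny)
    if not np.all(np.isfinite(p)):
        raise DarcySolverError("Darcy solve produced non-finite pressure")

    ux = np.zeros((nx + 1, ny))
    ux[1:-1, :] = -mx[1:-1, :] * (p[1:, :] - p[:-1, :]) / dx
    ux[0, :] = -mx[0, :] * (p[0, :] - params.P_inlet) / (dx / 2.0)
    ux[-1, :] = -mx[-1, :] * (0.0 - p[-1, :]) / (dx / 2.0)
    uy = np.zeros((nx, ny + 1))
    uy[:, 1:-1] = -my[:, 1:-1] * (p[:, 1:] - p[:, :-1]) / dy

    flux = ux.sum(axis=1) * dy
    fmean = float(np.mean(flux))
    imbalance = float(np.max(np.abs(flux - fmean)) / max(abs(fmean), 1e-300))
    return DarcyField(grid=grid, p=p, ux=ux, uy=uy, flux_imbalance=imbalance)


def darcy_at_time(t: float, grid: MembraneGrid) -> tuple[WettingState, DarcyField]:
    """Convenience: wetting state and Darcy field at membrane time t."""
    ws = wetting_state(t, grid)
    return ws, solve_darcy(ws.k_eff, grid)
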