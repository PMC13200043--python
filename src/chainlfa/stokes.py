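"""Steady creeping-flow solver for the chain-stirred microdomain.

The chain Reynolds number is ~1e-5 at 3 Hz, so inertia is dropped and the
steady Stokes equations are solved:

    -mu laplacian(u) + grad p = f,     div u = 0,

with no-slip outer walls and rigid-rotation velocities on the chain walls.
Chains are imposed by volume penalization (Angot): inside the (fractional)
solid mask a Darcy-type drag K*(u - u_wall) forces the fluid to the wall
velocity, with K chosen so the penetration depth sqrt(mu/K) is a small
fraction of a cell.  The discrete saddle-point problem on the MAC grid is
solved by conjugate gradients on the pressure Schur complement, with the two
penalized vector-Laplacian blocks factorized once (sparse LU).  The Stokes
problem is linear in omega, so a base solution can be rescaled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import MicroGrid


class FlowSolverError(RuntimeError):
    """The Stokes solve failed to converge."""


@dataclass
class FlowField:
    """Steady velocity/pressure field on a :class:`MicroGrid`.

    ``u`` (n+1, n) and ``v`` (n, n+1) are staggered face velocities in m/s
    (outer boundary faces are exactly zero), ``p`` (n, n) is the cell
    pressure in Pa pinned to zero mean over fluid cells.
    """

    grid: MicroGrid
    omega: float
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    div_residual: float
    iterations: int
    wall_bc: str = "prescribed"

    def scaled(self, omega_new: float) -> "FlowField":
        """Exact rescaling by linearity of the Stokes problem."""
        if self.omega == 0.0:
            if omega_new == 0.0:
                return self
            raise ValueError("cannot rescale a zero-frequency base solution")
        f = omega_new / self.omega
        return FlowField(grid=self.grid, omega=omega_new, u=self.u * f,
                         v=self.v * f, p=self.p * f,
                         div_residual=abs(self.div_residual * f),
                         iterations=self.iterations, wall_bc=self.wall_bc)

    def cell_speed(self) -> np.ndarray:
        """Cell-centred velocity magnitude (m/s)."""
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        return np.hypot(uc, vc)

    def max_speed(self) -> float:
        return float(self.cell_speed()[self.grid.fluid_mask].max(initial=0.0))


def _laplacian_block(n: int, axis: int, dx: float, mu: float,
                     chi: np.ndarray, K: float) -> sp.csr_matrix:
    """-mu*laplacian + K*chi on interior staggered faces of one axis.

    axis=0: u on x-faces, unknowns (n-1, n); axis=1: v on y-faces (n, n-1).
    Dirichlet u=0 on the domain boundary; the tangential no-slip wall is
    applied through the half-cell ghost reflection (coefficient 3 on the
    diagonal for the wall-adjacent row).
    """
    if axis == 0:
        ni, nj = n - 1, n
        chi_int = chi[1:-1, :]
        normal_axis = 0
    else:
        ni, nj = n, n - 1
        chi_int = chi[:, 1:-1]
        normal_axis = 1
    N = ni * nj
    idx = np.arange(N).reshape(ni, nj)
    c = mu / dx**2

    diag = np.full((ni, nj), 4.0 * c)
    rows, cols, vals = [idx.ravel()], [idx.ravel()], []

    off_r, off_c, off_v = [], [], []
    # neighbours along i
    off_r.append(idx[:-1, :].ravel()); off_c.append(idx[1:, :].ravel())
    off_r.append(idx[1:, :].ravel()); off_c.append(idx[:-1, :].ravel())
    # neighbours along j
    off_r.append(idx[:, :-1].ravel()); off_c.append(idx[:, 1:].ravel())
    off_r.append(idx[:, 1:].ravel()); off_c.append(idx[:, :-1].ravel())
    n_off = sum(len(r) for r in off_r)

    # boundary treatment: along the normal axis the neighbour at the wall is
    # a Dirichlet-0 face (dropped, diagonal keeps 4c); along the tangential
    # axis the wall lies half a cell beyond -> ghost = -u -> diagonal +c.
    tang = np.zeros((ni, nj))
    if axis == 0:
        tang[:, 0] += c
        tang[:, -1] += c
    else:
        tang[0, :] += c
        tang[-1, :] += c
    diag += tang + K * chi_int

    data = np.concatenate([diag.ravel(), -c * np.ones(n_off)])
    rows = np.concatenate(rows + off_r)
    cols = np.concatenate(cols + off_c)
    return sp.csr_matrix((data, (rows, cols)), shape=(N, N))


def _div_matrices(n: int, dx: float) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Divergence operators cell <- interior u-faces / v-faces."""
    cell = np.arange(n * n).reshape(n, n)
    # u-faces interior: (n-1, n); face i sits between cells i-1 and i
    uf = np.arange((n - 1) * n).reshape(n - 1, n)
    rows = np.concatenate([cell[:-1, :].ravel(), cell[1:, :].ravel()])
    cols = np.concatenate([uf.ravel(), uf.ravel()])
    vals = np.concatenate([np.full(uf.size, 1.0 / dx), np.full(uf.size, -1.0 / dx)])
    Du = sp.csr_matrix((vals, (rows, cols)), shape=(n * n, (n - 1) * n))
    vf = np.arange(n * (n - 1)).reshape(n, n - 1)
    rows = np.concatenate([cell[:, :-1].ravel(), cell[:, 1:].ravel()])
    cols = np.concatenate([vf.ravel(), vf.ravel()])
    vals = np.concatenate([np.full(vf.size, 1.0 / dx), np.full(vf.size, -1.0 / dx)])
    Dv = sp.csr_matrix((vals, (rows, cols)), shape=(n * n, n * (n - 1)))
    return Du, Dv


def solve_stokes_penalized(n: int, dx: float, mu: float,
                           chi_u: np.ndarray, chi_v: np.ndarray,
                           us: np.ndarray, vs: np.ndarray,
                           penalty: float = 1e-4,
                           tol: float = 1e-10, maxiter: int = 600):
    """Low-level penalized MAC Stokes solve.

    ``chi_u``/``chi_v`` are solid fractions at the full staggered face
    arrays ((n+1, n) and (n, n+1)); ``us``/``vs`` the wall-velocity targets
    there.  Returns (u, v, p, div_residual, iterations) with full-size
    staggered arrays (boundary faces zero).
    """
    K = mu / (penalty * dx * dx)
    Au = _laplacian_block(n, 0, dx, mu, chi_u, K)
    Av = _laplacian_block(n, 1, dx, mu, chi_v, K)
    Du, Dv = _div_matrices(n, dx)
    fu = (K * chi_u[1:-1, :] * us[1:-1, :]).ravel()
    fv = (K * chi_v[:, 1:-1] * vs[:, 1:-1]).ravel()

    lu_u = spla.splu(Au.tocsc())
    lu_v = spla.splu(Av.tocsc())

    def a_inv(bu, bv):
        return lu_u.solve(bu), lu_v.solve(bv)

    def schur(p):
        gu = Du.T @ p
        gv = Dv.T @ p
        su, sv = a_inv(gu, gv)
        return Du @ su + Dv @ sv

    u0, v0 = a_inv(fu, fv)
    rhs = -(Du @ u0 + Dv @ v0)   # solve S p = -(D A^-1 f), S = D A^-1 D^T
    rhs -= rhs.mean()

    scale = float(np.abs(np.concatenate([us.ravel(), vs.ravel()])).max())
    if scale == 0.0 or np.linalg.norm(rhs) == 0.0:
        u = np.zeros((n + 1, n))
        v = np.zeros((n, n + 1))
        return u, v, np.zeros((n, n)), 0.0, 0

    # preconditioned CG on the SPD Schur complement (constants projected out)
    p = np.zeros_like(rhs)
    r = rhs.copy()
    z = mu * r
    d = z.copy()
    rz = r @ z
    rhs_norm = np.linalg.norm(rhs)
    it = 0
    for it in range(1, maxiter + 1):
        Sd = schur(d)
        alpha = rz / (d @ Sd)
        p += alpha * d
        r -= alpha * Sd
        r -= r.mean()
        if np.linalg.norm(r) <= tol * rhs_norm:
            break
        z = mu * r
        rz_new = r @ z
        d = z + (rz_new / rz) * d
        rz = rz_new
    else:
        raise FlowSolverError(
            f"Schur CG did not converge in {maxiter} iterations "
            f"(residual {np.linalg.norm(r) / rhs_norm:.2e})")

    uu, vv = a_inv(fu + Du.T @ p, fv + Dv.T @ p)
    u = np.zeros((n + 1, n))
    v = np.zeros((n, n + 1))
    u[1:-1, :] = uu.reshape(n - 1, n)
    v[:, 1:-1] = vv.reshape(n, n - 1)
    div = Du @ uu + Dv @ vv
    return u, v, p.reshape(n, n), float(np.linalg.norm(div) * dx), it


def solve_flow(grid: MicroGrid, params, omega: float,
               wall_bc: str = "prescribed", penalty: float = 1e-4,
               tol: float = 1e-10) -> FlowField:
    """Solve the steady chain-stirred Stokes flow at angular velocity omega.

    ``wall_bc='prescribed'`` imposes the full rigid-rotation vector on chain
    walls (the method's literal prescription, which carries a nonzero
    normal component on flat faces); ``'tangential'`` projects it onto the
    local wall tangent first.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if wall_bc not in ("prescribed", "tangential"):
        raise ValueError(f"unknown wall_bc {wall_bc!r}")
    us, vs = grid.rigid_targets(omega, tangential=(wall_bc == "tangential"))
    u, v, p, div, it = solve_stokes_penalized(
        grid.n, grid.dx, params.mu_fluid, grid.chi_u, grid.chi_v, us, vs,
        penalty=penalty, tol=tol)
    p = p - p[grid.fluid_mask].mean()
    return FlowField(grid=grid, omega=omega, u=u, v=v, p=p,
                     div_residual=div, iterations=it, wall_bc=wall_bc)
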