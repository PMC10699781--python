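"""Instantaneous tissue mechanics: the elliptic force balance and diagnostics.

Force balance (nondimensional, inertia neglected)::

    2 p1 Lap(v) + grad(div v)  +  2 p1 (B grad m + m div B) + p1 (p0 - 1) grad m = 0

with Dirichlet velocity ``v = v_b n_hat`` on the disk boundary (epiboly)
and zero tangential component.  Eliminating the pressure through the
continuity law ``div v = -p1 (2 p + p0 m)`` gives the pressure recovery
``p = -((div v)/p1 + p0 m) / 2``.

Discretization (a contract, not a mandate: any scheme passing the
manufactured-solution order-2 test is conforming):

* second-order central differences in ``r`` on cell-centred nodes;
  periodic central differences in ``theta``;
* the across-origin coupling uses the standard pole treatment -- the
  innermost ring's inner neighbour at ``(r0, theta)`` is the node at
  ``(r0, theta + pi)`` (Cartesian components are true scalars under this
  identification, which is why fields are stored in a fixed Cartesian
  frame);
* Dirichlet data enter through quadratic ghost extrapolation at
  ``r = R + dr/2``; zero-flux (Neumann) through a mirror ghost;
* the joint sparse system for ``(u, v)`` is factorized once per
  ``(grid, p1)`` by direct sparse LU and reused across time steps.

Cartesian derivatives on the polar layout use the exact polar expansions,
e.g. ``f_x = cos(t) f_r - sin(t)/r f_t`` and the corresponding
second-derivative formulas, assembled as sparse matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import uniform_filter1d

from .core import DiskGrid, ModelParams, SymTensorField, structure_tensor

__all__ = [
    "BoundaryCondition",
    "SolverReport",
    "DiskOperators",
    "ForceBalanceSolver",
    "solve_force_balance",
    "recover_pressure",
    "active_force_field",
    "strain_rate_diagnostics",
    "divergence",
    "vorticity",
    "infer_active_force",
]


# --------------------------------------------------------------------------
# Boundary condition / report plumbing
# --------------------------------------------------------------------------

@dataclass
class BoundaryCondition:
    """Velocity boundary data on the disk rim.

    ``normal_speed`` is the outward-normal speed (epiboly), a constant or
    a function of theta; the tangential component is identically zero.
    ``zero_flux_fields`` records that m and phi carry no-flux conditions.
    """

    normal_speed: Union[float, Callable[[np.ndarray], np.ndarray]] = 0.0
    zero_flux_fields: bool = True

    def velocity_samples(self, thetas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cartesian boundary samples (u_b, v_b) at the given angles."""
        if callable(self.normal_speed):
            vn = np.asarray(self.normal_speed(thetas), dtype=float)
        else:
            vn = float(self.normal_speed) * np.ones_like(thetas)
        if not np.all(np.isfinite(vn)):
            raise ValueError("boundary normal speed must be finite")
        return vn * np.cos(thetas), vn * np.sin(thetas)


@dataclass
class SolverReport:
    residual: float
    converged: bool
    method: str = "splu"
    iterations: int = 0
    message: str = ""


# --------------------------------------------------------------------------
# Affine sparse operators:  op(f) = M @ f + Bmat @ f_boundary
# --------------------------------------------------------------------------

class AffineOp:
    """A linear operator on interior nodes plus an affine boundary part."""

    __slots__ = ("M", "B")

    def __init__(self, M: sp.spmatrix, B: Optional[sp.spmatrix] = None):
        self.M = M.tocsr()
        self.B = B.tocsr() if B is not None else None

    def __add__(self, other: "AffineOp") -> "AffineOp":
        if self.B is None and other.B is None:
            B = None
        elif self.B is None:
            B = other.B
        elif other.B is None:
            B = self.B
        else:
            B = self.B + other.B
        return AffineOp(self.M + other.M, B)

    def scale(self, d: np.ndarray) -> "AffineOp":
        """Left-multiply by a diagonal (pointwise coefficient) field."""
        D = sp.diags(np.asarray(d, dtype=float).ravel())
        return AffineOp(D @ self.M, None if self.B is None else D @ self.B)

    def apply(self, f: np.ndarray, f_b: Optional[np.ndarray] = None) -> np.ndarray:
        out = self.M @ f.ravel()
        if self.B is not None:
            if f_b is None:
                raise ValueError("operator requires boundary data")
            out = out + self.B @ np.asarray(f_b, dtype=float)
        return out.reshape(f.shape)


class DiskOperators:
    """Sparse finite-difference operators on a :class:`DiskGrid`.

    Boundary-condition tags for the radial direction:

    * ``"dirichlet"`` -- ghost from quadratic extrapolation through the
      boundary value at r = R (operators carry an affine boundary part);
    * ``"neumann"``   -- mirror ghost (zero radial derivative at r = R);
    * ``"extrap"``    -- ghost from quadratic extrapolation of the three
      outermost interior nodes (no boundary data; used for diagnostics
      of fields whose rim values are unknown).
    """

    def __init__(self, grid: DiskGrid):
        self.grid = grid
        nr, nt = grid.nr, grid.ntheta
        self.N = nr * nt
        r, t = grid.mesh_polar()
        self._r = r.ravel()
        self._t = t.ravel()
        self._cache: dict = {}

    # -- index helpers -----------------------------------------------------
    def _idx(self, j, k):
        nt = self.grid.ntheta
        return np.asarray(j) * nt + np.mod(k, nt)

    # -- base angular operators (no boundary data needed) ------------------
    def Dt(self) -> AffineOp:
        return self._cached("Dt", self._build_Dt)

    def Dtt(self) -> AffineOp:
        return self._cached("Dtt", self._build_Dtt)

    def _build_Dt(self) -> AffineOp:
        nr, nt = self.grid.shape
        dth = self.grid.dtheta
        j, k = np.meshgrid(np.arange(nr), np.arange(nt), indexing="ij")
        rows = self._idx(j, k).ravel()
        c = 0.5 / dth
        M = sp.coo_matrix(
            (
                np.concatenate([np.full(rows.size, c), np.full(rows.size, -c)]),
                (
                    np.concatenate([rows, rows]),
                    np.concatenate(
                        [self._idx(j, k + 1).ravel(), self._idx(j, k - 1).ravel()]
                    ),
                ),
            ),
            shape=(self.N, self.N),
        )
        return AffineOp(M)

    def _build_Dtt(self) -> AffineOp:
        nr, nt = self.grid.shape
        dth = self.grid.dtheta
        j, k = np.meshgrid(np.arange(nr), np.arange(nt), indexing="ij")
        rows = self._idx(j, k).ravel()
        c = 1.0 / dth**2
        M = sp.coo_matrix(
            (
                np.concatenate(
                    [np.full(rows.size, c), np.full(rows.size, -2 * c), np.full(rows.size, c)]
                ),
                (
                    np.concatenate([rows, rows, rows]),
                    np.concatenate(
                        [
                            self._idx(j, k + 1).ravel(),
                            self._idx(j, k).ravel(),
                            self._idx(j, k - 1).ravel(),
                        ]
                    ),
                ),
            ),
            shape=(self.N, self.N),
        )
        return AffineOp(M)

    # -- radial operators --------------------------------------------------
    def Dr(self, bc: str) -> AffineOp:
        return self._cached(("Dr", bc), lambda: self._build_radial(bc, order=1))

    def Drr(self, bc: str) -> AffineOp:
        return self._cached(("Drr", bc), lambda: self._build_radial(bc, order=2))

    def _build_radial(self, bc: str, order: int) -> AffineOp:
        if bc not in ("dirichlet", "neumann", "extrap"):
            raise ValueError(f"unknown radial bc {bc!r}")
        nr, nt = self.grid.shape
        h = self.grid.dr
        half = nt // 2
        rows, cols, vals = [], [], []
        brows, bcols, bvals = [], [], []
        ks = np.arange(nt)

        def add(j, k, jc, kc, v):
            rows.append(self._idx(j, k))
            cols.append(self._idx(jc, kc))
            vals.append(np.full(nt, v) if np.isscalar(v) else v)

        def add_b(j, k, kb, v):
            brows.append(self._idx(j, k))
            bcols.append(np.mod(kb, nt))
            bvals.append(np.full(nt, v) if np.isscalar(v) else v)

        if order == 1:
            c1, c2 = -0.5 / h, 0.5 / h  # inner, outer neighbour weights
            cc = 0.0
        else:
            c1 = c2 = 1.0 / h**2
            cc = -2.0 / h**2

        # innermost ring: inner neighbour across the origin
        add(0, ks, 0, ks + half, c1)
        if cc:
            add(0, ks, 0, ks, cc)
        add(0, ks, 1, ks, c2)
        # interior rings
        for j in range(1, nr - 1):
            add(j, ks, j - 1, ks, c1)
            if cc:
                add(j, ks, j, ks, cc)
            add(j, ks, j + 1, ks, c2)
        # outermost ring: ghost elimination
        j = nr - 1
        add(j, ks, j - 1, ks, c1)
        if cc:
            add(j, ks, j, ks, cc)
        if bc == "neumann":
            # ghost = value at nr-1 (mirror)
            add(j, ks, j, ks, c2)
        elif bc == "dirichlet":
            # ghost = (8/3) f_b - 2 f_{nr-1} + (1/3) f_{nr-2}
            add(j, ks, j, ks, -2.0 * c2)
            add(j, ks, j - 1, ks, c2 / 3.0)
            add_b(j, ks, ks, 8.0 * c2 / 3.0)
        else:  # extrap: ghost = 3 f_{nr-1} - 3 f_{nr-2} + f_{nr-3}
            add(j, ks, j, ks, 3.0 * c2)
            add(j, ks, j - 1, ks, -3.0 * c2)
            add(j, ks, j - 2, ks, c2)

        M = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.N, self.N),
        )
        B = None
        if brows:
            B = sp.coo_matrix(
                (np.concatenate(bvals), (np.concatenate(brows), np.concatenate(bcols))),
                shape=(self.N, nt),
            )
        return AffineOp(M, B)

    def Drt(self, bc: str) -> AffineOp:
        """Mixed derivative d^2/(dr dtheta) = Dr o Dt.

        With Dirichlet data the ghost of the theta-derivative field uses
        the theta-derivative of the boundary samples (periodic central
        difference on the rim).
        """
        def build():
            dr = self.Dr(bc)
            dt = self.Dt()
            M = dr.M @ dt.M
            B = None
            if dr.B is not None:
                nt = self.grid.ntheta
                dth = self.grid.dtheta
                k = np.arange(nt)
                Tb = sp.coo_matrix(
                    (
                        np.concatenate([np.full(nt, 0.5 / dth), np.full(nt, -0.5 / dth)]),
                        (
                            np.concatenate([k, k]),
                            np.concatenate([(k + 1) % nt, (k - 1) % nt]),
                        ),
                    ),
                    shape=(nt, nt),
                )
                B = dr.B @ Tb
            return AffineOp(M, B)

        return self._cached(("Drt", bc), build)

    # -- Cartesian derivative operators ------------------------------------
    def Dx(self, bc: str) -> AffineOp:
        def build():
            r, t = self._r, self._t
            return self.Dr(bc).scale(np.cos(t)) + self.Dt().scale(-np.sin(t) / r)
        return self._cached(("Dx", bc), build)

    def Dy(self, bc: str) -> AffineOp:
        def build():
            r, t = self._r, self._t
            return self.Dr(bc).scale(np.sin(t)) + self.Dt().scale(np.cos(t) / r)
        return self._cached(("Dy", bc), build)

    def Dxx(self, bc: str) -> AffineOp:
        def build():
            r, t = self._r, self._t
            s, c = np.sin(t), np.cos(t)
            return (
                self.Drr(bc).scale(c * c)
                + self.Drt(bc).scale(-2.0 * s * c / r)
                + self.Dtt().scale(s * s / r**2)
                + self.Dr(bc).scale(s * s / r)
                + self.Dt().scale(2.0 * s * c / r**2)
            )
        return self._cached(("Dxx", bc), build)

    def Dyy(self, bc: str) -> AffineOp:
        def build():
            r, t = self._r, self._t
            s, c = np.sin(t), np.cos(t)
            return (
                self.Drr(bc).scale(s * s)
                + self.Drt(bc).scale(2.0 * s * c / r)
                + self.Dtt().scale(c * c / r**2)
                + self.Dr(bc).scale(c * c / r)
                + self.Dt().scale(-2.0 * s * c / r**2)
            )
        return self._cached(("Dyy", bc), build)

    def Dxy(self, bc: str) -> AffineOp:
        def build():
            r, t = self._r, self._t
            s, c = np.sin(t), np.cos(t)
            c2t = np.cos(2.0 * t)
            return (
                self.Drr(bc).scale(s * c)
                + self.Drt(bc).scale(c2t / r)
                + self.Dtt().scale(-s * c / r**2)
                + self.Dr(bc).scale(-s * c / r)
                + self.Dt().scale(-c2t / r**2)
            )
        return self._cached(("Dxy", bc), build)

    def laplacian(self, bc: str) -> AffineOp:
        def build():
            r = self._r
            return (
                self.Drr(bc)
                + self.Dr(bc).scale(1.0 / r)
                + self.Dtt().scale(1.0 / r**2)
            )
        return self._cached(("lap", bc), build)

    def _cached(self, key, builder):
        if key not in self._cache:
            self._cache[key] = builder()
        return self._cache[key]


_OPERATOR_CACHE: dict[DiskGrid, DiskOperators] = {}


def get_operators(grid: DiskGrid) -> DiskOperators:
    ops = _OPERATOR_CACHE.get(grid)
    if ops is None:
        ops = _OPERATOR_CACHE[grid] = DiskOperators(grid)
    return ops


# --------------------------------------------------------------------------
# Active force and the elliptic solve
# --------------------------------------------------------------------------

def active_force_field(
    m: np.ndarray, phi: np.ndarray, params: ModelParams, grid: DiskGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Active force density 2 p1 (B grad m + m div B) + p1 (p0 - 1) grad m.

    m and phi carry zero-flux boundary conditions, so their Cartesian
    gradients are evaluated with mirror (Neumann) ghosts.
    """
    ops = get_operators(grid)
    Dx, Dy = ops.Dx("neumann"), ops.Dy("neumann")
    B = structure_tensor(phi)
    mx = Dx.apply(m)
    my = Dy.apply(m)
    divB_x = Dx.apply(B.t11) + Dy.apply(B.t12)
    divB_y = Dx.apply(B.t12) + Dy.apply(B.t22)
    p1, p0 = params.p1, params.p0
    fx = 2.0 * p1 * (B.t11 * mx + B.t12 * my + m * divB_x) + p1 * (p0 - 1.0) * mx
    fy = 2.0 * p1 * (B.t12 * mx + B.t22 * my + m * divB_y) + p1 * (p0 - 1.0) * my
    return fx, fy


class ForceBalanceSolver:
    """Prefactorized solver for the joint (u, v) elliptic system.

    The system matrix depends only on the grid and p1, so one LU
    factorization serves every time step of a simulation.
    """

    def __init__(self, grid: DiskGrid, params: ModelParams):
        self.grid = grid
        self.params = params
        ops = get_operators(grid)
        self.ops = ops
        p1 = params.p1
        L = ops.laplacian("dirichlet")
        Dxx, Dyy, Dxy = ops.Dxx("dirichlet"), ops.Dyy("dirichlet"), ops.Dxy("dirichlet")
        self._A11 = AffineOp(2.0 * p1 * L.M, None if L.B is None else 2.0 * p1 * L.B) + Dxx
        self._A22 = AffineOp(2.0 * p1 * L.M, None if L.B is None else 2.0 * p1 * L.B) + Dyy
        self._A12 = Dxy
        A = sp.bmat([[self._A11.M, self._A12.M], [self._A12.M, self._A22.M]], format="csc")
        self._A = A
        self._lu = None
        self._factor_error: Optional[str] = None
        try:
            self._lu = spla.splu(A)
        except RuntimeError as exc:  # singular / failed factorization
            self._factor_error = str(exc)

    def solve(
        self,
        m: np.ndarray,
        phi: np.ndarray,
        bc: Optional[BoundaryCondition] = None,
        forcing: Optional[tuple[np.ndarray, np.ndarray]] = None,
        rtol: float = 1e-10,
    ) -> tuple[np.ndarray, np.ndarray, SolverReport]:
        grid = self.grid
        if m.shape != grid.shape or phi.shape != grid.shape:
            raise ValueError("m/phi shape does not match the grid")
        bc = bc if bc is not None else BoundaryCondition(self.params.v_b)
        ub, vb = bc.velocity_samples(grid.thetas)

        fx, fy = active_force_field(m, phi, self.params, grid)
        if forcing is not None:
            fx = fx + np.asarray(forcing[0], dtype=float)
            fy = fy + np.asarray(forcing[1], dtype=float)

        # boundary-affine contributions of the left-hand side
        bc1 = self._A11.B @ ub + self._A12.B @ vb
        bc2 = self._A12.B @ ub + self._A22.B @ vb
        rhs = -np.concatenate([fx.ravel() + bc1, fy.ravel() + bc2])

        if self._lu is not None:
            w = self._lu.solve(rhs)
            method = "splu"
            iters = 0
        else:
            w, info = spla.gmres(self._A, rhs, rtol=rtol, maxiter=2000)
            method = "gmres"
            iters = int(info) if info > 0 else 0
            if info != 0:
                warnings.warn("iterative force-balance solve did not converge")
        res = np.linalg.norm(self._A @ w - rhs)
        scale = max(np.linalg.norm(rhs), 1.0)
        converged = bool(res <= max(rtol * scale, 1e-8))
        if not converged:
            warnings.warn(
                f"force-balance residual {res:.3e} above tolerance; fields returned"
            )
        report = SolverReport(
            residual=float(res),
            converged=converged,
            method=method,
            iterations=iters,
            message=self._factor_error or "",
        )
        N = grid.size
        return w[:N].reshape(grid.shape), w[N:].reshape(grid.shape), report


_SOLVER_CACHE: dict[tuple, ForceBalanceSolver] = {}


def solve_force_balance(
    m: np.ndarray,
    phi: np.ndarray,
    params: ModelParams,
    bc: Optional[BoundaryCondition] = None,
    grid: Optional[DiskGrid] = None,
    forcing: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> tuple[np.ndarray, np.ndarray, SolverReport]:
    """Solve the force balance for the velocity given (m, phi).

    Convenience wrapper around :class:`ForceBalanceSolver` with a
    factorization cache keyed by (grid, p1).
    """
    if grid is None:
        raise ValueError("grid is required")
    key = (grid, params.p1)
    solver = _SOLVER_CACHE.get(key)
    if solver is None:
        solver = _SOLVER_CACHE[key] = ForceBalanceSolver(grid, params)
    return solver.solve(m, phi, bc=bc, forcing=forcing)


# --------------------------------------------------------------------------
# Velocity-derived diagnostics
# --------------------------------------------------------------------------

def _velocity_gradients(
    u: np.ndarray,
    v: np.ndarray,
    grid: DiskGrid,
    bc: Optional[BoundaryCondition] = None,
):
    """(u_x, u_y, v_x, v_y) with Dirichlet rim data when bc is given,
    one-sided extrapolation otherwise."""
    ops = get_operators(grid)
    if bc is not None:
        ub, vb = bc.velocity_samples(grid.thetas)
        Dx, Dy = ops.Dx("dirichlet"), ops.Dy("dirichlet")
        return (
            Dx.apply(u, ub), Dy.apply(u, ub),
            Dx.apply(v, vb), Dy.apply(v, vb),
        )
    Dx, Dy = ops.Dx("extrap"), ops.Dy("extrap")
    return Dx.apply(u), Dy.apply(u), Dx.apply(v), Dy.apply(v)


def divergence(
    u: np.ndarray, v: np.ndarray, grid: DiskGrid, bc: Optional[BoundaryCondition] = None
) -> np.ndarray:
    ux, _, _, vy = _velocity_gradients(u, v, grid, bc)
    return ux + vy


def vorticity(
    u: np.ndarray, v: np.ndarray, grid: DiskGrid, bc: Optional[BoundaryCondition] = None
) -> np.ndarray:
    """omega = dv/dx - du/dy, counterclockwise positive (project-wide)."""
    _, uy, vx, _ = _velocity_gradients(u, v, grid, bc)
    return vx - uy


def recover_pressure(
    u: np.ndarray,
    v: np.ndarray,
    m: np.ndarray,
    params: ModelParams,
    grid: DiskGrid,
    bc: Optional[BoundaryCondition] = None,
) -> np.ndarray:
    """Pressure from the continuity law: p = -((div v)/p1 + p0 m)/2."""
    if params.p1 == 0:
        raise ValueError("pressure recovery requires p1 > 0")
    div = divergence(u, v, grid, bc)
    return -0.5 * (div / params.p1 + params.p0 * m)


def strain_rate_diagnostics(
    u: np.ndarray,
    v: np.ndarray,
    grid: DiskGrid,
    bc: Optional[BoundaryCondition] = None,
) -> tuple[SymTensorField, np.ndarray, np.ndarray, np.ndarray]:
    """Deviatoric strain rate S_s, divergence, and the contraction data.

    ``S_s = (grad v + grad v^T - (div v) I)/2`` is traceless exactly by
    construction.  The contracting direction is the eigenvector of the
    most negative eigenvalue; the contracting rate its magnitude (a proxy
    for the local intercalation axis and strength).
    """
    ux, uy, vx, vy = _velocity_gradients(u, v, grid, bc)
    div = ux + vy
    s11 = 0.5 * (ux - vy)
    s12 = 0.5 * (uy + vx)
    S = SymTensorField(t11=s11, t12=s12, t22=-s11, role="S_s")
    lam_min, _, angle_min = S.eig()
    contracting_rate = np.abs(np.minimum(lam_min, 0.0))
    return S, div, angle_min, contracting_rate


# --------------------------------------------------------------------------
# Active-force inference from gridded (PIV-like) velocities
# --------------------------------------------------------------------------

def infer_active_force(
    vseries,
    params: ModelParams,
    smooth_space: int = 1,
    smooth_time: int = 1,
    normalize: bool = False,
) -> np.ndarray:
    """Infer the active force from a gridded velocity time series.

    For highly viscous active flows the force balance gives
    ``F_A = -F_V = -(grad(div v) + 2 p1 Lap(v))``, which can be evaluated
    from measured (PIV) velocities alone.  Velocities are first smoothed
    by a plain moving average (boxcar) over ``smooth_space`` grid cells in
    each spatial direction and ``smooth_time`` frames, then
    differentiated by central finite differences.

    Parameters
    ----------
    vseries : VelocitySeries
        Regular space-time grid of velocities (see :mod:`.lagrangian`).
    smooth_space, smooth_time : int
        Boxcar window lengths in samples (>= 1).  A time window longer
        than the series is truncated with a warning.
    normalize : bool
        If True, scale each frame by its maximal force magnitude.

    Returns
    -------
    ndarray of shape (nt, ny, nx, 2) -- (F_Ax, F_Ay) per frame.
    """
    if smooth_space < 1 or smooth_time < 1:
        raise ValueError("smoothing windows must be >= 1 sample")
    u = np.array(vseries.u, dtype=float)
    v = np.array(vseries.v, dtype=float)
    nt = u.shape[0]
    if smooth_time > nt:
        warnings.warn(
            f"time window {smooth_time} exceeds series length {nt}; truncated"
        )
        smooth_time = nt
    for axis, size in ((0, smooth_time), (1, smooth_space), (2, smooth_space)):
        if size > 1:
            u = uniform_filter1d(u, size=size, axis=axis, mode="nearest")
            v = uniform_filter1d(v, size=size, axis=axis, mode="nearest")

    x = np.asarray(vseries.x, dtype=float)
    y = np.asarray(vseries.y, dtype=float)
    out = np.empty(u.shape + (2,), dtype=float)
    p1 = params.p1
    for it in range(nt):
        ux = np.gradient(u[it], x, axis=1)
        uy = np.gradient(u[it], y, axis=0)
        vx = np.gradient(v[it], x, axis=1)
        vy = np.gradient(v[it], y, axis=0)
        div = ux + vy
        ddiv_x = np.gradient(div, x, axis=1)
        ddiv_y = np.gradient(div, y, axis=0)
        lap_u = np.gradient(ux, x, axis=1) + np.gradient(uy, y, axis=0)
        lap_v = np.gradient(vx, x, axis=1) + np.gradient(vy, y, axis=0)
        fax = -(ddiv_x + 2.0 * p1 * lap_u)
        fay = -(ddiv_y + 2.0 * p1 * lap_v)
        if normalize:
            mag = np.hypot(fax, fay).max()
            if mag > 0:
                fax, fay = fax / mag, fay / mag
        out[it, ..., 0] = fax
        out[it, ..., 1] = fay
    return out
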