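"""Dynamic morphoskeleton: trajectories, FTLE fields and their ridges.

Morphogenetic flows must be quantified by frame-invariant (objective)
diagnostics: velocities themselves change under a time-dependent shift
of reference frame, but the separation of nearby material trajectories
does not.  The finite-time Lyapunov exponent over ``[t0, tf]``,

    Lambda = ln( lambda_max( grad F^T grad F ) ) / (2 |tf - t0|),

where ``F`` is the flow map of the velocity field, measures the maximal
exponential separation rate of nearby cells.  Ridges of the *forward*
FTLE mark repellers; ridges of the *backward* FTLE (computed from the
time-reversed flow and displayed at final positions) mark attractors --
in gastrulation, the forming primitive streak.  The backward FTLE pulled
back through the forward flow map to initial positions gives the domain
of attraction (DOA): the initial location of the cells that will end up
on the attractor.

Velocities enter as a :class:`VelocitySeries` -- a time series of gridded
2D velocities, either simulation output resampled to a Cartesian grid or
imported PIV-style measurements.  Interpolation is linear in time and
bilinear in space; queries outside the domain hold the nearest boundary
value and are flagged (flagged points are excluded from ridge
statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core import DiskGrid

__all__ = [
    "VelocitySeries",
    "FTLEField",
    "Morphoskeleton",
    "flow_map",
    "ftle",
    "morphoskeleton",
    "benchmark_flow",
    "lagrangian_grid",
    "resample_disk_to_cartesian",
]


# --------------------------------------------------------------------------
# Velocity container
# --------------------------------------------------------------------------

@dataclass
class VelocitySeries:
    """Time series of gridded 2D velocities on a fixed rectangular grid.

    ``u`` and ``v`` have shape (nt, ny, nx); ``x`` (nx,), ``y`` (ny,)
    are strictly increasing; ``times`` strictly increasing (a single
    time is allowed for steady use).  The interpolation contract is
    linear in time and bilinear in space; out-of-domain queries hold the
    nearest in-domain value and are flagged by the samplers.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    exact_flow_map: Optional[Callable] = None  # analytic oracle, if known

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.ndim == 2:
            self.u = self.u[None]
            self.v = self.v[None]
        nt, ny, nx = self.u.shape
        if self.v.shape != (nt, ny, nx):
            raise ValueError("u and v must share one shape")
        if self.times.size != nt:
            raise ValueError("times length must match the number of frames")
        if self.x.size != nx or self.y.size != ny:
            raise ValueError("x/y lengths must match the grid shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.x) <= 0) or np.any(np.diff(self.y) <= 0):
            raise ValueError("spatial coordinates must be strictly increasing")
        self._build_interp()

    def _build_interp(self):
        vals = np.stack([self.u, self.v], axis=-1)
        if self.times.size == 1:
            self._interp = RegularGridInterpolator(
                (self.y, self.x), vals[0], method="linear"
            )
            self._steady = True
        else:
            self._interp = RegularGridInterpolator(
                (self.times, self.y, self.x), vals, method="linear"
            )
            self._steady = False

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def tf(self) -> float:
        return float(self.times[-1])

    def sample(self, t: float, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Velocities at points (N, 2) = (x, y); returns (vel, escaped).

        Out-of-domain coordinates are clipped to the boundary (hold
        nearest) and reported in the boolean ``escaped`` mask.
        """
        pts = np.atleast_2d(pts)
        xq = pts[:, 0]
        yq = pts[:, 1]
        escaped = (
            (xq < self.x[0]) | (xq > self.x[-1])
            | (yq < self.y[0]) | (yq > self.y[-1])
        )
        xq = np.clip(xq, self.x[0], self.x[-1])
        yq = np.clip(yq, self.y[0], self.y[-1])
        if self._steady:
            return self._interp(np.column_stack([yq, xq])), escaped
        tq = np.full_like(xq, np.clip(t, self.times[0], self.times[-1]))
        return self._interp(np.column_stack([tq, yq, xq])), escaped

    def shifted(self, drift: Callable[[float], Sequence[float]]) -> "VelocitySeries":
        """A copy with a uniform time-dependent translation added
        (frame change; used to exercise objectivity)."""
        g = np.array([drift(t) for t in self.times], dtype=float)
        return VelocitySeries(
            times=self.times.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            u=self.u + g[:, 0][:, None, None],
            v=self.v + g[:, 1][:, None, None],
        )


# --------------------------------------------------------------------------
# Trajectory integration
# --------------------------------------------------------------------------

def flow_map(
    vseries: VelocitySeries,
    x0: np.ndarray,
    t0: float,
    tf: float,
    n_steps: Optional[int] = None,
    return_escaped: bool = False,
):
    """Advect points from t0 to tf (either order) through the series.

    Fixed-step RK4 on the space-time-interpolated velocity, vectorized
    over points; backward maps integrate with reversed time.  ``x0`` has
    shape (N, 2).  Points whose trajectory leaves the domain follow the
    held (nearest-boundary) velocity and are flagged.
    """
    x = np.atleast_2d(np.asarray(x0, dtype=float)).copy()
    T = tf - t0
    if T == 0:
        out = (x, np.zeros(len(x), dtype=bool))
        return out if return_escaped else x
    if n_steps is None:
        if vseries._steady or vseries.times.size < 2:
            n_frames = 1
        else:
            span = vseries.times[-1] - vseries.times[0]
            n_frames = max(1, int(round(abs(T) / span * (vseries.times.size - 1))))
        n_steps = max(32, 4 * n_frames)
    dt = T / n_steps
    escaped = np.zeros(len(x), dtype=bool)
    t = t0
    for _ in range(n_steps):
        k1, e1 = vseries.sample(t, x)
        k2, e2 = vseries.sample(t + 0.5 * dt, x + 0.5 * dt * k1)
        k3, e3 = vseries.sample(t + 0.5 * dt, x + 0.5 * dt * k2)
        k4, e4 = vseries.sample(t + dt, x + dt * k3)
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        escaped |= e1 | e2 | e3 | e4
        t += dt
    escaped |= (
        (x[:, 0] < vseries.x[0]) | (x[:, 0] > vseries.x[-1])
        | (x[:, 1] < vseries.y[0]) | (x[:, 1] > vseries.y[-1])
    )
    return (x, escaped) if return_escaped else x


# --------------------------------------------------------------------------
# FTLE
# --------------------------------------------------------------------------

@dataclass
class FTLEField:
    """FTLE values on a rectangular evaluation grid.

    ``direction`` is "forward" or "backward"; ``display`` records whether
    the values sit at initial positions (forward FTLE, DOA) or final
    positions (attractors).  ``flags`` marks nodes whose auxiliary
    trajectories left the domain (excluded from ridge statistics).
    """

    t0: float
    tf: float
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    direction: str
    display: str
    flags: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.tf == self.t0:
            raise ValueError("FTLE requires tf != t0")
        if self.flags is None:
            self.flags = np.zeros_like(self.values, dtype=bool)


def ftle(
    vseries: VelocitySeries,
    x: np.ndarray,
    y: np.ndarray,
    t0: float,
    tf: float,
    direction: str = "forward",
    h_aux: Optional[float] = None,
    n_steps: Optional[int] = None,
) -> FTLEField:
    """FTLE on the grid (x, y) over [t0, tf].

    Forward: seeds at initial positions, integrated t0 -> tf.  Backward:
    seeds at *final* positions, integrated tf -> t0 (values displayed at
    final positions).  The flow-map gradient uses auxiliary four-point
    stencils of half-spacing ``h_aux`` (default half the smaller grid
    step), giving better ridge fidelity than differencing the main grid.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    if tf == t0:
        raise ValueError("FTLE requires tf != t0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if h_aux is None:
        h_aux = 0.5 * min(np.min(np.diff(x)), np.min(np.diff(y)))
    X, Y = np.meshgrid(x, y)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    npts = len(pts)
    offsets = np.array([[h_aux, 0], [-h_aux, 0], [0, h_aux], [0, -h_aux]])
    seeds = (pts[None, :, :] + offsets[:, None, :]).reshape(-1, 2)
    if direction == "forward":
        ta, tb = t0, tf
    else:
        ta, tb = tf, t0
    mapped, escaped = flow_map(vseries, seeds, ta, tb, n_steps=n_steps, return_escaped=True)
    mapped = mapped.reshape(4, npts, 2)
    escaped = escaped.reshape(4, npts).any(axis=0)
    # centred gradient of the flow map from the auxiliary stencil
    dFdx = (mapped[0] - mapped[1]) / (2.0 * h_aux)
    dFdy = (mapped[2] - mapped[3]) / (2.0 * h_aux)
    # Cauchy-Green tensor C = gradF^T gradF
    c11 = dFdx[:, 0] ** 2 + dFdx[:, 1] ** 2
    c22 = dFdy[:, 0] ** 2 + dFdy[:, 1] ** 2
    c12 = dFdx[:, 0] * dFdy[:, 0] + dFdx[:, 1] * dFdy[:, 1]
    mean = 0.5 * (c11 + c22)
    rad = np.sqrt(np.maximum(0.25 * (c11 - c22) ** 2 + c12**2, 0.0))
    lam_max = mean + rad
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(lam_max > 0, np.log(np.maximum(lam_max, 1e-300)), np.nan)
    vals = vals / (2.0 * abs(tf - t0))
    return FTLEField(
        t0=t0,
        tf=tf,
        x=x,
        y=y,
        values=vals.reshape(Y.shape),
        direction=direction,
        display="initial_positions" if direction == "forward" else "final_positions",
        flags=escaped.reshape(Y.shape),
    )


# --------------------------------------------------------------------------
# Ridge extraction and the morphoskeleton
# --------------------------------------------------------------------------

def _ridge_mask(fld: FTLEField, quantile: float) -> np.ndarray:
    """Ridge cells: above the quantile AND a local maximum transverse to
    the ridge (sampled along the strongest-downward-curvature direction
    of the local Hessian).  A constant field yields an empty mask."""
    vals = fld.values
    ok = np.isfinite(vals) & ~fld.flags
    if not np.any(ok):
        return np.zeros_like(vals, dtype=bool)
    pool = vals[ok]
    if pool.max() - pool.min() < 1e-12 * max(1.0, abs(pool.max())):
        return np.zeros_like(vals, dtype=bool)  # constant field convention
    thresh = np.quantile(pool, quantile)
    cand = ok & (vals >= thresh)
    if not np.any(cand):
        return np.zeros_like(vals, dtype=bool)

    x, y = fld.x, fld.y
    dx = float(np.min(np.diff(x)))
    dy = float(np.min(np.diff(y)))
    safe = np.where(np.isfinite(vals), vals, pool.min())
    gy, gx = np.gradient(safe, y, x)
    hyy, hyx = np.gradient(gy, y, x)
    hxy, hxx = np.gradient(gx, y, x)
    hxy = 0.5 * (hxy + hyx)
    # eigenvector of the most negative Hessian eigenvalue (transverse dir)
    mean = 0.5 * (hxx + hyy)
    rad = np.sqrt(np.maximum(0.25 * (hxx - hyy) ** 2 + hxy**2, 0.0))
    lam_min = mean - rad
    ang = 0.5 * np.arctan2(2.0 * hxy, hxx - hyy) + 0.5 * np.pi  # min-eig direction
    interp = RegularGridInterpolator(
        (y, x), safe, bounds_error=False, fill_value=None
    )
    X, Y = np.meshgrid(x, y)
    step = max(dx, dy)
    ex = np.cos(ang) * step
    ey = np.sin(ang) * step
    p_plus = np.column_stack([(Y + ey)[cand], (X + ex)[cand]])
    p_minus = np.column_stack([(Y - ey)[cand], (X - ex)[cand]])
    v_plus = interp(p_plus)
    v_minus = interp(p_minus)
    centre = vals[cand]
    is_max = (centre >= v_plus) & (centre >= v_minus) & (lam_min[cand] < 0)
    mask = np.zeros_like(vals, dtype=bool)
    mask[cand] = is_max
    return mask


@dataclass
class Morphoskeleton:
    """Repellers, attractors and the domain of attraction of a flow."""

    repeller_mask: np.ndarray   # on the initial grid (forward FTLE ridges)
    attractor_mask: np.ndarray  # on the final grid (backward FTLE ridges)
    doa: FTLEField              # backward FTLE at initial positions
    forward: FTLEField
    backward: FTLEField


def morphoskeleton(
    vseries: VelocitySeries,
    x: np.ndarray,
    y: np.ndarray,
    t0: float,
    tf: float,
    ridge_quantile: float = 0.95,
    h_aux: Optional[float] = None,
    n_steps: Optional[int] = None,
) -> Morphoskeleton:
    """Extract the dynamic morphoskeleton over [t0, tf].

    Repellers are ridge cells of the forward FTLE; attractors of the
    backward FTLE at final positions; the DOA is the backward FTLE
    pulled back through the forward flow map to initial positions.
    """
    fwd = ftle(vseries, x, y, t0, tf, "forward", h_aux=h_aux, n_steps=n_steps)
    bwd = ftle(vseries, x, y, t0, tf, "backward", h_aux=h_aux, n_steps=n_steps)
    repeller = _ridge_mask(fwd, ridge_quantile)
    attractor = _ridge_mask(bwd, ridge_quantile)

    X, Y = np.meshgrid(x, y)
    pts0 = np.column_stack([X.ravel(), Y.ravel()])
    mapped, escaped = flow_map(vseries, pts0, t0, tf, n_steps=n_steps, return_escaped=True)
    interp = RegularGridInterpolator(
        (bwd.y, bwd.x), np.where(np.isfinite(bwd.values), bwd.values, np.nan),
        bounds_error=False, fill_value=np.nan,
    )
    doa_vals = interp(np.column_stack([mapped[:, 1], mapped[:, 0]])).reshape(Y.shape)
    doa = FTLEField(
        t0=t0, tf=tf, x=x, y=y,
        values=doa_vals,
        direction="backward",
        display="initial_positions",
        flags=escaped.reshape(Y.shape) | ~np.isfinite(doa_vals),
    )
    return Morphoskeleton(
        repeller_mask=repeller,
        attractor_mask=attractor,
        doa=doa,
        forward=fwd,
        backward=bwd,
    )


# --------------------------------------------------------------------------
# Analytic benchmark flows (fixture generator)
# --------------------------------------------------------------------------

def benchmark_flow(
    name: str,
    extent: float = 2.0,
    n: int = 64,
    times: Optional[np.ndarray] = None,
    **params,
) -> VelocitySeries:
    """Analytic test flows sampled onto a grid, with closed-form flow
    maps attached where available (used as oracles in tests).

    Names: uniform(vx, vy), rigid_rotation(omega), saddle(s),
    simple_shear(gamma), compressive_line(), double_gyre(A, eps, omega).
    """
    if times is None:
        times = np.linspace(0.0, 1.0, 5)
    times = np.asarray(times, dtype=float)
    x = np.linspace(-extent, extent, n)
    y = np.linspace(-extent, extent, n)
    X, Y = np.meshgrid(x, y)
    exact = None

    if name == "uniform":
        vx = params.get("vx", 1.0)
        vy = params.get("vy", 0.5)
        U = np.full_like(X, vx)
        V = np.full_like(Y, vy)

        def exact(p, t0, tf):
            p = np.atleast_2d(p)
            return p + (tf - t0) * np.array([vx, vy])

    elif name == "rigid_rotation":
        om = params.get("omega", 1.0)
        U, V = -om * Y, om * X

        def exact(p, t0, tf):
            p = np.atleast_2d(p)
            a = om * (tf - t0)
            R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            return p @ R.T

    elif name == "saddle":
        s = params.get("s", 1.0)
        U, V = s * X, -s * Y

        def exact(p, t0, tf):
            p = np.atleast_2d(p)
            T = tf - t0
            return np.column_stack([p[:, 0] * np.exp(s * T), p[:, 1] * np.exp(-s * T)])

    elif name == "simple_shear":
        g = params.get("gamma", 1.0)
        U, V = g * Y, np.zeros_like(X)

        def exact(p, t0, tf):
            p = np.atleast_2d(p)
            return np.column_stack([p[:, 0] + g * (tf - t0) * p[:, 1], p[:, 1]])

    elif name == "compressive_line":
        U = np.zeros_like(X)
        V = -np.tanh(Y)

        def exact(p, t0, tf):
            p = np.atleast_2d(p)
            T = tf - t0
            return np.column_stack(
                [p[:, 0], np.arcsinh(np.sinh(p[:, 1]) * np.exp(-T))]
            )

    elif name == "double_gyre":
        A = params.get("A", 0.1)
        eps = params.get("eps", 0.25)
        om = params.get("omega", 2.0 * np.pi / 10.0)
        x = np.linspace(0.0, 2.0, n)
        y = np.linspace(0.0, 1.0, max(8, n // 2))
        X, Y = np.meshgrid(x, y)
        U = np.empty((times.size,) + X.shape)
        V = np.empty_like(U)
        for i, t in enumerate(times):
            a = eps * np.sin(om * t)
            b = 1.0 - 2.0 * a
            f = a * X**2 + b * X
            dfdx = 2.0 * a * X + b
            U[i] = -np.pi * A * np.sin(np.pi * f) * np.cos(np.pi * Y)
            V[i] = np.pi * A * np.cos(np.pi * f) * np.sin(np.pi * Y) * dfdx
        return VelocitySeries(times=times, x=x, y=y, u=U, v=V)

    else:
        raise ValueError(f"unknown benchmark flow {name!r}")

    U = np.repeat(U[None], times.size, axis=0)
    V = np.repeat(V[None], times.size, axis=0)
    return VelocitySeries(times=times, x=x, y=y, u=U, v=V, exact_flow_map=exact)


# --------------------------------------------------------------------------
# Deformed Lagrangian grids
# --------------------------------------------------------------------------

def lagrangian_grid(
    vseries: VelocitySeries,
    t0: float,
    tf: float,
    n_lines: int = 10,
    pts_per_line: int = 50,
    extent: Optional[tuple[float, float, float, float]] = None,
    n_steps: Optional[int] = None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Material grid lines advected from t0 to tf for visualization.

    Returns (initial_polylines, deformed_polylines); each polyline is an
    (npts, 2) array.  Cell areas of the deformed grid obey the Liouville
    relation area_f = area_0 * exp(integral of div v along the path).
    """
    if extent is None:
        extent = (vseries.x[0], vseries.x[-1], vseries.y[0], vseries.y[-1])
    xa, xb, ya, yb = extent
    xs = np.linspace(xa, xb, n_lines)
    ys = np.linspace(ya, yb, n_lines)
    lines0: list[np.ndarray] = []
    for xv in xs:
        t = np.linspace(ya, yb, pts_per_line)
        lines0.append(np.column_stack([np.full_like(t, xv), t]))
    for yv in ys:
        t = np.linspace(xa, xb, pts_per_line)
        lines0.append(np.column_stack([t, np.full_like(t, yv)]))
    all_pts = np.vstack(lines0)
    mapped = flow_map(vseries, all_pts, t0, tf, n_steps=n_steps)
    out: list[np.ndarray] = []
    i = 0
    for ln in lines0:
        out.append(mapped[i : i + len(ln)])
        i += len(ln)
    return lines0, out


# --------------------------------------------------------------------------
# Disk -> Cartesian resampling (for feeding simulations into the DM)
# --------------------------------------------------------------------------

def resample_disk_to_cartesian(
    grid: DiskGrid,
    fields: Sequence[np.ndarray],
    x: np.ndarray,
    y: np.ndarray,
    rim_values: Optional[Sequence[np.ndarray]] = None,
    method: str = "linear",
) -> list[np.ndarray]:
    """(r, theta) resampling of disk fields onto a Cartesian grid.

    The (r, theta) table is padded with a centre value (the mean of the
    innermost ring -- second-order for smooth Cartesian-component
    fields), a rim ring (given ``rim_values`` such as the epiboly
    boundary velocity, or linear extrapolation), and a periodic wrap in
    theta.  Query points outside the disk are clipped to r = R (hold
    nearest).  ``method`` is "linear" (default; the trajectory-analysis
    interpolation contract) or "cubic" (C1-smooth, needed when second
    derivatives of the resampled field are taken, as in force
    inference).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X, Y = np.meshgrid(x, y)
    r_q = np.hypot(X, Y)
    th_q = np.mod(np.arctan2(Y, X), 2.0 * np.pi)
    r_q = np.clip(r_q, 0.0, grid.R)
    pts = np.column_stack([r_q.ravel(), th_q.ravel()])

    npad = 3 if method == "cubic" else 1
    r_ext = np.concatenate([[0.0], grid.radii, [grid.R]])
    th_ext = np.concatenate(
        [grid.thetas[-npad:] - 2.0 * np.pi, grid.thetas, grid.thetas[:npad] + 2.0 * np.pi]
    )
    out = []
    for i, f in enumerate(fields):
        centre = np.full(grid.ntheta, f[0].mean())
        if rim_values is not None and rim_values[i] is not None:
            rim = np.asarray(rim_values[i], dtype=float)
        else:
            rim = 1.5 * f[-1] - 0.5 * f[-2]
        tab = np.vstack([centre, f, rim])
        tab = np.hstack([tab[:, -npad:], tab, tab[:, :npad]])
        interp = RegularGridInterpolator((r_ext, th_ext), tab, method=method)
        out.append(interp(pts).reshape(X.shape))
    return out
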