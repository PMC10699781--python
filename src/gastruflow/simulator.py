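"""Time integration of the coupled model in 1D and 2D, plus scenarios.

The 2D loop is quasi-static in the velocity: the elliptic force balance
is re-solved from the current (m, phi) at every step (inertia is
negligible at these scales), then the cable fields advance by an
operator-split step,

* advection (first-order upwind on the polar grid) + reaction,
  together, by the explicit SSP-RK2 (Heun) method under an advective /
  kinetic CFL bound;
* along-cable diffusion of m by backward Euler with the conservative
  finite-volume operator of :mod:`.cable_dynamics` (the angular CFL of
  an explicit scheme collapses near the disk centre, where cell arcs
  shrink like r0*dtheta; the implicit step removes that constraint at
  the cost of a sparse factorization, refreshed every few steps as the
  orientation field drifts).

Orientation is integrated through the double-angle pair
``(cos 2 phi, sin 2 phi)`` (renormalized each step), which advects and
rotates without branch cuts; no boundary data are needed where
characteristics leave the domain (epiboly makes the rim outflow).

Scenarios express the gastrulation modes as initial data: every mode
starts from the *unstable* uniform equilibrium of m plus Gaussian
features (a posterior sickle arc for the wild type, two arcs for twins,
a marginal ring for the teleost mode) and azimuthal cables; the
reptilian and amphibian modes reuse the wild-type and teleost patterns
with the ingression propensity p0 set to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import (
    DiskGrid,
    FieldState,
    ModelParams,
    canonicalize_phi,
    double_angle_to_phi,
    phi_to_double_angle,
)
from .mechanics import (
    BoundaryCondition,
    ForceBalanceSolver,
    SolverReport,
    get_operators,
    strain_rate_diagnostics,
)
from .cable_dynamics import (
    anisotropic_diffusion_matrix,
    reaction_rate,
    reaction_rate_derivative,
    uniform_equilibria,
)
from .config import load_defaults

__all__ = [
    "GaussianFeature",
    "Scenario",
    "SimulationResult",
    "Result1D",
    "build_scenario",
    "run_1d",
    "run_2d",
    "parameter_sweep",
    "streak_metrics",
]

SCENARIO_NAMES = ("wild_type", "twin", "reptilian", "teleost", "amphibian", "custom")


# --------------------------------------------------------------------------
# Scenario construction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianFeature:
    """One Gaussian feature added to the unstable-equilibrium baseline.

    kind "arc": Gaussian cross-section (width ``sigma``, fraction of R)
    around a circular arc at ``radius*R``, centred ``center_deg`` away
    from the posterior direction with an angular Gaussian envelope of
    scale ``half_width_deg/2``.  kind "ring": rotationally symmetric
    Gaussian around ``radius*R``.  kind "point": isotropic Gaussian at
    (radius*R, center_deg).
    """

    kind: str
    radius: float
    sigma: float
    amplitude: float
    center_deg: float = 0.0
    half_width_deg: float = 30.0

    def __post_init__(self):
        if self.kind not in ("arc", "ring", "point"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("feature amplitude must be >= 0")
        if not 0.0 < self.radius < 1.0:
            raise ValueError("feature radius (fraction of R) must be inside the disk")

    def evaluate(self, grid: DiskGrid) -> np.ndarray:
        r, th = grid.mesh_polar()
        r_c = self.radius * grid.R
        sig = self.sigma * grid.R
        center = grid.ap_angle + np.deg2rad(self.center_deg)
        if self.kind == "ring":
            return self.amplitude * np.exp(-((r - r_c) ** 2) / (2 * sig**2))
        if self.kind == "arc":
            dth = np.angle(np.exp(1j * (th - center)))
            sig_th = np.deg2rad(self.half_width_deg) / 2.0
            return (
                self.amplitude
                * np.exp(-((r - r_c) ** 2) / (2 * sig**2))
                * np.exp(-(dth**2) / (2 * sig_th**2))
            )
        # point feature
        x, y = grid.mesh_xy()
        x0, y0 = r_c * np.cos(center), r_c * np.sin(center)
        d2 = (x - x0) ** 2 + (y - y0) ** 2
        return self.amplitude * np.exp(-d2 / (2 * sig**2))


@dataclass
class Scenario:
    """Named initial-condition builder with optional parameter override."""

    name: str = "custom"
    features: Sequence[GaussianFeature] = field(default_factory=tuple)
    phi_init: Union[str, np.ndarray] = "azimuthal"
    p0_override: Optional[float] = None
    noise_amplitude: float = 0.0
    seed: Optional[int] = None

    @classmethod
    def from_name(cls, name: str) -> "Scenario":
        cfg = load_defaults()["scenarios"]
        if name not in cfg:
            raise ValueError(
                f"unknown scenario {name!r}; known: {sorted(cfg)} (or 'custom')"
            )
        entry = cfg[name]
        p0_override = entry.get("p0_override")
        while "like" in entry:
            entry = cfg[entry["like"]]
        feats = tuple(GaussianFeature(**f) for f in entry["features"])
        return cls(
            name=name,
            features=feats,
            phi_init=entry.get("phi_init", "azimuthal"),
            p0_override=p0_override,
        )


def build_scenario(
    scenario: Union[str, Scenario],
    params: ModelParams,
    grid: DiskGrid,
) -> tuple[FieldState, ModelParams]:
    """Initial fields for a named (or custom) scenario.

    m(x, t0) is the *middle* (unstable) uniform root plus the feature
    sum; phi(x, t0) is azimuthal unless a custom field is given.  The
    parameter set must have three uniform roots -- otherwise the
    calibration procedure (choose p3..p6 so f(m) has three roots with
    the middle one near 0.3 m_sat, then size p7 for a 0.1 R diffusion
    length) must be redone, and an explicit error says so.
    """
    if isinstance(scenario, str):
        scenario = Scenario.from_name(scenario)
    eq = uniform_equilibria(params)
    if len(eq.roots) < 3:
        raise ValueError(
            f"parameter set has {len(eq.roots)} uniform equilibria; scenarios "
            "require the bistable regime (3 roots). Recalibrate p3..p6 so that "
            "f(m) = p3 - p4 m exp(-p5 m/2) - p6 m has three roots with the "
            "middle root near 0.3*m_sat, then size p7 for a ~0.1 R diffusion "
            "length."
        )
    m_unstable = eq.roots[1]
    m0 = np.full(grid.shape, m_unstable)
    for feat in scenario.features:
        m0 = m0 + feat.evaluate(grid)
    if scenario.noise_amplitude > 0:
        rng = np.random.default_rng(scenario.seed)
        m0 = np.maximum(m0 + scenario.noise_amplitude * rng.standard_normal(grid.shape), 0.0)
    if isinstance(scenario.phi_init, str):
        if scenario.phi_init != "azimuthal":
            raise ValueError("phi_init must be 'azimuthal' or an array")
        _, th = grid.mesh_polar()
        phi0 = canonicalize_phi(th + 0.5 * np.pi)
    else:
        phi0 = canonicalize_phi(np.asarray(scenario.phi_init, dtype=float))
    out_params = params
    if scenario.p0_override is not None:
        out_params = params.replace(p0=scenario.p0_override)
    return FieldState(grid=grid, t=0.0, m=m0, phi=phi0), out_params


# --------------------------------------------------------------------------
# Upwind advection on the polar grid
# --------------------------------------------------------------------------

def _upwind_advect(q, vr, vt, grid: DiskGrid):
    """-(v . grad) q by first-order upwind; across-origin and mirror ghosts."""
    h, dth = grid.dr, grid.dtheta
    half = grid.ntheta // 2
    q_up = np.vstack([q[1:], q[-1:]])                       # rim mirror ghost
    q_dn = np.vstack([np.roll(q[:1], -half, axis=1), q[:-1]])  # across origin
    dqdr = np.where(vr > 0, (q - q_dn) / h, (q_up - q) / h)
    q_p = np.roll(q, -1, axis=1)
    q_m = np.roll(q, 1, axis=1)
    dqdth = np.where(vt > 0, (q - q_m) / dth, (q_p - q) / dth)
    r = grid.radii[:, None]
    return -(vr * dqdr + vt * dqdth / r)


# --------------------------------------------------------------------------
# Results
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Snapshots plus scalar summary series of one run.

    Summary columns: t, max_m, min_div, ingression_flux
    (= integral of min(div v, 0) dA, a negative number), streak_length
    (AP extent of the region with div v below a fixed threshold) and
    symmetry_error (relative mirror asymmetry of m about the AP axis).
    """

    grid: DiskGrid
    params: ModelParams
    times: np.ndarray
    states: list[FieldState]
    summaries: pd.DataFrame
    reports: list[SolverReport] = field(default_factory=list)
    scenario_name: str = "custom"
    completed: bool = True
    message: str = ""

    def to_velocity_series(self, n: int = 96, pad: float = 0.0):
        """Resample the velocity snapshots onto a Cartesian grid.

        Returns a :class:`~gastruflow.lagrangian.VelocitySeries` covering
        the square [-R-pad, R+pad]^2; points outside the disk hold the
        rim (epiboly) velocity of the nearest boundary point.
        """
        from .lagrangian import VelocitySeries, resample_disk_to_cartesian

        bc = BoundaryCondition(self.params.v_b)
        ub, vb = bc.velocity_samples(self.grid.thetas)
        half = self.grid.R + pad
        x = np.linspace(-half, half, n)
        y = np.linspace(-half, half, n)
        u_list, v_list = [], []
        for st in self.states:
            u_c, v_c = resample_disk_to_cartesian(
                self.grid, [st.u, st.v], x, y, rim_values=[ub, vb]
            )
            u_list.append(u_c)
            v_list.append(v_c)
        return VelocitySeries(
            times=self.times.copy(),
            x=x,
            y=y,
            u=np.stack(u_list),
            v=np.stack(v_list),
        )


def streak_metrics(
    state: FieldState,
    params: ModelParams,
    div: Optional[np.ndarray] = None,
    div_threshold: Optional[float] = None,
) -> dict:
    """Scalar streak/ingression diagnostics of one snapshot."""
    grid = state.grid
    bc = BoundaryCondition(params.v_b)
    if div is None:
        _, div, _, _ = strain_rate_diagnostics(state.u, state.v, grid, bc)
    if div_threshold is None:
        div_threshold = load_defaults()["run"]["streak_div_threshold"]
    areas = grid.cell_areas()
    ingression = float(np.sum(np.minimum(div, 0.0) * areas))
    mask = div < div_threshold
    if np.any(mask):
        x, y = grid.mesh_xy()
        ax, ay = grid.ap_unit()
        s = (x * ax + y * ay)[mask]
        streak_length = float(s.max() - s.min())
    else:
        streak_length = 0.0
    mir = grid.mirror_index()
    scale = max(float(np.abs(state.m).max()), 1e-300)
    symmetry_error = float(np.abs(state.m - state.m[:, mir]).max() / scale)
    return {
        "max_m": float(state.m.max()),
        "min_div": float(div.min()),
        "ingression_flux": ingression,
        "streak_length": streak_length,
        "symmetry_error": symmetry_error,
    }


# --------------------------------------------------------------------------
# 2D integration
# --------------------------------------------------------------------------

def run_2d(
    scenario: Union[str, Scenario, FieldState],
    params: ModelParams,
    grid: Optional[DiskGrid] = None,
    t_end: Optional[float] = None,
    cfl: Optional[float] = None,
    dt_max: Optional[float] = None,
    output_every: Optional[float] = None,
    refactor_every: Optional[int] = None,
    div_threshold: Optional[float] = None,
) -> SimulationResult:
    """Integrate the coupled 2D system on the disk.

    ``scenario`` may be a scenario name, a :class:`Scenario`, or a
    ready-made initial :class:`FieldState` (whose grid then wins).
    Returns the snapshot series at the requested cadence together with
    summary metrics; a solver failure or NaN mid-run yields a truncated
    result with ``completed=False``.
    """
    run_cfg = load_defaults()["run"]
    t_end = run_cfg["t_end"] if t_end is None else t_end
    cfl = run_cfg["cfl"] if cfl is None else cfl
    dt_max = run_cfg["dt_max"] if dt_max is None else dt_max
    output_every = run_cfg["output_every"] if output_every is None else output_every
    refactor_every = run_cfg["refactor_every"] if refactor_every is None else refactor_every

    scenario_name = "custom"
    if isinstance(scenario, FieldState):
        state0 = scenario
        grid = state0.grid
    else:
        if grid is None:
            raise ValueError("grid is required when building from a scenario")
        if isinstance(scenario, str):
            scenario_name = scenario
        else:
            scenario_name = scenario.name
        state0, params = build_scenario(scenario, params, grid)

    solver = ForceBalanceSolver(grid, params)
    bc = BoundaryCondition(params.v_b)
    ops = get_operators(grid)
    Dx_d, Dy_d = ops.Dx("dirichlet"), ops.Dy("dirichlet")
    ub, vb = bc.velocity_samples(grid.thetas)
    r_mesh, th_mesh = grid.mesh_polar()
    cos_t, sin_t = np.cos(th_mesh), np.sin(th_mesh)
    r_arc = grid.radii[:, None] * grid.dtheta
    N = grid.size
    identity = sp.identity(N, format="csr")

    m = state0.m.copy()
    c2, s2 = phi_to_double_angle(state0.phi)
    t = 0.0

    times, states, reports, rows = [], [], [], []
    diff_lu = None
    diff_dt = None
    steps_since_factor = 10**9
    next_output = 0.0
    completed = True
    message = ""

    def explicit_rates(m_, c2_, s2_, u, v, ux, uy, vx, vy):
        vr = u * cos_t + v * sin_t
        vt = -u * sin_t + v * cos_t
        omega = vx - uy
        rot = 0.5 * omega + params.p2 * (
            0.5 * (uy + vx) * c2_ + 0.5 * (vy - ux) * s2_
        )
        dm = _upwind_advect(m_, vr, vt, grid) + reaction_rate(m_, params)
        dc2 = _upwind_advect(c2_, vr, vt, grid) - 2.0 * s2_ * rot
        ds2 = _upwind_advect(s2_, vr, vt, grid) + 2.0 * c2_ * rot
        return dm, dc2, ds2

    max_steps = 10**7
    step = 0
    while True:
        phi = double_angle_to_phi(c2, s2)
        u, v, report = solver.solve(m, phi, bc=bc)
        if not np.isfinite(u).all() or not np.isfinite(m).all():
            completed = False
            message = f"non-finite fields at t={t:.4f}"
            warnings.warn(message)
            break

        if t >= next_output - 1e-12 or t >= t_end - 1e-12:
            st = FieldState(grid=grid, t=t, m=np.maximum(m, 0.0), phi=phi, u=u, v=v)
            from .mechanics import recover_pressure

            st.p = recover_pressure(u, v, st.m, params, grid, bc)
            _, div, _, _ = strain_rate_diagnostics(u, v, grid, bc)
            row = {"t": t, **streak_metrics(st, params, div=div, div_threshold=div_threshold)}
            times.append(t)
            states.append(st)
            reports.append(report)
            rows.append(row)
            next_output = t + output_every
        if t >= t_end - 1e-12:
            break
        if not report.converged:
            completed = False
            message = f"force-balance solver failed at t={t:.4f}"
            warnings.warn(message)
            break

        # CFL time step (advective + kinetic)
        vr = u * cos_t + v * sin_t
        vt = -u * sin_t + v * cos_t
        speed = np.abs(vr) / grid.dr + np.abs(vt) / r_arc
        dt_adv = cfl / max(speed.max(), 1e-12)
        dt_kin = 0.25 / max(np.abs(reaction_rate_derivative(m, params)).max(), 1e-12)
        dt = min(dt_max, dt_adv, dt_kin, t_end - t)

        # Heun step for advection + reaction (+ orientation rotation)
        ux, uy = Dx_d.apply(u, ub), Dy_d.apply(u, ub)
        vx, vy = Dx_d.apply(v, vb), Dy_d.apply(v, vb)
        dm1, dc1, ds1 = explicit_rates(m, c2, s2, u, v, ux, uy, vx, vy)
        m1 = m + dt * dm1
        c21 = c2 + dt * dc1
        s21 = s2 + dt * ds1
        dm2, dc2_, ds2_ = explicit_rates(m1, c21, s21, u, v, ux, uy, vx, vy)
        m = 0.5 * (m + m1 + dt * dm2)
        c2 = 0.5 * (c2 + c21 + dt * dc2_)
        s2 = 0.5 * (s2 + s21 + dt * ds2_)

        # implicit along-cable diffusion (lagged refactorization)
        if params.p7 > 0:
            if (
                diff_lu is None
                or steps_since_factor >= refactor_every
                or diff_dt is None
                or abs(dt - diff_dt) > 1e-3 * diff_dt
            ):
                D = anisotropic_diffusion_matrix(c2, s2, grid)
                diff_lu = spla.splu((identity - dt * params.p7 * D).tocsc())
                diff_dt = dt
                steps_since_factor = 0
            m = diff_lu.solve(m.ravel()).reshape(grid.shape)
            steps_since_factor += 1

        m_min = m.min()
        if m_min < -1e-4:
            warnings.warn(f"intensity undershoot {m_min:.2e} at t={t:.4f}")
        m = np.maximum(m, 0.0)
        norm = np.hypot(c2, s2)
        np.divide(c2, norm, out=c2, where=norm > 1e-12)
        np.divide(s2, norm, out=s2, where=norm > 1e-12)

        t += dt
        step += 1
        if step > max_steps:
            completed = False
            message = "step budget exhausted"
            break

    return SimulationResult(
        grid=grid,
        params=params,
        times=np.asarray(times),
        states=states,
        summaries=pd.DataFrame(rows),
        reports=reports,
        scenario_name=scenario_name,
        completed=completed,
        message=message,
    )


# --------------------------------------------------------------------------
# 1D model
# --------------------------------------------------------------------------

@dataclass
class Result1D:
    """1D run output: m(x, t), u(x, t) and u_x(x, t) snapshots."""

    x: np.ndarray
    times: np.ndarray
    m: np.ndarray   # (nt, nx)
    u: np.ndarray
    ux: np.ndarray
    summaries: pd.DataFrame
    params: ModelParams
    completed: bool = True


def _solve_1d_velocity(m, dx, alpha, periodic):
    """1D force balance (2 p1 + 1) u_xx + p1 (p0 + 1) m_x = 0.

    Integrates to u_x = -alpha (m - mean m); u fixed by u = 0 at the
    ends (no-flux domain) or zero mean (periodic).
    """
    ux = -alpha * (m - m.mean())
    u = np.cumsum(ux) * dx - 0.5 * dx * ux  # midpoint cumulative integral
    if periodic:
        u = u - u.mean()
    else:
        u = u - u[0] + 0.5 * dx * ux[0]  # u(0) = 0 at the left wall
    return u, ux


def run_1d(
    params: ModelParams,
    ic: np.ndarray,
    domain_length: float = 10.0,
    t_end: float = 20.0,
    periodic: bool = False,
    cfl: float = 0.8,
    dt_max: float = 0.02,
    output_every: float = 0.5,
) -> Result1D:
    """Integrate the 1D reduction of the model.

    The 1D model describes the dynamics perpendicular to the AP axis
    with the cables lying along the 1D coordinate (the configuration of
    the posterior sickle), so the active force reduces to
    ``p1 (p0 + 1) m_x`` and the along-cable diffusion to ``p7 m_xx``.
    A Gaussian of m seeded above the unstable uniform root focuses into
    a growing peak with a colocated velocity sink (u_x << 0) -- the 1D
    signature of ingression at the forming streak.
    """
    m = np.asarray(ic, dtype=float).copy()
    if np.any(m < 0):
        raise ValueError("initial 1D intensity must be nonnegative")
    nx = m.size
    dx = domain_length / nx
    x = (np.arange(nx) + (0.0 if periodic else 0.5)) * dx
    alpha = params.p1 * (params.p0 + 1.0) / (2.0 * params.p1 + 1.0)

    def ghost_pad(q):
        if periodic:
            return np.concatenate([q[-1:], q, q[:1]])
        return np.concatenate([q[:1], q, q[-1:]])  # mirror: no-flux

    def rhs(m_, u):
        qp = ghost_pad(m_)
        back = (qp[1:-1] - qp[:-2]) / dx
        fwd = (qp[2:] - qp[1:-1]) / dx
        adv = -u * np.where(u > 0, back, fwd)
        diff = params.p7 * (qp[2:] - 2 * qp[1:-1] + qp[:-2]) / dx**2
        return adv + reaction_rate(m_, params) + diff

    t = 0.0
    times, snaps_m, snaps_u, snaps_ux, rows = [], [], [], [], []
    next_output = 0.0
    completed = True
    while True:
        u, ux = _solve_1d_velocity(m, dx, alpha, periodic)
        if t >= next_output - 1e-12 or t >= t_end - 1e-12:
            times.append(t)
            snaps_m.append(m.copy())
            snaps_u.append(u.copy())
            snaps_ux.append(ux.copy())
            rows.append(
                {
                    "t": t,
                    "max_m": float(m.max()),
                    "argmax_m": float(x[int(m.argmax())]),
                    "min_ux": float(ux.min()),
                    "argmin_ux": float(x[int(ux.argmin())]),
                }
            )
            next_output = t + output_every
        if t >= t_end - 1e-12:
            break
        dt_adv = cfl * dx / max(np.abs(u).max(), 1e-12)
        dt_diff = 0.4 * dx**2 / max(params.p7, 1e-12)
        dt_kin = 0.25 / max(np.abs(reaction_rate_derivative(m, params)).max(), 1e-12)
        dt = min(dt_max, dt_adv, dt_diff, dt_kin, t_end - t)
        m1 = m + dt * rhs(m, u)
        u1, _ = _solve_1d_velocity(np.maximum(m1, 0.0), dx, alpha, periodic)
        m = 0.5 * (m + m1 + dt * rhs(np.maximum(m1, 0.0), u1))
        if not np.isfinite(m).all():
            completed = False
            warnings.warn(f"non-finite 1D fields at t={t:.4f}")
            break
        m = np.maximum(m, 0.0)
        t += dt

    return Result1D(
        x=x,
        times=np.asarray(times),
        m=np.asarray(snaps_m),
        u=np.asarray(snaps_u),
        ux=np.asarray(snaps_ux),
        summaries=pd.DataFrame(rows),
        params=params,
        completed=completed,
    )


# --------------------------------------------------------------------------
# Parameter sweeps
# --------------------------------------------------------------------------

def parameter_sweep(
    base_scenario: Union[str, Scenario],
    params: ModelParams,
    sweep_param: str,
    values: Sequence[float],
    grid: Optional[DiskGrid] = None,
    t_end: Optional[float] = None,
    **run_kwargs,
) -> pd.DataFrame:
    """One reduced-resolution 2D run per parameter value.

    Returns a table with the final-time summary metrics per value;
    individual failures are recorded per-row and the sweep continues.
    """
    if sweep_param not in ModelParams.__dataclass_fields__:
        raise ValueError(
            f"unknown parameter {sweep_param!r}; valid: "
            f"{sorted(ModelParams.__dataclass_fields__)}"
        )
    if grid is None:
        grid = DiskGrid(32, 64)
    rows = []
    for val in values:
        if not np.isfinite(val):
            raise ValueError("sweep values must be finite")
        p = params.replace(**{sweep_param: float(val)})
        row = {sweep_param: float(val)}
        try:
            res = run_2d(base_scenario, p, grid=grid, t_end=t_end, **run_kwargs)
            last = res.summaries.iloc[-1].to_dict()
            last.pop("t", None)
            row.update(last)
            row["completed"] = res.completed
            row["message"] = res.message
        except Exception as exc:  # noqa: BLE001 -- per-row failure policy
            row["completed"] = False
            row["message"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
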