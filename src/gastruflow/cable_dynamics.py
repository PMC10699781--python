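"""Kinetics of the actomyosin cable fields: orientation and intensity.

Orientation (a nematic director, evolving like a material fibre)::

    dphi/dt = -(v . grad) phi  +  omega/2
              + p2 [ (u_y + v_x)/2 cos(2 phi) + (v_y - u_x)/2 sin(2 phi) ]

Intensity (reaction - advection - anisotropic diffusion)::

    dm/dt = -(v . grad) m + p3 - p4 m exp(-p5 m / 2) - p6 m + p7 Lap_phi m

where ``Lap_phi m = div( e(phi) e(phi)^T grad m )`` diffuses intensity
strictly along the local cable axis (tension propagation).  The
dissociation term is the catch bond: its rate per unit m,
``p4 exp(-p5 m/2)``, decreases with tension ``T_c = m/2``, the positive
feedback that makes intermediate uniform states unstable and drives the
focusing instability.

Numerical notes
---------------
* The advection gradient of phi is taken on the locally unwrapped nematic
  angle via the double-angle identity
  ``2 grad phi = cos(2phi) grad sin(2phi) - sin(2phi) grad cos(2phi)``,
  which is free of branch-cut artifacts.
* ``Lap_phi`` is discretized in conservative (divergence) finite-volume
  form with zero-flux boundary faces, so total intensity is conserved by
  the diffusion term exactly (to solver tolerance).  This differs from
  the directional second derivative ``e^T (Hess m) e`` by first-order
  terms in grad phi; the divergence form is chosen because it conserves
  total m under no-flux boundaries.
* ``T_c`` is everywhere replaced by its long-timescale closure ``m/2``;
  there is no independent tension field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq

from .core import DiskGrid, ModelParams, phi_to_double_angle
from .mechanics import BoundaryCondition, get_operators, _velocity_gradients

__all__ = [
    "EquilibriumSet",
    "reaction_rate",
    "reaction_rate_derivative",
    "orientation_rate",
    "intensity_rate",
    "anisotropic_diffusion_matrix",
    "uniform_equilibria",
    "perturbation_growth_rate",
]


# --------------------------------------------------------------------------
# Uniform kinetics f(m) and equilibria
# --------------------------------------------------------------------------

def reaction_rate(m, params: ModelParams):
    """Spatially uniform kinetics f(m) = p3 - p4 m e^{-p5 m/2} - p6 m."""
    s = params.catch_bond_sign * params.p5 / 2.0
    return params.p3 - params.p4 * m * np.exp(s * m) - params.p6 * m


def reaction_rate_derivative(m, params: ModelParams):
    """f'(m), used for linear stability of uniform states."""
    s = params.catch_bond_sign * params.p5 / 2.0
    return -params.p4 * np.exp(s * m) * (1.0 + s * m) - params.p6


@dataclass
class EquilibriumSet:
    """Nonnegative roots of f(m) = 0 with their linear stability.

    ``roots`` are sorted ascending; ``stability[i]`` is "stable" when
    f'(root) < 0 and "unstable" otherwise.
    """

    roots: list[float]
    stability: list[str]

    @property
    def stable(self) -> list[float]:
        return [r for r, s in zip(self.roots, self.stability) if s == "stable"]

    @property
    def unstable(self) -> list[float]:
        return [r for r, s in zip(self.roots, self.stability) if s == "unstable"]


def uniform_equilibria(
    params: ModelParams, n_scan: int = 4000, tol: float = 1e-12
) -> EquilibriumSet:
    """All nonnegative uniform equilibria of the intensity kinetics.

    Roots are bracketed by a dense sign scan of f on ``[0, 2 p3/p6]``
    (f < 0 for m > p3/p6, so every root lies below the upper end; the
    factor 2 is safety margin) and polished by Brent's method.  With
    ``p4 = 0`` the unique root is exactly ``p3/p6``; the default
    parameter set has three roots with the (stable, unstable, stable)
    pattern whose middle root seeds every scenario.
    """
    if params.p6 <= 0:
        raise ValueError("uniform equilibria require p6 > 0")
    upper = 2.0 * params.p3 / params.p6 if params.p3 > 0 else 1.0
    ms = np.linspace(0.0, upper, n_scan)
    fs = reaction_rate(ms, params)
    roots: list[float] = []
    # exact zeros at scan nodes (e.g. m = 0 when p3 = 0)
    for mi, fi in zip(ms, fs):
        if fi == 0.0:
            roots.append(float(mi))
    sign_change = np.where(np.sign(fs[:-1]) * np.sign(fs[1:]) < 0)[0]
    for i in sign_change:
        r = brentq(lambda m: reaction_rate(m, params), ms[i], ms[i + 1], xtol=tol)
        roots.append(float(r))
    roots = sorted(set(np.round(roots, 12)))
    if not roots:
        raise AssertionError(
            "no uniform equilibria found; f(m) should always vanish at least "
            "once on [0, 2 p3/p6] when p6 > 0"
        )
    stability = [
        "stable" if reaction_rate_derivative(r, params) < 0 else "unstable"
        for r in roots
    ]
    return EquilibriumSet(roots=[float(r) for r in roots], stability=stability)


# --------------------------------------------------------------------------
# Orientation dynamics (Eq. for phi)
# --------------------------------------------------------------------------

def orientation_rate(
    phi: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    params: ModelParams,
    grid: DiskGrid,
    bc: BoundaryCondition | None = None,
) -> np.ndarray:
    """Continuous-time rate dphi/dt of the nematic director field."""
    ops = get_operators(grid)
    c2, s2 = phi_to_double_angle(phi)
    Dx, Dy = ops.Dx("neumann"), ops.Dy("neumann")
    # locally unwrapped nematic gradient: 2 grad(phi) = c2 grad(s2) - s2 grad(c2)
    phix = 0.5 * (c2 * Dx.apply(s2) - s2 * Dx.apply(c2))
    phiy = 0.5 * (c2 * Dy.apply(s2) - s2 * Dy.apply(c2))
    ux, uy, vx, vy = _velocity_gradients(u, v, grid, bc)
    omega = vx - uy
    shear = 0.5 * (uy + vx) * c2 + 0.5 * (vy - ux) * s2
    return -(u * phix + v * phiy) + 0.5 * omega + params.p2 * shear


# --------------------------------------------------------------------------
# Anisotropic (along-cable) diffusion, conservative finite volumes
# --------------------------------------------------------------------------

def anisotropic_diffusion_matrix(
    c2: np.ndarray, s2: np.ndarray, grid: DiskGrid
) -> sp.csr_matrix:
    """Sparse matrix D with (D m) = div( e e^T grad m ), zero-flux rim.

    Finite-volume discretization on the polar cells: fluxes are evaluated
    on cell faces from face-averaged diffusion tensors and face-centred
    gradients; the rim faces carry zero flux and the r = 0 faces have
    zero length, so row sums telescope and ``sum(area * D m) = 0``
    exactly for every m (discrete conservation).  Across-origin radial
    neighbours use the standard pole identification.
    """
    nr, nt = grid.shape
    h, dth = grid.dr, grid.dtheta
    half = nt // 2
    radii = grid.radii
    area = radii * h * dth  # exact annular-sector area per ring

    b11 = 0.5 * (1.0 + c2)
    b12 = 0.5 * s2
    b22 = 0.5 * (1.0 - c2)

    def idx(j, k):
        return np.asarray(j) * nt + np.mod(k, nt)

    rows_all, cols_all, vals_all = [], [], []

    def add_face_fluxes(row_lo, row_hi, inv_a_lo, inv_a_hi, cols, coefs):
        """Flux F = sum(coefs * m[cols]); +F/area to lo row, -F/area to hi."""
        nface, nc = cols.shape
        rows_all.append(np.repeat(row_lo, nc))
        cols_all.append(cols.ravel())
        vals_all.append((coefs * inv_a_lo[:, None]).ravel())
        rows_all.append(np.repeat(row_hi, nc))
        cols_all.append(cols.ravel())
        vals_all.append((-coefs * inv_a_hi[:, None]).ravel())

    # ---- internal radial faces: between rings j-1 and j, j = 1..nr-1 ----
    jf, kf = np.meshgrid(np.arange(1, nr), np.arange(nt), indexing="ij")
    jf, kf = jf.ravel(), kf.ravel()
    r_f = jf * h
    th = kf * dth
    c, s = np.cos(th), np.sin(th)
    lo, hi = idx(jf - 1, kf), idx(jf, kf)
    a11 = 0.5 * (b11.ravel()[lo] + b11.ravel()[hi])
    a12 = 0.5 * (b12.ravel()[lo] + b12.ravel()[hi])
    a22 = 0.5 * (b22.ravel()[lo] + b22.ravel()[hi])
    Krr = a11 * c * c + 2.0 * a12 * c * s + a22 * s * s
    Krt = (a22 - a11) * c * s + a12 * (c * c - s * s)
    w_rr = Krr * r_f * dth / h          # multiplies (m_hi - m_lo)
    w_rt = 0.25 * Krt                   # multiplies 4-point theta average
    cols = np.stack(
        [hi, lo, idx(jf - 1, kf + 1), idx(jf, kf + 1), idx(jf - 1, kf - 1), idx(jf, kf - 1)],
        axis=1,
    )
    coefs = np.stack([w_rr, -w_rr, w_rt, w_rt, -w_rt, -w_rt], axis=1)
    add_face_fluxes(lo, hi, 1.0 / area[jf - 1], 1.0 / area[jf], cols, coefs)

    # ---- angular faces: between (j, k) and (j, k+1), all j, k ----
    jf, kf = np.meshgrid(np.arange(nr), np.arange(nt), indexing="ij")
    jf, kf = jf.ravel(), kf.ravel()
    th = (kf + 0.5) * dth
    c, s = np.cos(th), np.sin(th)
    lo, hi = idx(jf, kf), idx(jf, kf + 1)
    a11 = 0.5 * (b11.ravel()[lo] + b11.ravel()[hi])
    a12 = 0.5 * (b12.ravel()[lo] + b12.ravel()[hi])
    a22 = 0.5 * (b22.ravel()[lo] + b22.ravel()[hi])
    Ktt = a11 * s * s - 2.0 * a12 * c * s + a22 * c * c
    Ktr = (a22 - a11) * c * s + a12 * (c * c - s * s)
    r_j = radii[jf]
    w_tt = Ktt * h / (dth * r_j)        # multiplies (m_hi - m_lo)
    # radial derivative at the face: mean of the two cells' central d/dr,
    # each contributing +-1/(2h); flux weight Ktr * h * 0.5
    w_tr = Ktr * h * 0.5 / (2.0 * h)    # = Ktr / 4
    up_k = np.where(jf < nr - 1, jf + 1, jf)            # ghost mirror at rim
    dn_k = np.where(jf > 0, jf - 1, 0)
    dn_shift = np.where(jf > 0, 0, half)                # across-origin at j=0
    up_col_k = idx(up_k, kf)
    dn_col_k = idx(dn_k, kf + dn_shift)
    # rim Neumann ghost: (m[nr-1] - m[nr-2])/(2h) -> up col = (nr-1), dn = (nr-2)
    rim = jf == nr - 1
    dn_col_k = np.where(rim, idx(jf - 1, kf), dn_col_k)
    up_col_kp = idx(up_k, kf + 1)
    dn_col_kp = idx(dn_k, kf + 1 + dn_shift)
    dn_col_kp = np.where(rim, idx(jf - 1, kf + 1), dn_col_kp)
    cols = np.stack([hi, lo, up_col_k, dn_col_k, up_col_kp, dn_col_kp], axis=1)
    coefs = np.stack([w_tt, -w_tt, w_tr, -w_tr, w_tr, -w_tr], axis=1)
    add_face_fluxes(lo, hi, 1.0 / area[jf], 1.0 / area[jf], cols, coefs)

    N = nr * nt
    D = sp.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(N, N),
    )
    return D.tocsr()


def anisotropic_diffusion(m: np.ndarray, phi: np.ndarray, grid: DiskGrid) -> np.ndarray:
    """div( e(phi) e(phi)^T grad m ) with zero-flux boundary."""
    c2, s2 = phi_to_double_angle(phi)
    D = anisotropic_diffusion_matrix(c2, s2, grid)
    return (D @ m.ravel()).reshape(grid.shape)


# --------------------------------------------------------------------------
# Intensity dynamics (Eq. for m)
# --------------------------------------------------------------------------

def intensity_rate(
    m: np.ndarray,
    phi: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    params: ModelParams,
    grid: DiskGrid,
) -> np.ndarray:
    """Continuous-time rate dm/dt of the active stress intensity."""
    if np.any(np.asarray(m) < 0):
        raise ValueError("intensity m must be nonnegative")
    ops = get_operators(grid)
    mx = ops.Dx("neumann").apply(m)
    my = ops.Dy("neumann").apply(m)
    rate = -(u * mx + v * my) + reaction_rate(m, params)
    if params.p7 > 0:
        rate = rate + params.p7 * anisotropic_diffusion(m, phi, grid)
    return rate


# --------------------------------------------------------------------------
# Linear response of uniform states (1D dispersion measurement)
# --------------------------------------------------------------------------

def perturbation_growth_rate(
    m_star: float,
    k: float,
    params: ModelParams,
    domain_length: float = 2.0 * np.pi,
    amplitude: float = 1e-5,
    max_retries: int = 5,
) -> float:
    """Growth rate of a sinusoidal perturbation of wavenumber k about
    the uniform state (m*, u = 0) on a periodic 1D domain.

    Measured, not assumed: a tiny-amplitude nonlinear 1D simulation
    (spectral derivatives, RK4) is run over a short window, the Fourier
    amplitude of the seeded mode is tracked and its log regressed against
    time.  If the measurement leaves the linear regime (split-half rates
    disagree) the amplitude is reduced automatically and the run retried.

    For this model the flow coupling is quadratic in the perturbation, so
    the linear rate is ``f'(m*) - p7 k^2``: pure kinetic relaxation at
    k = 0 and diffusion-dominated decay at large k.
    """
    L = float(domain_length)
    n_mode = int(round(k * L / (2.0 * np.pi)))
    k_eff = 2.0 * np.pi * n_mode / L
    nx = max(64, 8 * abs(n_mode))
    x = np.arange(nx) * (L / nx)
    kspec = 2.0 * np.pi * np.fft.rfftfreq(nx, d=L / nx)
    alpha = params.p1 * (params.p0 + 1.0) / (2.0 * params.p1 + 1.0)

    fprime = reaction_rate_derivative(m_star, params)
    rate_scale = abs(fprime) + params.p7 * k_eff**2 + 1e-3
    T = min(2.0, 0.5 / rate_scale)
    kmax = kspec.max()
    dt = min(0.2 / rate_scale, 0.5 / (params.p7 * kmax**2 + 1e-12), T / 20.0)
    nsteps = max(20, int(np.ceil(T / dt)))
    dt = T / nsteps

    def rhs(m):
        mh = np.fft.rfft(m)
        mx = np.fft.irfft(1j * kspec * mh, n=nx)
        mxx = np.fft.irfft(-(kspec**2) * mh, n=nx)
        # 1D force balance: (2 p1 + 1) u_xx + p1 (p0 + 1) m_x = 0
        uxh = -alpha * mh.copy()
        uxh[0] = 0.0
        uh = np.zeros_like(uxh)
        uh[1:] = uxh[1:] / (1j * kspec[1:])
        un = np.fft.irfft(uh, n=nx)
        return -un * mx + reaction_rate(m, params) + params.p7 * mxx

    def mode_amp(m):
        mh = np.fft.rfft(m - m_star) / nx
        if n_mode == 0:
            return abs(mh[0].real)
        return 2.0 * abs(mh[n_mode])

    eps = amplitude * max(abs(m_star), 1.0)
    for _ in range(max_retries):
        m = m_star + eps * np.cos(k_eff * x)
        amps, times = [mode_amp(m)], [0.0]
        ok = True
        for istep in range(nsteps):
            k1 = rhs(m)
            k2 = rhs(m + 0.5 * dt * k1)
            k3 = rhs(m + 0.5 * dt * k2)
            k4 = rhs(m + dt * k3)
            m = m + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            if np.any(m < 0) or not np.all(np.isfinite(m)):
                ok = False
                break
            amps.append(mode_amp(m))
            times.append((istep + 1) * dt)
        amps = np.asarray(amps)
        times = np.asarray(times)
        if not ok or np.any(amps <= 0):
            eps *= 0.1
            continue
        loga = np.log(amps)
        half = len(times) // 2
        rate_all = np.polyfit(times, loga, 1)[0]
        rate_1 = np.polyfit(times[: half + 1], loga[: half + 1], 1)[0]
        rate_2 = np.polyfit(times[half:], loga[half:], 1)[0]
        if abs(rate_1 - rate_2) <= 0.05 * max(abs(rate_all), 1e-6) + 1e-6:
            return float(rate_all)
        eps *= 0.1
    return float(rate_all)
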