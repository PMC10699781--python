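"""Domain types and nematic-tensor algebra for the gastrulation flow model.

The model couples three coarse-grained fields on a disk-shaped embryo:
the planar tissue velocity ``v = (u, v)``, the active stress intensity
``m >= 0`` produced by supracellular actomyosin cables, and the mean cable
orientation ``phi`` (a nematic director, defined modulo pi).  The active
stress carried by the cables is the traceless tensor

    sigma_A = m (B - I/2),      B = e(phi) e(phi)^T,  e = (cos phi, sin phi),

so that the tension carried along a cable is ``<e, sigma_A e> = m/2``.

Conventions fixed here and used project-wide:

* Fields live on a polar node layout (``DiskGrid``) but vector/tensor
  components are stored in a fixed **Cartesian** frame; polar components
  are views, never storage.  This avoids coordinate-singularity
  bookkeeping at the disk centre.
* Radial nodes are cell-centred, ``r_j = (j + 1/2) dr``, excluding r = 0.
* Orientation is canonicalized to ``[0, pi)``; interpolation and averaging
  always go through the double-angle pair ``(cos 2phi, sin 2phi)``.
* The anterior-posterior (AP) axis defaults to posterior at
  ``theta = 3*pi/2`` (bottom of the image in standard figures); it is
  configurable per grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ModelParams",
    "DiskGrid",
    "FieldState",
    "SymTensorField",
    "canonicalize_phi",
    "phi_to_double_angle",
    "double_angle_to_phi",
    "structure_tensor",
    "active_stress",
    "cable_tension",
]


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """The eight nondimensional model parameters plus boundary data.

    The model is nondimensionalized by a characteristic length ``x_c``,
    speed ``u_c`` and viscous shear stress ``mu*u_c/x_c``.  The parameters
    absorb the dimensional constants as follows (documentation only; the
    code never sees the dimensional symbols):

    ==========  =============================  =================================
    parameter   dimensional content            meaning
    ==========  =============================  =================================
    p0          --                             active-ingression propensity
    p1          mu*c                           shear/bulk viscosity ratio
    p2          --                             shear-rotation coupling (~1 for
                                               elongated fibres)
    p3          (t_p/t_r)(m_n x_c)/(mu u_c)    myosin recruitment rate
    p4          t_p/t_d                        base dissociation rate
    p5          k_o mu u_c / x_c               catch-bond tension sensitivity
    p6          chi t_p                        linear saturation rate
    p7          xi/(x_c u_c)                   tension-propagation diffusivity
    ==========  =============================  =================================

    ``v_b`` is the outward-normal boundary speed modelling epiboly; ``R``
    the nondimensional domain radius.

    ``catch_bond_sign`` exposes the sign of the exponent in the
    dissociation term ``p4 * m * exp(sign * p5 * m / 2)``; the default -1
    is the catch-bond form (dissociation decreases with tension), which is
    what drives the focusing instability.  +1 (slip bond) is provided for
    sensitivity exploration only.
    """

    p0: float = 1.0
    p1: float = 0.5
    p2: float = 1.0
    p3: float = 1.0
    p4: float = 6.0
    p5: float = 4.0
    p6: float = 0.28
    p7: float = 0.005
    v_b: float = 0.05
    R: float = 1.0
    catch_bond_sign: int = -1

    def __post_init__(self) -> None:
        if not np.isfinite(
            [self.p0, self.p1, self.p2, self.p3, self.p4, self.p5,
             self.p6, self.p7, self.v_b, self.R]
        ).all():
            raise ValueError("ModelParams entries must be finite")
        if self.p0 < 0:
            raise ValueError("p0 (ingression propensity) must be >= 0")
        if self.p1 <= 0:
            raise ValueError("p1 (viscosity ratio) must be > 0")
        if not 0.0 <= self.p2 <= 1.0:
            raise ValueError("p2 (shear-rotation coupling) must lie in [0, 1]")
        for name in ("p3", "p4", "p5", "p7"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.p6 <= 0:
            raise ValueError("p6 (saturation rate) must be > 0")
        if self.R <= 0:
            raise ValueError("domain radius R must be > 0")
        if self.catch_bond_sign not in (-1, 1):
            raise ValueError("catch_bond_sign must be -1 (catch) or +1 (slip)")

    @property
    def m_sat(self) -> float:
        """Saturation scale of the intensity kinetics, ``p3/p6``."""
        return self.p3 / self.p6

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


# --------------------------------------------------------------------------
# Grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiskGrid:
    """Polar node layout on a disk of radius ``R``.

    Radial nodes are cell-centred, ``r_j = (j + 1/2) * dr`` with
    ``dr = R / nr``, excluding the origin; angles are uniform on
    ``[0, 2*pi)``.  ``ntheta`` must be even so that every node has an
    across-origin partner at ``theta + pi`` (used by the pole treatment)
    and the grid is symmetric under reflection about the AP axis.
    """

    nr: int
    ntheta: int
    R: float = 1.0
    ap_angle: float = 3.0 * np.pi / 2.0  # posterior direction

    def __post_init__(self) -> None:
        if self.nr < 3:
            raise ValueError("need at least 3 radial nodes")
        if self.ntheta < 4 or self.ntheta % 2:
            raise ValueError("ntheta must be even and >= 4")
        if self.R <= 0:
            raise ValueError("R must be positive")

    # -- coordinates -------------------------------------------------------
    @property
    def dr(self) -> float:
        return self.R / self.nr

    @property
    def dtheta(self) -> float:
        return 2.0 * np.pi / self.ntheta

    @property
    def radii(self) -> np.ndarray:
        return (np.arange(self.nr) + 0.5) * self.dr

    @property
    def thetas(self) -> np.ndarray:
        return np.arange(self.ntheta) * self.dtheta

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nr, self.ntheta)

    @property
    def size(self) -> int:
        return self.nr * self.ntheta

    def mesh_polar(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, theta) arrays of shape (nr, ntheta)."""
        return np.meshgrid(self.radii, self.thetas, indexing="ij")

    def mesh_xy(self) -> tuple[np.ndarray, np.ndarray]:
        r, t = self.mesh_polar()
        return r * np.cos(t), r * np.sin(t)

    def cell_areas(self) -> np.ndarray:
        """Exact annular-sector areas, shape (nr, ntheta); sums to pi R^2."""
        j = np.arange(self.nr)
        r_in = j * self.dr
        r_out = (j + 1) * self.dr
        ring = 0.5 * (r_out**2 - r_in**2) * self.dtheta
        return np.repeat(ring[:, None], self.ntheta, axis=1)

    def ap_unit(self) -> tuple[float, float]:
        """Unit vector pointing from posterior toward anterior."""
        return (-np.cos(self.ap_angle), -np.sin(self.ap_angle))

    def mirror_index(self) -> np.ndarray:
        """Angular index permutation that reflects fields about the AP axis.

        Reflection about the line through the origin at angle ``ap_angle``
        maps ``theta -> 2*ap_angle - theta``, which is again a grid node
        because ``ap_angle`` is a multiple of ``dtheta`` for even grids
        with the default AP convention.
        """
        k = np.arange(self.ntheta)
        ka = 2.0 * self.ap_angle / self.dtheta
        ka_round = int(round(ka))
        if abs(ka - ka_round) > 1e-12:
            raise ValueError("AP axis is not aligned with the angular grid")
        return (ka_round - k) % self.ntheta


# --------------------------------------------------------------------------
# Orientation helpers (nematic, pi-periodic)
# --------------------------------------------------------------------------

def canonicalize_phi(phi: np.ndarray) -> np.ndarray:
    """Map an orientation field into the canonical branch [0, pi)."""
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("orientation field contains non-finite values")
    return np.mod(phi, np.pi)


def phi_to_double_angle(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Branch-cut-free representation (cos 2phi, sin 2phi)."""
    phi = np.asarray(phi, dtype=float)
    return np.cos(2.0 * phi), np.sin(2.0 * phi)


def double_angle_to_phi(c2: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Inverse of :func:`phi_to_double_angle`, canonical branch [0, pi)."""
    return np.mod(0.5 * np.arctan2(s2, c2), np.pi)


# --------------------------------------------------------------------------
# Field containers
# --------------------------------------------------------------------------

@dataclass
class FieldState:
    """Snapshot of the model fields (m, phi, v, optionally p) on one grid."""

    grid: DiskGrid
    t: float
    m: np.ndarray
    phi: np.ndarray
    u: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None
    p: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shape = self.grid.shape
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != shape:
            raise ValueError(f"m has shape {self.m.shape}, grid is {shape}")
        if np.any(self.m < 0):
            raise ValueError("active stress intensity m must be >= 0")
        self.phi = canonicalize_phi(self.phi)
        if self.phi.shape != shape:
            raise ValueError(f"phi has shape {self.phi.shape}, grid is {shape}")
        for name in ("u", "v", "p"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != shape:
                    raise ValueError(f"{name} has shape {arr.shape}, grid is {shape}")
                setattr(self, name, arr)


@dataclass
class SymTensorField:
    """Symmetric 2x2 tensor field; components in the fixed Cartesian frame.

    ``role`` tags the physical meaning: "B" (nematic structure tensor,
    trace 1 / det 0), "sigma_A" (active stress, traceless) or "S_s"
    (deviatoric strain rate, traceless).
    """

    t11: np.ndarray
    t12: np.ndarray
    t22: np.ndarray
    role: str = ""

    def __post_init__(self) -> None:
        self.t11 = np.asarray(self.t11, dtype=float)
        self.t12 = np.asarray(self.t12, dtype=float)
        self.t22 = np.asarray(self.t22, dtype=float)
        if not (self.t11.shape == self.t12.shape == self.t22.shape):
            raise ValueError("tensor components must share one shape")

    @property
    def shape(self):
        return self.t11.shape

    def trace(self) -> np.ndarray:
        return self.t11 + self.t22

    def det(self) -> np.ndarray:
        return self.t11 * self.t22 - self.t12**2

    def eig(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigenvalues (ascending) and the angle of the smaller-eigenvalue
        eigenvector, all computed in closed form per node.

        Returns ``(lam_min, lam_max, angle_min)`` with ``angle_min`` in
        ``[0, pi)``.
        """
        mean = 0.5 * (self.t11 + self.t22)
        half_diff = 0.5 * (self.t11 - self.t22)
        rad = np.hypot(half_diff, self.t12)
        lam_min = mean - rad
        lam_max = mean + rad
        # eigenvector of lam_max makes angle 0.5*atan2(2 t12, t11 - t22);
        # the lam_min direction is perpendicular.
        ang_max = 0.5 * np.arctan2(2.0 * self.t12, self.t11 - self.t22)
        angle_min = np.mod(ang_max + 0.5 * np.pi, np.pi)
        return lam_min, lam_max, angle_min


# --------------------------------------------------------------------------
# Tensor algebra
# --------------------------------------------------------------------------

def structure_tensor(phi: np.ndarray) -> SymTensorField:
    """Nematic structure tensor ``B = e(phi) e(phi)^T``.

    ``B11 = cos^2 phi``, ``B12 = sin(2 phi)/2``, ``B22 = sin^2 phi``;
    invariant under ``phi -> phi + pi`` with trace 1 and det 0 at every
    node.
    """
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("orientation field contains non-finite values")
    c2, s2 = phi_to_double_angle(phi)
    return SymTensorField(
        t11=0.5 * (1.0 + c2),
        t12=0.5 * s2,
        t22=0.5 * (1.0 - c2),
        role="B",
    )


def active_stress(m: np.ndarray, phi: np.ndarray) -> SymTensorField:
    """Active cable stress ``sigma_A = m (B - I/2)`` (traceless)."""
    m = np.asarray(m, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if m.shape != phi.shape:
        raise ValueError(f"m shape {m.shape} != phi shape {phi.shape}")
    if np.any(m < 0):
        raise ValueError("active stress intensity m must be >= 0")
    B = structure_tensor(phi)
    return SymTensorField(
        t11=m * (B.t11 - 0.5),
        t12=m * B.t12,
        t22=m * (B.t22 - 0.5),
        role="sigma_A",
    )


def cable_tension(m: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Tension carried along a cable, ``T_c = <e, sigma_A e>``.

    Algebraically ``e^T sigma_A e = m (e^T B e - 1/2) = m/2`` independent
    of ``phi``; the contraction is evaluated explicitly so the identity is
    a genuine check rather than a shortcut.
    """
    sig = active_stress(m, phi)
    c = np.cos(phi)
    s = np.sin(phi)
    return sig.t11 * c * c + 2.0 * sig.t12 * c * s + sig.t22 * s * s
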