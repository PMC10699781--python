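"""Elliptic force balance, pressure recovery, diagnostics, force inference."""

import numpy as np
import pytest
import sympy as sy

from gastruflow import (
    BoundaryCondition,
    DiskGrid,
    ForceBalanceSolver,
    ModelParams,
    VelocitySeries,
    divergence,
    infer_active_force,
    recover_pressure,
    solve_force_balance,
    strain_rate_diagnostics,
    vorticity,
)

rng = np.random.default_rng(7)


def manufactured_problem():
    """Analytic (v*, forcing) pair for the viscous operator, via sympy."""
    x, y = sy.symbols("x y")
    u_s = sy.sin(1.1 * x) * sy.cos(0.7 * y) + 0.2 * x**2 * y
    v_s = sy.cos(0.8 * x) * sy.sin(1.3 * y) - 0.1 * x * y**2
    p1 = 0.5
    lap = lambda f: sy.diff(f, x, 2) + sy.diff(f, y, 2)
    divv = sy.diff(u_s, x) + sy.diff(v_s, y)
    gx = -(2 * p1 * lap(u_s) + sy.diff(divv, x))
    gy = -(2 * p1 * lap(v_s) + sy.diff(divv, y))
    to_np = lambda e: sy.lambdify((x, y), e, "numpy")
    return p1, to_np(u_s), to_np(v_s), to_np(gx), to_np(gy)


def solve_manufactured(n, p1, fu, fv, fgx, fgy):
    grid = DiskGrid(n, 2 * n)
    X, Y = grid.mesh_xy()
    tb = grid.thetas
    xb, yb = grid.R * np.cos(tb), grid.R * np.sin(tb)
    ub, vb = fu(xb, yb), fv(xb, yb)

    class ExactBC(BoundaryCondition):
        def velocity_samples(self, thetas):
            return ub, vb

    solver = ForceBalanceSolver(grid, ModelParams(p1=p1))
    zeros = np.zeros(grid.shape)
    u, v, rep = solver.solve(zeros, zeros, bc=ExactBC(), forcing=(fgx(X, Y), fgy(X, Y)))
    err = max(np.abs(u - fu(X, Y)).max(), np.abs(v - fv(X, Y)).max())
    return err, rep


class TestForceBalance:
    def test_zero_activity_zero_boundary_gives_zero_velocity(self):
        grid = DiskGrid(12, 24)
        zeros = np.zeros(grid.shape)
        u, v, rep = solve_force_balance(
            zeros, zeros, ModelParams(), bc=BoundaryCondition(0.0), grid=grid
        )
        assert rep.converged
        assert np.abs(u).max() < 1e-10 and np.abs(v).max() < 1e-10

    def test_uniform_fields_zero_boundary_gives_zero_velocity(self):
        """Constant m and phi kill every active term (grad m = 0, div B = 0)."""
        grid = DiskGrid(12, 24)
        m = np.full(grid.shape, 1.7)
        phi = np.full(grid.shape, 0.4)
        u, v, _ = solve_force_balance(
            m, phi, ModelParams(), bc=BoundaryCondition(0.0), grid=grid
        )
        assert np.abs(u).max() < 1e-10 and np.abs(v).max() < 1e-10

    def test_manufactured_solution_second_order(self):
        p1, fu, fv, fgx, fgy = manufactured_problem()
        errs = [solve_manufactured(n, p1, fu, fv, fgx, fgy)[0] for n in (12, 24)]
        order = np.log2(errs[0] / errs[1])
        assert order > 1.85

    def test_repeated_solves_identical(self):
        grid = DiskGrid(10, 20)
        m = rng.uniform(0.5, 2.0, grid.shape)
        phi = rng.uniform(0, np.pi, grid.shape)
        p = ModelParams()
        u1, v1, _ = solve_force_balance(m, phi, p, grid=grid)
        u2, v2, _ = solve_force_balance(m, phi, p, grid=grid)
        np.testing.assert_array_equal(u1, u2)
        np.testing.assert_array_equal(v1, v2)

    def test_reflection_equivariance(self):
        """Mirroring (m, phi) about the AP axis mirrors the velocity."""
        grid = DiskGrid(16, 32)
        x, y = grid.mesh_xy()
        m = 1.2 + 0.5 * np.exp(-((x - 0.2) ** 2 + (y + 0.4) ** 2) / 0.05)
        _, th = grid.mesh_polar()
        phi = np.mod(th + 0.5 * np.pi, np.pi)
        p = ModelParams()
        u, v, _ = solve_force_balance(m, phi, p, grid=grid)
        mir = grid.mirror_index()
        # reflect inputs: x -> -x is theta -> 2*ap - theta; phi -> pi - phi
        u2, v2, _ = solve_force_balance(
            m[:, mir], np.mod(-phi[:, mir], np.pi), p, grid=grid
        )
        scale = np.abs(u).max()
        assert np.abs(u2 + u[:, mir]).max() < 1e-8 * max(scale, 1)
        assert np.abs(v2 - v[:, mir]).max() < 1e-8 * max(scale, 1)

    def test_discrete_divergence_theorem(self):
        """Boundary flux of the solved velocity matches the area integral
        of its divergence within discretization error."""
        grid = DiskGrid(32, 64)
        x, y = grid.mesh_xy()
        m = 1.2 + 0.8 * np.exp(-((x) ** 2 + (y + 0.5) ** 2) / 0.04)
        _, th = grid.mesh_polar()
        phi = np.mod(th + 0.5 * np.pi, np.pi)
        p = ModelParams()
        bc = BoundaryCondition(p.v_b)
        u, v, _ = solve_force_balance(m, phi, p, bc=bc, grid=grid)
        div = divergence(u, v, grid, bc)
        area_integral = float((div * grid.cell_areas()).sum())
        boundary_flux = p.v_b * 2 * np.pi * grid.R
        assert area_integral == pytest.approx(boundary_flux, abs=0.05)


class TestPressureRecovery:
    def test_zero_divergence_zero_intensity(self):
        grid = DiskGrid(8, 16)
        zeros = np.zeros(grid.shape)
        p = recover_pressure(zeros, zeros, zeros, ModelParams(), grid)
        np.testing.assert_allclose(p, 0.0, atol=1e-12)

    def test_uniform_intensity_balancing_divergence(self):
        """div v = -p1 p0 m0 with uniform m0 gives p = 0: v = c*(x, y)/2."""
        grid = DiskGrid(24, 48)
        params = ModelParams()
        m0 = 1.3
        c = -params.p1 * params.p0 * m0
        x, y = grid.mesh_xy()
        u, v = 0.5 * c * x, 0.5 * c * y
        p = recover_pressure(u, v, np.full(grid.shape, m0), params, grid)
        assert np.abs(p).max() < 0.01

    def test_pure_divergence_arithmetic(self):
        """div v = -2 p1, m = 0  =>  p = 1 (linear field, exact)."""
        grid = DiskGrid(16, 32)
        params = ModelParams()
        x, y = grid.mesh_xy()
        u, v = -params.p1 * x, -params.p1 * y
        p = recover_pressure(u, v, np.zeros(grid.shape), params, grid)
        np.testing.assert_allclose(p, 1.0, atol=0.01)

    def test_p1_zero_rejected(self):
        grid = DiskGrid(4, 8)
        z = np.zeros(grid.shape)
        bad = ModelParams()
        object.__setattr__(bad, "p1", 0.0)  # bypass validation to hit the guard
        with pytest.raises(ValueError):
            recover_pressure(z, z, z, bad, grid)


class TestStrainRateDiagnostics:
    def test_isotropic_expansion(self):
        grid = DiskGrid(16, 32)
        x, y = grid.mesh_xy()
        S, div, _, rate = strain_rate_diagnostics(x, y, grid)
        np.testing.assert_allclose(div, 2.0, atol=0.02)
        assert np.abs(S.t11).max() < 0.02 and np.abs(S.t12).max() < 0.02
        assert np.abs(rate).max() < 0.02

    def test_simple_shear_eigenstructure(self):
        """v = (y, 0): eigenvalues +-1/2, contraction at 135 degrees."""
        grid = DiskGrid(16, 32)
        x, y = grid.mesh_xy()
        S, div, direction, rate = strain_rate_diagnostics(y, np.zeros_like(y), grid)
        np.testing.assert_allclose(div, 0.0, atol=0.02)
        np.testing.assert_allclose(rate, 0.5, atol=0.02)
        np.testing.assert_allclose(direction, 3 * np.pi / 4, atol=0.02)

    def test_rigid_rotation_is_strain_free(self):
        grid = DiskGrid(16, 32)
        x, y = grid.mesh_xy()
        om = 0.7
        S, div, _, rate = strain_rate_diagnostics(-om * y, om * x, grid)
        assert np.abs(div).max() < 0.02
        assert np.abs(rate).max() < 0.02
        np.testing.assert_allclose(
            vorticity(-om * y, om * x, grid), 2 * om, atol=0.02
        )

    def test_trace_free_by_construction(self):
        grid = DiskGrid(10, 20)
        u = rng.standard_normal(grid.shape)
        v = rng.standard_normal(grid.shape)
        S, _, _, _ = strain_rate_diagnostics(u, v, grid)
        assert np.abs(S.trace()).max() == 0.0


class TestForceInference:
    def _series(self, fu, fv, n=41, extent=1.0, nt=3):
        x = np.linspace(-extent, extent, n)
        y = np.linspace(-extent, extent, n)
        X, Y = np.meshgrid(x, y)
        U = np.repeat(fu(X, Y)[None], nt, axis=0)
        V = np.repeat(fv(X, Y)[None], nt, axis=0)
        return VelocitySeries(times=np.linspace(0, 1, nt), x=x, y=y, u=U, v=V)

    def test_affine_field_gives_exact_zero(self):
        vs = self._series(lambda x, y: 0.3 * x - 0.2 * y + 1.0, lambda x, y: 0.5 * y)
        fa = infer_active_force(vs, ModelParams(p1=0.8))
        assert np.abs(fa).max() < 1e-10

    def test_quadratic_field_closed_form(self):
        """v = (x^2, 0): F_A = (-2 - 4 p1, 0), exact for central differences."""
        p1 = 0.6
        vs = self._series(lambda x, y: x**2, lambda x, y: np.zeros_like(x))
        fa = infer_active_force(vs, ModelParams(p1=p1))
        interior = fa[:, 2:-2, 2:-2, :]
        np.testing.assert_allclose(interior[..., 0], -2.0 - 4.0 * p1, atol=1e-9)
        np.testing.assert_allclose(interior[..., 1], 0.0, atol=1e-9)

    def test_long_time_window_truncated_with_warning(self):
        vs = self._series(lambda x, y: x**2, lambda x, y: 0 * x, nt=2)
        with pytest.warns(UserWarning, match="truncated"):
            infer_active_force(vs, ModelParams(), smooth_time=10)

    def test_invalid_window_rejected(self):
        vs = self._series(lambda x, y: x, lambda x, y: y)
        with pytest.raises(ValueError):
            infer_active_force(vs, ModelParams(), smooth_space=0)
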