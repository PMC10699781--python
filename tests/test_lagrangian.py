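"""Flow maps, FTLE, morphoskeleton, benchmark flows, Lagrangian grids."""

import numpy as np
import pytest

from gastruflow import (
    DiskGrid,
    VelocitySeries,
    benchmark_flow,
    flow_map,
    ftle,
    lagrangian_grid,
    morphoskeleton,
    resample_disk_to_cartesian,
)

XS = np.linspace(-0.6, 0.6, 31)


class TestFlowMap:
    def test_uniform_translation(self):
        vs = benchmark_flow("uniform", vx=0.7, vy=-0.3, extent=3.0)
        x0 = np.array([[0.1, 0.2], [-0.5, 0.4]])
        F = flow_map(vs, x0, 0.0, 1.0)
        np.testing.assert_allclose(F, x0 + [0.7, -0.3], atol=1e-9)

    def test_saddle_matches_closed_form(self):
        vs = benchmark_flow("saddle", s=0.5, extent=3.0, n=96)
        x0 = np.array([[0.3, 0.4], [-0.2, 0.6], [0.05, -0.7]])
        F = flow_map(vs, x0, 0.0, 1.0)
        exact = vs.exact_flow_map(x0, 0.0, 1.0)
        assert np.abs(F - exact).max() < 1e-6 * np.abs(exact).max()

    def test_forward_backward_composition_returns_start(self):
        vs = benchmark_flow("double_gyre", n=128, times=np.linspace(0, 10, 21))
        x0 = np.column_stack(
            [np.linspace(0.3, 1.7, 15), np.linspace(0.2, 0.8, 15)]
        )
        mid = flow_map(vs, x0, 0.0, 5.0, n_steps=400)
        back = flow_map(vs, mid, 5.0, 0.0, n_steps=400)
        assert np.abs(back - x0).max() < 1e-5

    def test_escaping_trajectories_flagged(self):
        vs = benchmark_flow("uniform", vx=5.0, vy=0.0, extent=1.0)
        F, esc = flow_map(vs, np.array([[0.5, 0.0]]), 0.0, 1.0, return_escaped=True)
        assert esc[0]


class TestFTLE:
    def test_saddle_rate_forward_and_backward(self):
        vs = benchmark_flow("saddle", s=0.5, extent=3.0, n=96)
        for direction in ("forward", "backward"):
            fld = ftle(vs, XS, XS, 0.0, 1.0, direction)
            assert np.abs(fld.values - 0.5).max() < 1e-3

    def test_rigid_rotation_and_translation_are_ftle_free(self):
        for name in ("rigid_rotation", "uniform"):
            vs = benchmark_flow(name, extent=3.0, n=96)
            fld = ftle(vs, XS, XS, 0.0, 1.0)
            assert np.abs(fld.values).max() < 1e-6

    def test_objectivity_under_time_dependent_frame_drift(self):
        """Adding a uniform translation g(t) to the series leaves the
        FTLE unchanged -- the central frame-invariance requirement."""
        vs = benchmark_flow("saddle", s=0.5, extent=3.0, n=96)
        base = ftle(vs, XS, XS, 0.0, 1.0)
        drifted = vs.shifted(lambda t: (0.05 * np.sin(3 * t), -0.04 * t))
        moved = ftle(drifted, XS, XS, 0.0, 1.0)
        assert np.abs(moved.values - base.values).max() < 1e-6

    def test_refinement_is_cauchy(self):
        """Halving the auxiliary spacing and doubling the step count
        changes the FTLE by decreasing amounts."""
        vs = benchmark_flow("double_gyre", n=128, times=np.linspace(0, 10, 21))
        xg = np.linspace(0.2, 1.8, 33)
        yg = np.linspace(0.15, 0.85, 17)
        vals = [
            ftle(vs, xg, yg, 0.0, 4.0, h_aux=h, n_steps=n).values
            for h, n in ((0.04, 100), (0.02, 200), (0.01, 400))
        ]
        d1 = np.abs(vals[1] - vals[0])
        d2 = np.abs(vals[2] - vals[1])
        assert np.nanmax(d2) < np.nanmax(d1)
        assert np.nanmedian(d2) < np.nanmedian(d1)

    def test_degenerate_interval_rejected(self):
        vs = benchmark_flow("uniform")
        with pytest.raises(ValueError):
            ftle(vs, XS, XS, 1.0, 1.0)


class TestMorphoskeleton:
    def test_compressive_line_attractor_on_the_line(self):
        """u = 0, v = -tanh(y): backward separation is maximal at y = 0,
        so the attractor mask concentrates there."""
        vs = benchmark_flow("compressive_line", extent=2.0, n=128)
        xs = np.linspace(-1.5, 1.5, 61)
        ms = morphoskeleton(vs, xs, xs, 0.0, 2.0, ridge_quantile=0.9)
        iy, ix = np.where(ms.attractor_mask)
        assert len(iy) > 0
        assert np.abs(xs[iy]).max() < 0.1

    def test_uniform_ftle_gives_empty_masks(self):
        vs = benchmark_flow("rigid_rotation", extent=3.0, n=96)
        ms = morphoskeleton(vs, XS, XS, 0.0, 1.0)
        assert not ms.repeller_mask.any()
        assert not ms.attractor_mask.any()

    def test_doa_is_backward_ftle_at_initial_positions(self):
        """For the steady saddle the backward FTLE is uniform, so the
        DOA (pulled back to initial positions) matches it where defined."""
        vs = benchmark_flow("saddle", s=0.4, extent=4.0, n=96)
        xs = np.linspace(-0.4, 0.4, 21)
        ms = morphoskeleton(vs, xs, xs, 0.0, 1.0)
        ok = ~ms.doa.flags
        assert ok.any()
        np.testing.assert_allclose(ms.doa.values[ok], 0.4, atol=1e-2)
        assert ms.doa.display == "initial_positions"


class TestBenchmarkFlow:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            benchmark_flow("vortex_street")

    def test_rigid_rotation_is_divergence_and_strain_free(self):
        from gastruflow import strain_rate_diagnostics

        grid = DiskGrid(16, 32)
        x, y = grid.mesh_xy()
        om = 1.0
        S, div, _, rate = strain_rate_diagnostics(-om * y, om * x, grid)
        assert np.abs(div).max() < 0.01 and np.abs(rate).max() < 0.01

    def test_simple_shear_orientation_fixed_point(self):
        """Cross-module: the sampled shear flow leaves phi = 0 invariant."""
        from gastruflow import ModelParams, orientation_rate

        grid = DiskGrid(12, 24)
        vs = benchmark_flow("simple_shear", gamma=0.6, extent=2.0, n=64)
        x, y = grid.mesh_xy()
        u = 0.6 * y
        v = np.zeros_like(u)
        rate = orientation_rate(
            np.zeros(grid.shape), u, v, ModelParams(p2=1.0), grid
        )
        assert np.abs(rate).max() < 1e-9


class TestLagrangianGrid:
    def test_uniform_flow_translates_rigidly(self):
        vs = benchmark_flow("uniform", vx=0.3, vy=0.1, extent=3.0)
        lines0, lines = lagrangian_grid(
            vs, 0.0, 1.0, n_lines=4, pts_per_line=10, extent=(-1, 1, -1, 1)
        )
        for l0, l1 in zip(lines0, lines):
            np.testing.assert_allclose(
                l1 - l0, np.broadcast_to([0.3, 0.1], l1.shape), atol=1e-9
            )

    def test_saddle_cell_aspect_exponential(self):
        vs = benchmark_flow("saddle", s=0.5, extent=4.0, n=96)
        lines0, lines = lagrangian_grid(
            vs, 0.0, 1.0, n_lines=3, pts_per_line=5, extent=(-0.4, 0.4, -0.4, 0.4)
        )
        # vertical lines stretch in x by e^{sT}, shrink in y by e^{-sT}
        l0, l1 = lines0[0], lines[0]
        np.testing.assert_allclose(l1[:, 0], l0[:, 0] * np.exp(0.5), rtol=1e-5)
        np.testing.assert_allclose(l1[:, 1], l0[:, 1] * np.exp(-0.5), rtol=1e-5, atol=1e-9)

    def test_liouville_area_growth_in_expanding_flow(self):
        """Cell areas grow by exp(div * T) in v = a (x, y)."""
        a, T = 0.3, 1.0
        x = np.linspace(-2, 2, 40)
        X, Y = np.meshgrid(x, x)
        vs = VelocitySeries(
            times=[0.0, 1.0],
            x=x,
            y=x,
            u=np.repeat((a * X)[None], 2, axis=0),
            v=np.repeat((a * Y)[None], 2, axis=0),
        )
        corners = np.array([[0.1, 0.1], [0.3, 0.1], [0.3, 0.3], [0.1, 0.3]])
        mapped = flow_map(vs, corners, 0.0, T)

        def area(c):
            return 0.5 * abs(
                np.dot(c[:, 0], np.roll(c[:, 1], -1)) - np.dot(c[:, 1], np.roll(c[:, 0], -1))
            )

        assert area(mapped) / area(corners) == pytest.approx(np.exp(2 * a * T), rel=1e-4)


class TestVelocitySeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            VelocitySeries(
                times=[0, 0], x=[0, 1], y=[0, 1],
                u=np.zeros((2, 2, 2)), v=np.zeros((2, 2, 2)),
            )
        with pytest.raises(ValueError):
            VelocitySeries(
                times=[0], x=[0, 1], y=[0, 1],
                u=np.zeros((1, 2, 3)), v=np.zeros((1, 2, 3)),
            )

    def test_out_of_domain_sampling_holds_nearest_and_flags(self):
        vs = benchmark_flow("uniform", vx=1.0, vy=0.0, extent=1.0)
        vel, esc = vs.sample(0.0, np.array([[5.0, 0.0], [0.0, 0.0]]))
        assert esc[0] and not esc[1]
        np.testing.assert_allclose(vel[0], [1.0, 0.0])

    def test_disk_resampling_accuracy(self):
        grid = DiskGrid(32, 64)
        x, y = grid.mesh_xy()
        f = x + 0.5 * y**2
        xs = np.linspace(-0.95, 0.95, 49)
        out = resample_disk_to_cartesian(grid, [f], xs, xs)[0]
        X, Y = np.meshgrid(xs, xs)
        inside = np.hypot(X, Y) < 0.9
        assert np.abs(out - (X + 0.5 * Y**2))[inside].max() < 5e-3
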