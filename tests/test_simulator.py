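"""Scenario construction, 1D/2D integration, sweeps."""

import numpy as np
import pandas as pd
import pytest

from gastruflow import (
    DiskGrid,
    GaussianFeature,
    ModelParams,
    Scenario,
    build_scenario,
    default_params,
    parameter_sweep,
    run_1d,
    run_2d,
    uniform_equilibria,
)


class TestBuildScenario:
    def test_reptilian_is_wild_type_pattern_with_p0_zero(self):
        grid = DiskGrid(16, 32)
        p = default_params()
        wt, p_wt = build_scenario("wild_type", p, grid)
        rep, p_rep = build_scenario("reptilian", p, grid)
        np.testing.assert_array_equal(wt.m, rep.m)
        np.testing.assert_array_equal(wt.phi, rep.phi)
        assert p_wt.p0 == p.p0 and p_rep.p0 == 0.0

    def test_amphibian_is_teleost_pattern_with_p0_zero(self):
        grid = DiskGrid(16, 32)
        p = default_params()
        tel, _ = build_scenario("teleost", p, grid)
        amp, p_amp = build_scenario("amphibian", p, grid)
        np.testing.assert_array_equal(tel.m, amp.m)
        assert p_amp.p0 == 0.0

    def test_teleost_ring_is_rotationally_symmetric(self):
        grid = DiskGrid(16, 32)
        state, _ = build_scenario("teleost", default_params(), grid)
        variation = np.ptp(state.m, axis=1).max()
        assert variation < 1e-12

    def test_twin_has_exactly_two_feature_maxima(self):
        grid = DiskGrid(48, 96)
        state, _ = build_scenario("twin", default_params(), grid)
        mid = uniform_equilibria(default_params()).roots[1]
        excess = state.m - mid
        # local maxima above half the feature amplitude
        peaks = 0
        for j in range(1, grid.nr - 1):
            for k in range(grid.ntheta):
                kp, km = (k + 1) % grid.ntheta, (k - 1) % grid.ntheta
                if excess[j, k] > 0.4 and excess[j, k] >= max(
                    excess[j - 1, k], excess[j + 1, k], excess[j, kp], excess[j, km]
                ):
                    peaks += 1
        assert peaks == 2

    def test_baseline_is_middle_root_with_azimuthal_cables(self):
        grid = DiskGrid(16, 32)
        p = default_params()
        state, _ = build_scenario("wild_type", p, grid)
        mid = uniform_equilibria(p).roots[1]
        # anterior half is unperturbed baseline
        _, th = grid.mesh_polar()
        anterior = np.abs(np.angle(np.exp(1j * (th - np.pi / 2)))) < np.pi / 4
        np.testing.assert_allclose(state.m[anterior], mid, atol=1e-6)
        np.testing.assert_allclose(
            state.phi, np.mod(th + np.pi / 2, np.pi), atol=1e-12
        )

    def test_monostable_parameters_raise_calibration_error(self):
        grid = DiskGrid(8, 16)
        with pytest.raises(ValueError, match="[Rr]ecalibrate"):
            build_scenario("wild_type", ModelParams(p4=0.0), grid)

    def test_unknown_scenario_name_lists_options(self):
        with pytest.raises(ValueError, match="wild_type"):
            Scenario.from_name("zebra")

    def test_feature_validation(self):
        with pytest.raises(ValueError):
            GaussianFeature("blob", 0.5, 0.1, 1.0)
        with pytest.raises(ValueError):
            GaussianFeature("arc", 0.5, 0.1, -1.0)


class TestRun1D:
    def test_lower_stable_root_resists_noise(self):
        p = default_params()
        lo = uniform_equilibria(p).roots[0]
        nx, L = 256, 10.0
        x = (np.arange(nx) + 0.5) * L / nx
        rng = np.random.default_rng(11)
        ic = np.maximum(lo + 1e-6 * rng.standard_normal(nx), 0.0)
        res = run_1d(p, ic, domain_length=L, t_end=20.0)
        assert res.completed
        assert np.abs(res.m[-1] - lo).max() < 1e-3

    def test_focusing_instability_grows_peak_with_colocated_sink(self):
        p = default_params()
        eq = uniform_equilibria(p)
        mid, hi = eq.roots[1], eq.roots[2]
        nx, L = 512, 10.0
        x = (np.arange(nx) + 0.5) * L / nx
        ic = mid + 0.5 * np.exp(-((x - L / 2) ** 2) / 2.0)
        res = run_1d(p, ic, domain_length=L, t_end=60.0, output_every=1.0)
        mm = res.summaries.max_m.to_numpy()
        assert mm[-1] > mm[0]
        assert mm.max() <= 1.05 * hi
        assert res.ux[-1].min() < 0
        i_m = int(res.m[-1].argmax())
        i_u = int(res.ux[-1].argmin())
        assert abs(i_m - i_u) <= 2

    def test_mirror_symmetric_ic_stays_symmetric(self):
        p = default_params()
        mid = uniform_equilibria(p).roots[1]
        nx, L = 256, 10.0
        x = (np.arange(nx) + 0.5) * L / nx
        ic = mid + 0.5 * np.exp(-((x - L / 2) ** 2) / 2.0)
        res = run_1d(p, ic, domain_length=L, t_end=10.0)
        m = res.m[-1]
        assert np.abs(m - m[::-1]).max() < 1e-6 * m.max()


class TestRun2D:
    def test_uniform_lower_root_is_a_fixed_point(self):
        """Stable uniform state (uniform cables, v_b = 0): no flow, no
        drift.  Uniform phi is essential -- an azimuthal director carries
        hoop tension and would drive a centreward flow."""
        p = default_params(v_b=0.0)
        grid = DiskGrid(16, 32)
        lo = uniform_equilibria(p).roots[0]
        from gastruflow import FieldState

        state0 = FieldState(
            grid=grid, t=0.0, m=np.full(grid.shape, lo), phi=np.full(grid.shape, 0.3)
        )
        res = run_2d(state0, p, t_end=2.0, output_every=0.5)
        assert res.completed
        last = res.states[-1]
        assert np.hypot(last.u, last.v).max() < 1e-8
        assert np.abs(last.m - lo).max() < 1e-6

    def test_determinism_bit_identical(self):
        p = default_params()
        grid = DiskGrid(16, 32)
        r1 = run_2d("wild_type", p, grid=grid, t_end=1.0, output_every=0.5)
        r2 = run_2d("wild_type", p, grid=grid, t_end=1.0, output_every=0.5)
        pd.testing.assert_frame_equal(r1.summaries, r2.summaries)
        np.testing.assert_array_equal(r1.states[-1].m, r2.states[-1].m)

    def test_time_step_refinement_first_order(self):
        """Halving dt_max changes the final fields consistently with the
        first-order operator splitting (error ratio near 2)."""
        p = default_params()
        grid = DiskGrid(16, 32)
        fields = []
        for dt_max in (0.02, 0.01, 0.005):
            res = run_2d(
                "wild_type", p, grid=grid, t_end=0.5, dt_max=dt_max, cfl=10.0,
                output_every=0.5,
            )
            fields.append(res.states[-1].m)
        e1 = np.abs(fields[0] - fields[1]).max()
        e2 = np.abs(fields[1] - fields[2]).max()
        assert 1.3 < e1 / e2 < 3.5

    def test_saturation_bound_and_symmetry(self, wild_mid, params):
        """Shipped wild-type run: m bounded by the upper root and AP
        mirror symmetry preserved through t_end."""
        hi = uniform_equilibria(params).roots[2]
        for st in wild_mid.states:
            assert st.m.max() <= 1.05 * hi
        assert wild_mid.summaries.symmetry_error.max() < 1e-4

    def test_snapshot_times_increasing_and_summaries_match(self, wild_mid):
        assert np.all(np.diff(wild_mid.times) > 0)
        from gastruflow import streak_metrics

        last = wild_mid.states[-1]
        recomputed = streak_metrics(last, wild_mid.params)
        row = wild_mid.summaries.iloc[-1]
        assert recomputed["max_m"] == pytest.approx(row.max_m)
        assert recomputed["ingression_flux"] == pytest.approx(row.ingression_flux)


class TestParameterSweep:
    def test_degenerate_sweep_equals_base_run(self):
        p = default_params()
        grid = DiskGrid(12, 24)
        base = run_2d("wild_type", p, grid=grid, t_end=1.0)
        table = parameter_sweep(
            "wild_type", p, "p0", [p.p0], grid=grid, t_end=1.0
        )
        assert len(table) == 1
        assert table.iloc[0].max_m == pytest.approx(base.summaries.iloc[-1].max_m)

    def test_p0_sweep_reproduces_reptilian_ordering(self, wild_mid, reptilian_mid):
        """Consistency: sweep rows at p0 in {0, default} reproduce the
        wild-type vs reptilian comparison of the full runs."""
        w = wild_mid.summaries.iloc[-1]
        r = reptilian_mid.summaries.iloc[-1]
        assert abs(r.ingression_flux) < abs(w.ingression_flux)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="p0"):
            parameter_sweep("wild_type", default_params(), "bogus", [1.0])

    def test_individual_failures_recorded_not_raised(self):
        p = default_params()
        grid = DiskGrid(12, 24)
        table = parameter_sweep(
            "wild_type", p, "p4", [0.0, p.p4], grid=grid, t_end=0.5
        )
        assert len(table) == 2
        assert not table.iloc[0].completed  # p4=0: no bistability -> row failure
        assert table.iloc[1].completed
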