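"""Darcy–Forchheimer solver, coefficient models, tracer transport."""

import numpy as np
import pytest

from gradedtpms import porous_flow as pf
from gradedtpms import synthetic_ct as sc
from gradedtpms.grids import RegularGrid

from conftest import resistor_network_solve


class TestCoefficients:
    def test_reference_point_returns_reference_values(self):
        model = pf.ParametricCoefficients(d0=5e8, f0=2e4, cs0=1.2)
        D, F = model(1.2)
        assert D == pytest.approx(5e8) and F == pytest.approx(2e4)

    def test_pore_size_scaling_law(self):
        model = pf.ParametricCoefficients(d0=5e8, f0=2e4, cs0=1.2)
        D, F = model(2.4)
        assert D == pytest.approx(5e8 / 4) and F == pytest.approx(2e4 / 2)

    def test_parametric_d_strictly_decreasing(self):
        model = pf.ParametricCoefficients()
        cs = np.linspace(1.2, 3.0, 30)
        D, _ = model(cs)
        assert np.all(np.diff(D) < 0)

    def test_table_interpolation_and_range_error(self):
        cs = np.array([1.2, 1.8, 2.4])
        model = pf.TableCoefficients(cs, [9e8, 4e8, 2e8], [1e4, 7e3, 5e3])
        D, F = model(1.8)
        assert D == pytest.approx(4e8) and F == pytest.approx(7e3)
        with pytest.raises(ValueError, match="table range"):
            model(3.0)


class TestPressureLoss:
    def test_zero_velocity_gives_zero_gradient(self):
        props = pf.PorousProps(1e10, 1e4, 0.5)
        assert np.all(pf.pressure_loss(np.zeros(3), props) == 0)

    def test_direct_evaluation(self):
        # η=1e-3, ρ=1000, D=1e10, F=1e4, u=(0.01,0,0) → (ηD + ½ρF|u|)u
        props = pf.PorousProps(1e10, 1e4, 0.5, eta=1e-3, rho=1000.0)
        grad = pf.pressure_loss(np.array([0.01, 0.0, 0.0]), props)
        assert grad[0] == pytest.approx(100500.0)
        assert grad[1] == grad[2] == 0.0

    def test_darcy_limit_is_linear(self):
        props = pf.PorousProps(1e9, 0.0, 0.5)
        g1 = pf.pressure_loss(np.array([0.01, 0.0, 0.0]), props)
        g2 = pf.pressure_loss(np.array([0.02, 0.0, 0.0]), props)
        assert np.allclose(g2, 2 * g1)


class TestSteadySolver:
    def test_uniform_darcy_column_analytic(self):
        fx = sc.make_flow_fixture("uniform_column")
        flow = pf.solve_steady(fx.props, fx.geometry, fx.Q)
        u_y = flow.u[0, :, 0, 1]
        assert np.allclose(u_y, fx.expected["u"], rtol=1e-6)
        # linear pressure profile
        p = flow.p[0, :, 0]
        assert np.allclose(np.diff(p), np.diff(p)[0], rtol=1e-6)

    def test_inlet_outlet_flux_balance(self):
        fx = sc.make_flow_fixture("corner_inlet_box")
        flow = pf.solve_steady(fx.props, fx.geometry, fx.Q)
        qin, qout = pf.flow_balance(flow, fx.geometry)
        assert abs(qin - qout) / fx.Q < 1e-6
        assert qin == pytest.approx(fx.Q, rel=1e-9)

    def test_two_channel_split_matches_resistor_ratio(self):
        fx = sc.make_flow_fixture("two_channel")
        flow = pf.solve_steady(fx.props, fx.geometry, fx.Q)
        fy = flow.face_flux[1]
        q0, q2 = fy[0, 5, 0], fy[2, 5, 0]
        split = q2 / (q0 + q2)
        assert split == pytest.approx(0.8, abs=0.008)  # D₂ = D₁/4 → 80/20

    def test_darcy_matches_dense_resistor_oracle(self, rng):
        """Random heterogeneous D on a 5×5 block grid vs the dense oracle."""
        shape = (5, 5, 1)
        grid = RegularGrid(shape, (0.01, 0.01, 0.01), centered=True)
        geom = pf.FlowGeometry(grid, [pf.Patch("ymin")], [pf.Patch("ymax")])
        D = 10 ** rng.uniform(8.5, 9.5, shape)
        props = pf.PorousProps(D, 0.0, 0.5)
        Q = 1e-6
        flow = pf.solve_steady(props, geom, Q)
        inlet = [(c, ax) for ax, _, cells in geom.patch_cells(geom.inlet) for c in cells]
        outlet = [(c, ax) for ax, _, cells in geom.patch_cells(geom.outlet) for c in cells]
        p_oracle = resistor_network_solve(D, grid, inlet, outlet, Q)
        assert np.allclose(flow.p, p_oracle, rtol=1e-8, atol=1e-8 * np.abs(p_oracle).max())
        # per-column flow split agrees within 1%
        fy = flow.face_flux[1]
        eta = 1e-3
        assert np.abs(fy[:, 2, 0].sum() - Q) / Q < 1e-9

    def test_flow_split_invariant_to_flow_rate_in_darcy_regime(self):
        fx = sc.make_flow_fixture("two_channel")
        splits = []
        for scale in (1.0, 4.0):
            flow = pf.solve_steady(fx.props, fx.geometry, fx.Q * scale)
            fy = flow.face_flux[1]
            splits.append(fy[2, 5, 0] / (fy[0, 5, 0] + fy[2, 5, 0]))
        assert splits[0] == pytest.approx(splits[1], abs=1e-10)

    def test_larger_cells_draw_more_flow(self):
        """Lowering D in one channel strictly increases its share."""
        fx = sc.make_flow_fixture("two_channel")
        props2 = pf.PorousProps(fx.props.D.copy(), 0.0, 0.5)
        props2.D[2, 1:-1, :] /= 2.0
        f1 = pf.solve_steady(fx.props, fx.geometry, fx.Q)
        f2 = pf.solve_steady(props2, fx.geometry, fx.Q)
        share = lambda f: f.face_flux[1][2, 5, 0]
        assert share(f2) > share(f1)

    def test_forchheimer_nonlinearity_converges(self):
        fx = sc.make_flow_fixture("corner_inlet_box")
        flow = pf.solve_steady(fx.props, fx.geometry, fx.Q)
        assert flow.iterations < 200
        assert flow.history[-1] < 1e-8

    def test_nonconvergence_raises_with_history(self):
        fx = sc.make_flow_fixture("corner_inlet_box")
        with pytest.raises(pf.ConvergenceError) as err:
            pf.solve_steady(fx.props, fx.geometry, fx.Q, max_iter=3)
        assert len(err.value.history) == 3


def test_reference_velocity_formula():
    assert pf.reference_velocity(1e-5, 1e-3, 0.5) == pytest.approx(0.02)
    assert pf.reference_velocity(1e-5, 1e-3, 1.0) == pytest.approx(0.01)
    assert pf.reference_velocity(1e-5, 1e-3, 0.25) == pytest.approx(0.04)
    with pytest.raises(ValueError):
        pf.reference_velocity(1e-5, 0.0, 0.5)


class TestTracer:
    def _column(self):
        fx = sc.make_flow_fixture("uniform_column")
        flow = pf.solve_steady(fx.props, fx.geometry, fx.Q)
        return fx, flow

    def test_zero_velocity_freezes_field(self):
        fx, flow = self._column()
        frozen = pf.FlowField(flow.grid, flow.p, flow.u * 0,
                              tuple(f * 0 for f in flow.face_flux),
                              flow.residual, flow.iterations, flow.history)
        series = pf.advect_tracer(frozen, fx.props, fx.geometry,
                                  pf.BolusInjection(), t_end=3.0)
        assert np.all(series.fields == 0)

    def test_front_speed_matches_characteristics(self):
        """Tracer front travels at the interstitial speed u/ε."""
        fx, flow = self._column()
        u_int = fx.expected["interstitial_u"]  # 0.02 m/s
        series = pf.advect_tracer(flow, fx.props, fx.geometry,
                                  pf.BolusInjection(duration=100.0), t_end=4.0)
        h = flow.grid.spacing[1]
        for t_idx in (4, 8):
            t = series.times[t_idx]
            front = u_int * t
            phi = series.fields[t_idx][0, :, 0]
            pos = (phi > 0.1).sum() * h  # half-height front position
            assert abs(pos - front) <= max(h, front / 10)

    def test_mass_conserved_between_injection_and_breakthrough(self):
        fx, flow = self._column()
        series = pf.advect_tracer(flow, fx.props, fx.geometry,
                                  pf.BolusInjection(duration=1.0), t_end=4.0)
        eps, V = 0.5, flow.grid.cell_volume
        masses = series.fields.sum(axis=(1, 2, 3)) * eps * V
        injected = fx.Q * 0.2 * 1.0  # Q · Φ_max · duration
        # column transit ≈ 5 s; mass constant from injection end until the
        # numerically diffused front nears the outlet
        for t_idx, t in enumerate(series.times):
            if 1.0 <= t <= 2.5:
                assert masses[t_idx] == pytest.approx(injected, rel=1e-10)

    def test_tracer_bounded_by_phi_max(self):
        fx = sc.make_flow_fixture("corner_inlet_box")
        flow = pf.solve_steady(fx.props, fx.geometry, fx.Q)
        series = pf.advect_tracer(flow, fx.props, fx.geometry,
                                  pf.BolusInjection(phi_max=0.2), t_end=20.0)
        assert series.fields.min() >= 0.0
        assert series.fields.max() <= 0.2 + 1e-12

    def test_total_mass_non_increasing_after_injection(self):
        fx = sc.make_flow_fixture("corner_inlet_box")
        flow = pf.solve_steady(fx.props, fx.geometry, fx.Q)
        series = pf.advect_tracer(flow, fx.props, fx.geometry,
                                  pf.BolusInjection(duration=2.0), t_end=20.0)
        masses = series.fields.sum(axis=(1, 2, 3))
        after = masses[series.times >= 2.5]
        assert np.all(np.diff(after) <= 1e-12)
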