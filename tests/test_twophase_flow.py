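"""Pressure solve, Darcy fluxes and implicit saturation transport."""

from dataclasses import replace

import numpy as np
import pytest

from thermoembo import InjectionSchedule, ParameterSet, make_box_mesh
from thermoembo.chemistry import ATM, ParameterError
from thermoembo.twophase_flow import (
    advance_saturation,
    assemble_pressure_system,
    capillary_pressure,
    compute_flow_state,
    darcy_velocity,
    fractional_flow,
    mobility,
    pressure_dirichlet,
    quiescent_state,
    solve_pressure,
)

from conftest import left_end_vessel


class TestConstitutive:
    def test_capillary_pressure_at_full_blood(self):
        pd = 0.074 * ATM
        assert capillary_pressure(1.0, pd) == pytest.approx(pd)

    def test_capillary_pressure_half_blood(self):
        pd = 0.074 * ATM
        assert capillary_pressure(0.5, pd) == pytest.approx(2 * pd)

    def test_capillary_floor_caps_blowup(self):
        pd = 0.074 * ATM
        assert capillary_pressure(1e-6, pd) == pytest.approx(pd / 1e-3)
        s = np.linspace(0.0, 1.0, 11)
        pc = capillary_pressure(s, pd)
        assert np.all(np.diff(pc) <= 0)  # non-increasing in blood saturation

    def test_mobility_values_and_linearity(self):
        assert mobility(0.0, 5e-12, 8.9e-4) == 0.0
        assert mobility(1.0, 5e-12, 8.9e-4) == pytest.approx(5.618e-9, rel=1e-3)
        assert mobility(0.5, 5e-12, 8.9e-4) == pytest.approx(
            0.5 * mobility(1.0, 5e-12, 8.9e-4)
        )
        with pytest.raises(ParameterError):
            mobility(0.5, 5e-12, 0.0)

    def test_fractional_flow_endpoints_and_derivative(self, params):
        f0, _ = fractional_flow(0.0, params)
        f1, _ = fractional_flow(1.0, params)
        assert f0 == 0.0 and f1 == pytest.approx(1.0)
        s = np.linspace(0.01, 0.99, 50)
        f, df = fractional_flow(s, params)
        num = np.gradient(f, s)
        np.testing.assert_allclose(df[2:-2], num[2:-2], rtol=1e-3)
        assert np.all(df > 0)


@pytest.fixture
def injection():
    return InjectionSchedule(t_start=0.0, duration=25.0, p_injection=1.16 * ATM)


class TestPressureSolve:
    def test_1d_laplace_linear_profile(self, injection):
        """Uniform mobility, no reaction: the pressure equation reduces to
        the 1-D Laplace problem with Dirichlet ends."""
        par = ParameterSet(gamma=0.0)
        mesh = left_end_vessel(make_box_mesh((0.05,), (50,)))
        p = solve_pressure(mesh, np.zeros(50), par, injection, t=1.0)
        x = mesh.cell_centers[:, 0]
        expected = injection.p_injection + (par.p0 - injection.p_injection) * x / 0.05
        np.testing.assert_allclose(p, expected, rtol=1e-7)

    def test_1d_flux_constant_along_domain(self, injection):
        par = ParameterSet(gamma=0.0)
        mesh = left_end_vessel(make_box_mesh((0.05,), (50,)))
        flow = compute_flow_state(mesh, np.zeros(50), par, injection, t=1.0)
        np.testing.assert_allclose(
            np.abs(flow.v_total), np.abs(flow.v_total[0]), rtol=1e-6
        )

    def test_2d_matches_dense_direct_solve(self, injection, params):
        """Sparse iterative/direct solve agrees with a dense solve of the
        same assembled system."""
        mesh = make_box_mesh((0.02, 0.02), (8, 8))
        mesh = left_end_vessel(mesh)
        rng = np.random.default_rng(3)
        s = rng.uniform(0.0, 0.8, mesh.n_cells)
        p_bc = pressure_dirichlet(mesh, params, injection, 1.0)
        A, b, _ = assemble_pressure_system(mesh, s, params, p_bc)
        dense = np.linalg.solve(A.toarray(), b)
        p = solve_pressure(mesh, s, params, injection, t=1.0)
        np.testing.assert_allclose(p, dense, rtol=1e-8)

    def test_initial_state_without_injection_is_atmospheric(self, params):
        mesh = left_end_vessel(make_box_mesh((0.01,), (10,)))
        late = InjectionSchedule(t_start=10.0, duration=25.0,
                                 p_injection=1.16 * ATM)
        p = solve_pressure(mesh, np.zeros(10), params, late, t=0.0)
        np.testing.assert_allclose(p, params.p0, rtol=1e-12)


class TestDarcyVelocity:
    def make_linear(self, dp):
        par = ParameterSet(gamma=0.0)
        mesh = make_box_mesh((0.05,), (50,))
        x = mesh.cell_centers[:, 0]
        p = par.p0 + dp * (1.0 - x / 0.05)
        p_bc = np.full(mesh.n_faces, np.nan)
        return par, mesh, p, p_bc

    def test_hand_computed_flux_for_pure_bolus(self):
        # |v| = (kappa/mu_bolus) * dp/L for a fully bolus-saturated column
        par, mesh, p, p_bc = self.make_linear(0.16 * ATM)
        s = np.ones(50)
        v_b, v_o, vt = darcy_velocity(mesh, p, s, par, p_bc)
        expected = (5e-12 / 0.70e-3) * (0.16 * ATM / 0.05)
        interior = mesh.interior
        np.testing.assert_allclose(v_o[interior], expected, rtol=1e-10)
        assert expected == pytest.approx(2.316e-3, rel=1e-3)
        np.testing.assert_allclose(v_b[interior], 0.0, atol=1e-20)

    def test_uniform_pressure_gives_zero_velocity(self, params):
        mesh = make_box_mesh((0.05,), (50,))
        p = np.full(50, params.p0)
        p_bc = np.full(mesh.n_faces, np.nan)
        v_b, v_o, vt = darcy_velocity(mesh, p, np.full(50, 0.3), params, p_bc)
        np.testing.assert_allclose(vt, 0.0, atol=1e-20)
        np.testing.assert_allclose(v_o, 0.0, atol=1e-20)

    def test_flipping_gradient_flips_velocities(self):
        par, mesh, p, p_bc = self.make_linear(0.16 * ATM)
        s = np.full(50, 0.5)
        _, v_o1, vt1 = darcy_velocity(mesh, p, s, par, p_bc)
        _, v_o2, vt2 = darcy_velocity(mesh, 2 * par.p0 - p, s, par, p_bc)
        np.testing.assert_allclose(vt2, -vt1, rtol=1e-12)
        np.testing.assert_allclose(v_o2, -v_o1, rtol=1e-12)


class TestSaturationTransport:
    def test_uniform_decay_matches_closed_form(self, params):
        """With no flow, the mass balance is the scalar ODE whose solution
        is s(t) = s(0) exp(-gamma*eps*rho_DCACl*t/rho_bolus)."""
        mesh = make_box_mesh((0.01,), (10,))
        s = np.full(10, 0.8)
        for _ in range(600):
            state = quiescent_state(mesh, s, params)
            s, _ = advance_saturation(state, mesh, params, None, 1.0)
        rate = params.gamma * params.epsilon * params.rho_dcacl / params.rho_bolus
        expected = 0.8 * np.exp(-rate * 600.0)
        np.testing.assert_allclose(s, expected, rtol=5e-3)

    def test_inert_bolus_is_untouched(self):
        par = ParameterSet(gamma=0.0)
        mesh = make_box_mesh((0.01,), (10,))
        s0 = np.linspace(0.0, 0.0, 10)
        state = quiescent_state(mesh, s0, par)
        s, _ = advance_saturation(state, mesh, par, None, 1.0)
        np.testing.assert_array_equal(s, s0)

    def test_implicit_advection_matches_explicit_reference(self):
        """Implicit upwind front propagation agrees with a brute-force
        explicit upwind reference run at tiny time steps."""
        par = ParameterSet(gamma=0.0, pd=1e-9)  # negligible capillarity
        mesh = make_box_mesh((0.05,), (100,))
        dx = mesh.spacing[0]
        v = 1e-3  # uniform total flux (m/s)
        s0 = np.where(mesh.cell_centers[:, 0] < 0.01, 0.8, 0.0)

        s_imp = s0.copy()
        base = quiescent_state(mesh, s0, par)
        base.v_total[:] = v
        for _ in range(100):
            state = replace(base, s_bolus=s_imp, s_blood=1.0 - s_imp)
            s_imp, _ = advance_saturation(state, mesh, par, None, 0.005)

        # explicit upwind oracle, same flux function, dt at 1/20 CFL
        s_exp = s0.copy()
        dt_exp = 2.5e-4
        for _ in range(2000):
            f, _ = fractional_flow(s_exp, par)
            F = np.zeros(101)
            F[1:] = f * v  # upwind face flux (flow to the right)
            s_exp = s_exp - dt_exp / par.phi * (F[1:] - F[:-1]) / dx

        l1 = np.abs(s_imp - s_exp).sum() * dx
        assert l1 < 1e-3

    def test_sealed_reaction_free_mass_conservation(self):
        """Capillary redistribution in a sealed box conserves bolus mass."""
        par = ParameterSet(gamma=0.0)
        mesh = make_box_mesh((0.02, 0.02), (16, 16))
        X = mesh.cell_centers
        s = 0.5 * np.exp(
            -((X[:, 0] - 0.01) ** 2 + (X[:, 1] - 0.01) ** 2) / (2 * 0.003**2)
        )
        total0 = s.sum()
        for _ in range(50):
            flow = compute_flow_state(mesh, s, par, None, 0.0, sealed_far=True)
            s, _ = advance_saturation(flow, mesh, par, None, 1.0)
        assert abs(s.sum() - total0) / total0 < 1e-8
        assert 0.0 <= s.min() and s.max() <= 1.0

    def test_injection_keeps_saturation_bounded(self, injection, params):
        mesh = left_end_vessel(make_box_mesh((0.02,), (40,)))
        s = np.zeros(40)
        for k in range(25):
            flow = compute_flow_state(mesh, s, params, injection, t=k + 1.0)
            s, _ = advance_saturation(flow, mesh, params, injection, 1.0)
            assert s.min() >= 0.0 and s.max() <= 1.0
        assert s.max() > 0.5  # bolus actually entered

    def test_reaction_mass_balance_ledger(self, injection, params):
        """Per-step discrete balance: change of bolus mass = rho_bolus *
        boundary influx - reacted mass."""
        mesh = left_end_vessel(make_box_mesh((0.02,), (40,)))
        V = mesh.cell_volume
        s = np.zeros(40)
        for k in range(10):
            flow = compute_flow_state(mesh, s, params, injection, t=k + 1.0)
            before = params.phi * params.rho_bolus * s.sum() * V
            s, diag = advance_saturation(flow, mesh, params, injection, 1.0)
            after = params.phi * params.rho_bolus * s.sum() * V
            expected = (
                params.rho_bolus * diag["boundary_bolus_volume_rate"]
                - diag["reacted_mass_rate"]
            )
            assert after - before == pytest.approx(expected, abs=1e-12 + 1e-8 * abs(after))
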