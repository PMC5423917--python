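"""Discretisation oracles and full-simulation invariants."""

import numpy as np
import pytest

import cuticle_uptake as cu
from cuticle_uptake import solver
from cuticle_uptake.params import NumericsConfig, with_overrides
from cuticle_uptake.solver import _System, flux_divergence, initial_state, make_mesh


class TestDiscretisation:
    def test_divergence_matches_dense_operator(self):
        # brute-force dense-matrix oracle on an 11-node mesh
        rng = np.random.default_rng(7)
        n = 11
        dx = 0.1
        a = rng.uniform(0.0, 1.0, n)
        D = rng.uniform(0.5, 2.0, n)
        M = np.zeros((n - 2, n))
        for row, i in enumerate(range(1, n - 1)):
            Dw = 0.5 * (D[i - 1] + D[i])
            De = 0.5 * (D[i] + D[i + 1])
            M[row, i - 1] = Dw / dx**2
            M[row, i] = -(Dw + De) / dx**2
            M[row, i + 1] = De / dx**2
        np.testing.assert_allclose(flux_divergence(a, D, dx), M @ a, rtol=1e-13)

    def test_single_spike_laplacian_response(self):
        n, dx = 11, 0.25
        a = np.zeros(n)
        a[5] = 1.0
        D = np.full(n, 2.0)
        expected = np.zeros(n - 2)
        expected[3] = 2.0 / dx**2
        expected[4] = -4.0 / dx**2
        expected[5] = 2.0 / dx**2
        np.testing.assert_allclose(flux_divergence(a, D, dx), expected, rtol=1e-13)

    def test_symmetric_field_symmetric_response(self):
        x = np.linspace(0, 1, 21)
        a = np.exp(-((x - 0.5) ** 2) / 0.02)
        D = np.ones_like(a)
        out = flux_divergence(a, D, x[1] - x[0])
        np.testing.assert_allclose(out, out[::-1], rtol=1e-12)

    def test_harmonic_face_average_option(self):
        a = np.array([0.0, 1.0, 0.0])
        D = np.array([1.0, 3.0, 1.0])
        arith = flux_divergence(a, D, 1.0)
        harm = flux_divergence(a, D, 1.0, harmonic=True)
        assert arith[0] == pytest.approx(-4.0)
        assert harm[0] == pytest.approx(-3.0)


class TestInitialState:
    def test_humidity_sets_uniform_pore_radius(self, preset, consts):
        mesh = make_mesh(preset.cuticle.b, 31)
        st = initial_state(preset, consts, mesh)
        np.testing.assert_allclose(st.rp[1:], 2.12e-9 * 0.7, rtol=1e-9)
        # drop node: the dissolved AI depresses the water concentration,
        # hence a marginally narrower surface pore
        assert 0.999 < st.rp[0] / (2.12e-9 * 0.7) < 1.0
        assert st.c_AI[0] == preset.droplet.c_AI0
        assert np.all(st.c_AI[1:] == 0.0)
        # surface water slightly depressed by the dissolved AI
        assert st.c_H2O[0] < consts.c_H2O_pure
        np.testing.assert_allclose(st.c_H2O[1:], consts.c_H2O_pure)

    def test_near_saturated_air_opens_pores_fully(self):
        p = cu.load_params({"H": 0.999})
        c = cu.derive_constants(p)
        st = initial_state(p, c, make_mesh(p.cuticle.b, 21))
        np.testing.assert_allclose(st.rp[1:], p.cuticle.rp_max * 0.999, rtol=1e-9)
        np.testing.assert_allclose(st.Gamma[1:], c.Gamma_S, rtol=5e-3)

    def test_all_water_state_is_discrete_steady_state(self):
        # no AI anywhere: every time derivative must vanish identically
        p = cu.load_params({"c_AI0": 0.0})
        c = cu.derive_constants(p)
        mesh = make_mesh(p.cuticle.b, 21)
        sys = _System(p, c, mesh)
        st = initial_state(p, c, mesh)
        y = np.concatenate([[0.0, 0.0, 0.0], st.c_AI[1:-1], st.c_H2O[1:-1]])
        dydt = sys.rhs(0.0, y, lambda t: p.droplet.V0)
        m = sys.m
        # AI, binding and bath channels are identically zero
        np.testing.assert_array_equal(dydt[:3 + m], 0.0)
        # the water channel carries only the minute mismatch between the
        # tabulated 1/vbar_H2O and rho_L/Mw_H2O (2.5e-5 relative) at the
        # surface node; everywhere else it vanishes
        assert np.max(np.abs(dydt[3 + m:])) < 0.02
        np.testing.assert_array_equal(dydt[3 + m + 1:], 0.0)


class TestSimulationInvariants:
    def test_uptake_monotone_and_bounded(self, preset_run):
        assert np.all(np.diff(preset_run.M_t_ug) >= -1e-10)
        assert np.all(preset_run.percent_uptake >= 0.0)
        assert preset_run.percent_uptake[-1] < 100.0

    def test_mass_audit_closes(self, preset_run):
        assert preset_run.mass_audit.rel_closure_error.max() < 1e-3

    def test_boundary_compliance(self, preset_run, consts):
        np.testing.assert_array_equal(preset_run.c_AI[:, -1], 0.0)
        np.testing.assert_array_equal(preset_run.c_H2O[:, -1], consts.c_H2O_pure)

    def test_drop_never_exceeds_solubility(self, preset_run, preset):
        assert preset_run.c_AI_drop.max() <= preset.solute.c_sat * (1 + 1e-9)

    def test_drop_exhausts_and_interior_relaxes(self, preset_run, consts):
        # late times: AI gone everywhere, water back to pure
        assert preset_run.c_AI_drop[-1] < 1e-3 * preset_run.c_AI_drop[0]
        assert np.max(np.abs(preset_run.c_AI[-1])) < 1e-3
        np.testing.assert_allclose(preset_run.c_H2O[-1], consts.c_H2O_pure,
                                   rtol=1e-4)

    def test_most_uptake_dynamics_before_four_hours(self, preset_run):
        # the cuticle interior loads and drains early: its content peaks
        # well before 4 h and most of the final uptake is in place by then
        content = preset_run.mass_audit.cuticle_mol.to_numpy()
        t_peak = preset_run.times[np.argmax(content)]
        assert t_peak < 4 * 3600.0
        i4 = np.searchsorted(preset_run.times, 4 * 3600.0)
        assert preset_run.M_t_ug[i4] > 0.5 * preset_run.M_t_ug[-1]

    def test_percent_uptake_consistent_with_mass(self, preset_run, preset):
        expected = preset_run.M_t_ug / cu.applied_mass_ug(preset) * 100.0
        np.testing.assert_allclose(preset_run.percent_uptake, expected, rtol=1e-12)

    def test_trapezoid_uptake_matches_integrated_state(self, preset_run, preset):
        # trapezoidal quadrature of the dense reported flux series agrees
        # with the ODE-integrated bath ledger behind M_t
        M_trap = solver.cumulative_uptake(
            preset_run.times, preset_run.bath_flux, preset.solute.Mw_AI,
            preset_run.consts.A_drop * preset.cuticle.rho0 * preset_run.consts.A_Pi,
            preset.droplet.n_drops)
        assert M_trap[-1] == pytest.approx(preset_run.M_t_ug[-1], rel=1e-3)

    def test_without_binding_uptake_dominates_everywhere(self, preset,
                                                         coarse_numerics):
        times = list(np.linspace(0.0, 48 * 3600.0, 49))
        coarse_numerics.output_times = times
        run_k = cu.simulate(preset, coarse_numerics)
        run_0 = cu.simulate(with_overrides(preset, k=0.0), coarse_numerics)
        mask = run_k.times > 0
        assert np.all(run_0.M_t_ug[mask] >= run_k.M_t_ug[mask] - 1e-9)
        # with no surface sink, essentially everything eventually crosses
        assert run_0.percent_uptake[-1] > 99.0
        assert run_k.percent_uptake[-1] < run_0.percent_uptake[-1]

    def test_floor_time_reported(self, preset_run):
        assert preset_run.t_star == pytest.approx(2761.1, rel=1e-3)
        assert np.min(np.abs(preset_run.times - preset_run.t_star)) < 1e-6


class TestCumulativeUptake:
    def test_zero_flux(self):
        t = np.linspace(0, 10, 11)
        out = solver.cumulative_uptake(t, np.zeros_like(t), 110.98, 1.6e-6, 5)
        np.testing.assert_array_equal(out, 0.0)

    def test_constant_flux_linear(self):
        t = np.linspace(0.0, 100.0, 26)
        f = 2.5e-7
        out = solver.cumulative_uptake(t, np.full_like(t, f), 110.98, 1.6e-6, 5)
        slope = 1e6 * 110.98 * 1.6e-6 * 5 * f
        np.testing.assert_allclose(out, slope * t, rtol=1e-12)


class TestErrorHandling:
    def test_output_times_outside_span_rejected(self, preset):
        num = NumericsConfig(t_final=10.0, output_times=[0.0, 20.0])
        with pytest.raises(cu.solver.IntegrationError):
            cu.simulate(preset, num)

    def test_small_mesh_rejected(self, preset):
        from cuticle_uptake.exceptions import ParameterError
        with pytest.raises(ParameterError):
            cu.simulate(preset, NumericsConfig(n_nodes=5))
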