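import numpy as np
import pytest

from conftest import zero_forcing
from stemheat import verification as ver
from stemheat.forcing import ForcingSeries, synthetic_lab_pulse
from stemheat.grid import StemGeometry, build_grid
from stemheat.solver import (ConstantPropertyModel, RunConfig, Simulator,
                             initial_state, run, uniform_state)

CONST = ConstantPropertyModel(rho=500.0, k=0.5, cp=2000.0)


def small_grid(n_wedges=8, d=0.08, spacing=4e-3):
    return build_grid(StemGeometry(diameter=d, outer_bark_thickness=1e-3,
                                   inner_bark_thickness=1e-3,
                                   n_wedges=n_wedges, radial_spacing=spacing))


class TestAssembly:
    def test_uniform_fixed_point(self, pine):
        g = small_grid()
        cfg = RunConfig(dt=1.0, total_time=10.0, enable_sinks=False,
                        enable_viability=False)
        sim = Simulator(g, pine, cfg, zero_forcing())
        st = initial_state(g, pine, cfg)
        for _ in range(5):
            st = sim.step(st)
        np.testing.assert_allclose(st.T, 300.0, atol=1e-9)

    def test_zero_conductivity_identity(self):
        g = small_grid()
        cfg = RunConfig(dt=1.0, total_time=1.0, enable_sinks=False,
                        enable_viability=False)
        sim = Simulator(g, None, cfg, zero_forcing(),
                        property_model=ConstantPropertyModel(500.0, 0.0, 2000.0))
        st = uniform_state(g, 300.0)
        rng = np.random.default_rng(0)
        st.T = st.T + rng.uniform(0, 50, st.T.shape)
        A, b, aux = sim.assemble_system(st, 1.0)
        # no coupling: A is the diagonal mass matrix, b = C T
        np.testing.assert_allclose((A @ st.T.ravel()), b, rtol=1e-12)

    def test_interior_row_sums_equal_mass_term(self):
        g = small_grid()
        cfg = RunConfig(dt=2.0, enable_sinks=False, enable_viability=False)
        sim = Simulator(g, None, cfg, zero_forcing(), property_model=CONST)
        st = uniform_state(g, 320.0)
        A, b, aux = sim.assemble_system(st, 2.0)
        # conduction stencil row-sums cancel, leaving only rho cp V / dt
        row_sums = np.asarray(A.sum(axis=1)).ravel()
        np.testing.assert_allclose(row_sums, aux["C"], rtol=1e-10)

    def test_nonfinite_property_named_rejection(self, pine):
        g = small_grid()
        cfg = RunConfig(enable_sinks=False, enable_viability=False)

        class Broken:
            def evaluate(self, grid, state):
                rho = np.full(state.T.shape, 500.0)
                k = np.full(state.T.shape, 0.3)
                k[2, 1] = np.nan
                return rho, k, np.full(state.T.shape, 2000.0)

        sim = Simulator(g, None, cfg, zero_forcing(), property_model=Broken())
        with pytest.raises(ValueError, match=r"i=2, j=1"):
            sim.assemble_system(uniform_state(g, 300.0), 1.0)


class TestStep:
    def test_steady_without_forcing(self, pine):
        g = small_grid()
        cfg = RunConfig(dt=5.0, total_time=50.0, enable_sinks=False)
        res = run(g, pine, cfg, zero_forcing())
        np.testing.assert_allclose(res.final_state.T, 300.0, atol=1e-8)

    def test_uniform_heating_wedges_identical(self, pine, pulse):
        g = small_grid()
        cfg = RunConfig(dt=1.0, total_time=120.0)
        res = run(g, pine, cfg, pulse)
        T = res.final_state.T
        spread = np.abs(T - T[:, :1]).max()
        assert spread < 1e-8

    def test_rotation_equivariance(self, pine, pulse):
        g = small_grid(n_wedges=8)
        cfg = RunConfig(dt=1.0, total_time=90.0)
        mult = np.array([2.0, 1.0, 0.5, 0, 0, 0, 0.5, 1.0])
        res_a = run(g, pine, cfg, pulse.scaled(mult))
        res_b = run(g, pine, cfg, pulse.scaled(np.roll(mult, 3)))
        np.testing.assert_allclose(np.roll(res_a.final_state.T, 3, axis=1),
                                   res_b.final_state.T, atol=1e-8)

    def test_mirror_symmetry(self, pine, pulse):
        # forcing symmetric about the wedge-0/wedge-1 boundary -> mirrored field
        g = small_grid(n_wedges=8)
        cfg = RunConfig(dt=1.0, total_time=90.0)
        mult = np.array([3.0, 2.0, 1.0, 0, 0, 1.0, 2.0, 3.0])
        res = run(g, pine, cfg, pulse.scaled(mult))
        T = res.final_state.T
        np.testing.assert_allclose(T, T[:, ::-1], atol=1e-8)

    def test_no_flux_center_coldest_under_uniform_forcing(self, pine, pulse):
        g = small_grid()
        cfg = RunConfig(dt=1.0, total_time=200.0)
        res = run(g, pine, cfg, pulse)
        T = res.final_state.T
        assert np.argmin(T.mean(axis=1)) == g.n_radial - 1
        assert np.ptp(T[-1, :]) < 1e-8


class TestRun:
    def test_zero_total_time(self, pine, pulse, lab_grid):
        cfg = RunConfig(dt=1.0, total_time=0.0)
        res = run(lab_grid, pine, cfg, pulse)
        assert len(res.snapshots) == 1
        assert res.final_state.time == 0.0

    def test_forcing_must_cover_horizon(self, pine, pulse, lab_grid):
        cfg = RunConfig(dt=1.0, total_time=pulse.t_end + 100.0)
        with pytest.raises(ValueError, match="horizon"):
            run(lab_grid, pine, cfg, pulse)

    def test_energy_residual_sinks_off(self, pine, pulse, lab_grid):
        cfg = RunConfig(dt=1.0, total_time=300.0, enable_sinks=False)
        res = run(lab_grid, pine, cfg, pulse)
        assert res.energy["residual"] < 0.01
        assert res.energy["input_J"] > 0

    def test_energy_residual_sinks_on(self, pine, pulse, lab_grid):
        cfg = RunConfig(dt=1.0, total_time=300.0, enable_sinks=True)
        res = run(lab_grid, pine, cfg, pulse)
        assert res.energy["residual"] < 0.02
        assert res.energy["sinks_J"] > 0

    def test_water_mass_balance(self, pine, pulse, lab_grid):
        cfg = RunConfig(dt=1.0, total_time=300.0, enable_viability=False)
        sim = Simulator(lab_grid, pine, cfg, pulse)
        st0 = initial_state(lab_grid, pine, cfg)
        res = sim.run(st0.copy())
        lost = st0.water_mass.sum() - res.final_state.water_mass.sum()
        # latent bookkeeping and mass bookkeeping must agree
        assert lost * cfg.latent_heat == pytest.approx(res.energy["sinks_J"],
                                                       rel=1e-8)
        assert np.all(res.final_state.water_mass <= st0.water_mass + 1e-15)

    def test_water_monotone_per_node(self, pine, pulse, lab_grid):
        cfg = RunConfig(dt=2.0, total_time=200.0, output_every=20.0)
        res = run(lab_grid, pine, cfg, pulse)
        prev = None
        for snap in res.snapshots:
            if prev is not None:
                assert np.all(snap.water_mass <= prev + 1e-15)
            prev = snap.water_mass

    def test_sinks_vanish_at_ambient(self, pine, lab_grid):
        # unforced stem at 300 K, 1-hour horizon: no water loss, no cooling
        cfg = RunConfig(dt=10.0, total_time=3600.0, output_every=600.0)
        sim = Simulator(lab_grid, pine, cfg, zero_forcing())
        st0 = initial_state(lab_grid, pine, cfg)
        res = sim.run(st0.copy())
        assert res.energy["sinks_J"] == 0.0
        np.testing.assert_array_equal(res.final_state.water_mass,
                                      st0.water_mass)
        np.testing.assert_allclose(res.final_state.T, 300.0, atol=1e-8)

    def test_probe_series_shapes(self, pine, pulse, lab_grid, short_config):
        res = run(lab_grid, pine, short_config, pulse)
        n = int(short_config.total_time / short_config.dt) + 1
        assert res.probe_times.shape == (n,)
        for arr in res.probes.values():
            assert arr.shape == (n, lab_grid.n_wedges)
        # surface probe is the hottest during heating
        assert res.probes["T_surface_K"].max() > res.probes["T_cambium_K"].max()

    def test_deterministic(self, pine, pulse, lab_grid, short_config):
        a = run(lab_grid, pine, short_config, pulse)
        b = run(lab_grid, pine, short_config, pulse)
        np.testing.assert_array_equal(a.final_state.T, b.final_state.T)
        np.testing.assert_array_equal(a.final_state.log_N, b.final_state.log_N)


class TestVerificationBenchmarks:
    def test_steady_log_profile(self):
        # fixed surface and interior-ring temperatures on a constant-property
        # annulus: discrete steady state vs the analytic logarithmic profile
        g = build_grid(StemGeometry(diameter=0.14, n_wedges=8,
                                    radial_spacing=1e-3))
        pin = 55  # r = 15 mm, well away from the singular center
        cfg = RunConfig(dt=500.0, total_time=200000.0, output_every=1e5,
                        enable_sinks=False, enable_viability=False,
                        fixed_surface_temperature=400.0,
                        fixed_inner_temperature=300.0, fixed_inner_index=pin)
        res = run(g, None, cfg, zero_forcing(t_end=3e5), property_model=CONST,
                  state=uniform_state(g, 300.0))
        r = g.node_radii[:pin + 1]
        expected = ver.log_annulus_profile(r, g.node_radii[pin],
                                           g.surface_radius, 300.0, 400.0)
        got = res.final_state.T[:pin + 1, 0]
        assert np.abs(got - expected).max() < 0.1

    def test_transient_bessel_benchmark(self):
        g = build_grid(StemGeometry(diameter=0.1, n_wedges=8,
                                    radial_spacing=2.5e-3))
        alpha = CONST.k / (CONST.rho * CONST.cp)
        t_diff = (0.05) ** 2 / alpha
        cfg = RunConfig(dt=t_diff / 1000.0, total_time=t_diff,
                        output_every=t_diff / 10.0, enable_sinks=False,
                        enable_viability=False, fixed_surface_temperature=400.0)
        res = run(g, None, cfg, zero_forcing(t_end=2 * t_diff),
                  property_model=CONST, state=uniform_state(g, 300.0))
        r_in = g.node_radii[-1]
        expected = ver.cylinder_step_response(r_in, t_diff, 0.05, alpha,
                                              300.0, 400.0)
        got = res.final_state.T[-1, 0]
        rise = 400.0 - 300.0
        assert abs(got - expected) / rise < 0.01

    def test_cn_vs_explicit_euler_oracle(self, pine):
        # 8 wedges x 20 nodes, 600 s pulse, oracle at dt/100
        g = build_grid(StemGeometry(diameter=0.14, outer_bark_thickness=2e-3,
                                    inner_bark_thickness=2e-3, n_wedges=8,
                                    radial_spacing=3.5e-3))
        pulse = synthetic_lab_pulse(2e4, 60.0, 240.0, 300.0, ambient=300.0)
        cfg = RunConfig(dt=1.0, total_time=600.0, enable_sinks=False,
                        enable_viability=False)
        sim = Simulator(g, pine, cfg, pulse)
        st0 = initial_state(g, pine, cfg)
        res = sim.run(st0.copy())
        T_ref = ver.explicit_reference_run(g, sim.property_model, cfg, pulse,
                                           st0.copy(), dt=0.01,
                                           total_time=600.0)
        assert np.abs(res.final_state.T - T_ref).max() <= 0.5
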