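import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemheat import forcing as fc


class TestRadiantExchange:
    def test_equilibrium(self):
        assert fc.radiant_exchange(400.0, 400.0) == 0.0

    def test_hand_evaluation(self):
        # sigma (673^4 - 300^4)
        expected = 5.67e-8 * (673.0 ** 4 - 300.0 ** 4)
        assert fc.radiant_exchange(300.0, 673.0) == pytest.approx(expected)
        assert expected == pytest.approx(1.12e4, rel=5e-3)

    def test_antisymmetry(self):
        assert fc.radiant_exchange(350.0, 500.0) == pytest.approx(
            -fc.radiant_exchange(500.0, 350.0))


class TestFireFluxFromTemperature:
    def test_equilibrium(self):
        assert fc.fire_flux_from_temperature(285.0, 285.0) == 0.0

    def test_surface_fire_ground_level(self):
        got = fc.fire_flux_from_temperature(823.0, 285.0)
        assert got == pytest.approx(5.67e-8 * (823.0 ** 4 - 285.0 ** 4))
        assert got == pytest.approx(2.56e4, rel=2e-3)

    def test_clamped_below_ambient(self):
        assert fc.fire_flux_from_temperature(280.0, 285.0) == 0.0

    def test_monotone_in_fire_temperature(self):
        q = fc.fire_flux_from_temperature(np.linspace(300, 1200, 30), 285.0)
        assert np.all(np.diff(q) > 0)

    def test_composition_consistency(self):
        # fire flux == radiant exchange with the fire playing ambient, when positive
        assert fc.fire_flux_from_temperature(800.0, 300.0) == pytest.approx(
            fc.radiant_exchange(300.0, 800.0))


class TestHeightProfile:
    def setup_method(self):
        self.profile = fc.HeightProfile(823.0, 285.0, 20.0, shape=-0.0155)
        self.times = np.linspace(0, 100, 11)
        self.shape = np.clip(np.sin(np.linspace(0, np.pi, 11)), 0, 1)

    def test_ground_unchanged(self):
        s = fc.height_interpolated_flux(self.profile, 0.0, self.times,
                                        self.shape, ambient=285.0)
        peak = fc.fire_flux_from_temperature(823.0, 285.0)
        assert s.flux.max() == pytest.approx(peak * self.shape.max())

    def test_twenty_meter_scale_factor(self):
        assert self.profile.scale(20.0) == pytest.approx(np.exp(-0.31))
        assert self.profile.scale(20.0) == pytest.approx(0.7334, rel=1e-3)

    def test_flux_non_increasing_with_height(self):
        peaks = [fc.height_interpolated_flux(self.profile, z, self.times,
                                             self.shape, 285.0).flux.max()
                 for z in (0.0, 5.0, 10.0, 20.0)]
        assert np.all(np.diff(peaks) < 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            self.profile.scale(25.0)


class TestCircumferentialDistribution:
    def test_uniform_case(self):
        m = fc.circumferential_distribution(2, 16)
        np.testing.assert_allclose(m, 1.0)

    @pytest.mark.parametrize("case", [1, 2, 3, 4, 5])
    def test_dose_conservation(self, case):
        m = fc.circumferential_distribution(case, 32)
        assert m.mean() == pytest.approx(1.0, rel=1e-12)
        assert np.all(m >= 0)

    def test_case3_octant_fractions(self):
        m = fc.circumferential_distribution(3, 16)
        # front & lee quadrants carry 3/8 of the dose each -> multiplier 1.5
        assert m[0] == pytest.approx(1.5)    # front (upper right)
        assert m[8] == pytest.approx(1.5)    # lee (lower left)
        assert m[4] == pytest.approx(0.5)
        assert m[12] == pytest.approx(0.5)

    def test_case4_lee_to_front_ratio(self):
        m = fc.circumferential_distribution(4, 16)
        front, lee = m[0], m[8]
        assert lee / front == pytest.approx(2.0)
        assert m[4] == 0.0 and m[12] == 0.0

    def test_case1_heats_half_circumference(self):
        m = fc.circumferential_distribution(1, 16)
        assert (m > 0).sum() == 8
        np.testing.assert_allclose(m[m > 0], 2.0)

    def test_unknown_case_rejected(self):
        with pytest.raises(ValueError):
            fc.circumferential_distribution(6, 16)

    def test_indivisible_wedge_count_rejected(self):
        with pytest.raises(ValueError):
            fc.circumferential_distribution(2, 12)

    @pytest.mark.parametrize("case", [1, 2, 3, 4, 5])
    def test_dose_invariance_on_series(self, case, pulse):
        m = fc.circumferential_distribution(case, 16)
        scaled = pulse.scaled(m)
        base = pulse.total_dose(16)
        assert scaled.total_dose(16) == pytest.approx(base, rel=1e-10)


class TestSyntheticPulse:
    def test_zero_peak(self):
        s = fc.synthetic_lab_pulse(0.0, 10.0, 50.0, 100.0)
        assert np.all(s.flux == 0.0)

    def test_step_onset(self):
        s = fc.synthetic_lab_pulse(1e4, 0.0, 50.0, 100.0)
        assert s.flux[0, 0] == 1e4

    def test_integral_matches_closed_form(self):
        peak, ramp, hold, cool = 2.5e4, 60.0, 300.0, 600.0
        s = fc.synthetic_lab_pulse(peak, ramp, hold, cool, dt=0.25)
        numeric = np.trapezoid(s.flux[:, 0], s.times)
        analytic = fc.pulse_integral(peak, ramp, hold, cool)
        assert numeric == pytest.approx(analytic, rel=2e-3)

    def test_deterministic(self):
        a = fc.synthetic_lab_pulse(1e4, 30.0, 60.0, 90.0)
        b = fc.synthetic_lab_pulse(1e4, 30.0, 60.0, 90.0)
        np.testing.assert_array_equal(a.flux, b.flux)


class TestForcingCsv:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        times = np.sort(rng.uniform(0, 1000, 40))
        times += np.arange(40) * 1e-3  # strictly increasing
        flux = rng.uniform(0, 5e4, (40, 3))
        s = fc.ForcingSeries(times, flux, ambient=293.0)
        path = tmp_path / "f.csv"
        fc.write_forcing_csv(s, path)
        back = fc.read_forcing_csv(path)
        np.testing.assert_allclose(back.times, s.times, rtol=1e-12)
        np.testing.assert_allclose(back.flux, s.flux, rtol=1e-12)
        assert back.ambient_at(0.0) == pytest.approx(293.0)

    def test_single_column_broadcast(self, pulse):
        q = pulse.flux_at(100.0, 16)
        assert q.shape == (16,)
        assert np.all(q == q[0])

    def test_missing_ambient_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,flux_W_m2\n0,0\n1,10\n")
        with pytest.raises(ValueError, match="T_ambient_K"):
            fc.read_forcing_csv(path)

    def test_non_monotone_time_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,T_ambient_K,flux_W_m2\n0,300,0\n2,300,1\n1,300,2\n")
        with pytest.raises(ValueError, match="row 3"):
            fc.read_forcing_csv(path)

    def test_negative_flux_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fc.ForcingSeries(np.array([0.0, 1.0]), np.array([[0.0], [-1.0]]))

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_property(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 30)
        times = np.cumsum(rng.uniform(0.1, 10.0, n))
        flux = rng.uniform(0, 1e5, (n, 1))
        s = fc.ForcingSeries(times, flux, ambient=float(rng.uniform(270, 320)))
        path = tmp_path_factory.mktemp("rt") / "f.csv"
        fc.write_forcing_csv(s, path)
        back = fc.read_forcing_csv(path)
        np.testing.assert_allclose(back.flux, s.flux, rtol=1e-12)


class TestHeightSpreadsheet:
    def test_import_per_height(self, tmp_path):
        import pandas as pd
        rows = []
        for z in (0.0, 10.0):
            for t in (0.0, 60.0, 120.0):
                rows.append({"time_s": t, "height_m": z, "T_ambient_K": 285.0,
                             "T_fire_K": 285.0 + (t == 60.0) * 400.0 * np.exp(-0.05 * z)})
        path = tmp_path / "heights.xlsx"
        pd.DataFrame(rows).to_excel(path, index=False)
        series = fc.read_height_spreadsheet(path)
        assert set(series) == {0.0, 10.0}
        assert series[0.0].flux.max() > series[10.0].flux.max()

    def test_missing_columns_rejected(self, tmp_path):
        import pandas as pd
        path = tmp_path / "bad.xlsx"
        pd.DataFrame({"time_s": [0, 1]}).to_excel(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            fc.read_height_spreadsheet(path)
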