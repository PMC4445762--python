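"""Reaction–diffusion core: logistic limit, conservation, wave speed,
radius extraction, stability contracts."""

import math

import numpy as np
import pytest

from gliomapi import (
    InvalidFieldError,
    Kinetics,
    RadialField,
    SolverSettings,
    UnstableSettingsError,
    extract_radius,
    front_profile,
    gaussian_bolus,
    logistic_reference,
    simulate,
    total_cells,
    wavefront_speed,
)

K = 1e5


def uniform_field(settings, level, K=K):
    grid = settings.grid()
    return RadialField(grid, np.full(grid.size, level), 0.0, K)


class TestLogistic:
    @pytest.mark.parametrize("c0,expected_frac", [(0.0, 0.0), (K, 1.0)])
    def test_fixed_points(self, c0, expected_frac):
        kin = Kinetics(D=1.0, rho=10.0, K=K)
        assert logistic_reference(c0, kin, 500.0) == pytest.approx(expected_frac * K)

    def test_half_capacity_triples_to_three_quarters(self):
        # c0 = K/2 and e^{rho t} = 3 gives c = 0.75 K in closed form
        kin = Kinetics(D=1.0, rho=16.0, K=K)
        t = math.log(3) / kin.rho_day
        assert logistic_reference(0.5 * K, kin, t) == pytest.approx(0.75 * K, rel=1e-12)

    def test_rejects_supercapacity_start(self):
        kin = Kinetics(D=1.0, rho=10.0, K=K)
        with pytest.raises(ValueError):
            logistic_reference(1.5 * K, kin, 1.0)

    def test_diffusion_free_simulation_matches_closed_form(self):
        # D -> 0: every node follows the logistic ODE exactly (rtol 1e-5)
        kin = Kinetics(D=1e-10, rho=16.0, K=K)
        st = SolverSettings(dr=0.5, dt=0.25, r_max=20.0)
        t = 100 * st.dt
        f0 = uniform_field(st, 0.5 * K)
        snap = simulate(kin, f0, t, st)[-1]
        expected = logistic_reference(0.5 * K, kin, t)
        np.testing.assert_allclose(snap.density, expected, rtol=1e-5)


class TestConservation:
    def test_pure_diffusion_conserves_mass(self):
        # rho -> 0 with zero-flux boundaries: total cells constant to 1e-6
        kin = Kinetics(D=25.0, rho=1e-12, K=K)
        st = SolverSettings(dr=0.25, dt=0.5, r_max=40.0)
        f0 = gaussian_bolus(kin, st, width=3.0)
        m0 = total_cells(f0)
        snap = simulate(kin, f0, 100 * st.dt, st)[-1]
        assert abs(total_cells(snap) - m0) / m0 < 1e-6

    def test_explicit_scheme_conserves_too(self):
        kin = Kinetics(D=5.0, rho=1e-12, K=K)
        dr = 0.5
        dt_ok = dr * dr / (6.0 * kin.D_day) * 0.9
        st = SolverSettings(dr=dr, dt=dt_ok, r_max=30.0, scheme="explicit")
        f0 = gaussian_bolus(kin, st, width=3.0)
        m0 = total_cells(f0)
        snap = simulate(kin, f0, 100 * dt_ok, st)[-1]
        assert abs(total_cells(snap) - m0) / m0 < 1e-6


class TestStabilityAndBounds:
    def test_explicit_overlong_step_rejected_before_stepping(self):
        kin = Kinetics(D=25.0, rho=10.0, K=K)
        st = SolverSettings(dr=0.2, dt=5.0, r_max=30.0, scheme="explicit")
        f0 = gaussian_bolus(kin, st)
        with pytest.raises(UnstableSettingsError):
            simulate(kin, f0, 10.0, st)

    def test_initial_density_above_capacity_rejected(self):
        kin = Kinetics(D=5.0, rho=5.0, K=K)
        st = SolverSettings(dr=0.5, dt=0.5, r_max=20.0)
        grid = st.grid()
        bad = RadialField(grid, np.full(grid.size, 1.2 * K), 0.0, 1.2 * K)
        with pytest.raises(InvalidFieldError):
            simulate(kin, bad, 10.0, st)

    @pytest.mark.parametrize("seed", range(4))
    def test_density_stays_within_saturation_bounds(self, seed):
        rng = np.random.default_rng(seed)
        kin = Kinetics(D=float(rng.uniform(2, 50)), rho=float(rng.uniform(2, 30)), K=K)
        st = SolverSettings.auto(kin, r_max=40.0)
        grid = st.grid()
        f0 = RadialField(grid, rng.uniform(0, K, grid.size), 0.0, K)
        for snap in simulate(kin, f0, 60.0, st, snapshot_times=[10, 30, 60]):
            assert snap.density.min() >= 0.0
            assert snap.density.max() <= K

    def test_field_invariants_enforced(self):
        with pytest.raises(InvalidFieldError):
            RadialField(np.array([1.0, 2.0, 3.0]), np.zeros(3), 0.0, K)  # grid[0] != 0
        with pytest.raises(InvalidFieldError):
            RadialField(np.array([0.0, 2.0, 1.0]), np.zeros(3), 0.0, K)  # not increasing


class TestExtractRadius:
    def test_step_profile(self):
        st = SolverSettings(dr=0.1, dt=1.0, r_max=30.0)
        grid = st.grid()
        c = np.where(grid <= 10.0, K, 0.0)
        f = RadialField(grid, c, 0.0, K)
        assert extract_radius(f, 0.8) == pytest.approx(10.0, abs=st.dr)

    def test_exponential_profile_closed_form(self):
        # c/K = exp(-r/2): crossing of e^{-1} sits at r = 2
        st = SolverSettings(dr=0.05, dt=1.0, r_max=30.0)
        grid = st.grid()
        f = RadialField(grid, K * np.exp(-grid / 2.0), 0.0, K)
        assert extract_radius(f, math.exp(-1)) == pytest.approx(2.0, abs=1e-3)

    def test_empty_tumor_returns_zero(self):
        st = SolverSettings(dr=0.5, dt=1.0, r_max=20.0)
        f = RadialField(st.grid(), np.zeros(st.grid().size), 0.0, K)
        assert extract_radius(f, 0.5) == 0.0

    def test_outermost_crossing_wins_on_multimodal_profile(self):
        st = SolverSettings(dr=0.1, dt=1.0, r_max=30.0)
        grid = st.grid()
        c = K * (np.exp(-((grid - 5) ** 2)) + 0.9 * np.exp(-((grid - 15) ** 2)))
        f = RadialField(grid, np.clip(c, 0, K), 0.0, K)
        assert extract_radius(f, 0.5) > 15.0

    def test_threshold_domain_checked(self):
        st = SolverSettings(dr=0.5, dt=1.0, r_max=20.0)
        f = RadialField(st.grid(), np.zeros(st.grid().size), 0.0, K)
        with pytest.raises(ValueError):
            extract_radius(f, 1.5)


class TestWavefrontSpeed:
    @staticmethod
    def step_field(radius, st, t):
        grid = st.grid()
        return RadialField(grid, np.where(grid <= radius, K, 0.0), t, K)

    def test_exact_line_recovered(self):
        st = SolverSettings(dr=0.05, dt=1.0, r_max=50.0)
        snaps = [self.step_field(10 + 20 * y, st, y * 365.25) for y in (0, 0.5, 1.0)]
        assert wavefront_speed(snaps, 0.5) == pytest.approx(20.0, rel=1e-3)

    def test_boundary_contamination_rejected(self):
        st = SolverSettings(dr=0.5, dt=1.0, r_max=30.0)
        snaps = [self.step_field(r, st, i * 100.0) for i, r in enumerate((10, 20, 29.9))]
        with pytest.raises(ValueError):
            wavefront_speed(snaps, 0.5)

    def test_front_speed_matches_fisher_kpp_prediction(self, kin_fast):
        # v = 2 sqrt(D rho) = 40 mm/yr for D=25, rho=16
        st = SolverSettings.auto(kin_fast, r_max=140.0)
        f0 = gaussian_bolus(kin_fast, st, width=2.0)
        times = np.linspace(600, 1000, 9)
        snaps = simulate(kin_fast, f0, 1000.0, st, snapshot_times=list(times))
        assert wavefront_speed(snaps, 0.5) == pytest.approx(40.0, rel=0.05)

    def test_speed_depends_only_on_product_D_rho(self):
        # same D*rho, different ratio: same speed (planar, wave-matched start)
        for D, rho in [(100.0, 4.0), (25.0, 16.0)]:
            kin = Kinetics(D=D, rho=rho, K=K)
            st = SolverSettings.auto(kin, r_max=100.0)
            f0 = front_profile(kin, st, 15.0, 0.5)
            times = np.linspace(300, 600, 7)
            snaps = simulate(kin, f0, 600.0, st, snapshot_times=list(times),
                             geometry="planar")
            assert wavefront_speed(snaps, 0.5) == pytest.approx(40.0, rel=0.05)

    def test_joint_rate_scaling_scales_speed(self):
        # (aD, a rho) multiplies the front speed by a
        speeds = {}
        for a in (1.0, 2.0):
            kin = Kinetics(D=10.0 * a, rho=10.0 * a, K=K)
            st = SolverSettings.auto(kin, r_max=80.0)
            f0 = front_profile(kin, st, 10.0, 0.5)
            times = np.linspace(200, 400, 5)
            snaps = simulate(kin, f0, 400.0, st, snapshot_times=list(times),
                             geometry="planar")
            speeds[a] = wavefront_speed(snaps, 0.5)
        assert speeds[2.0] / speeds[1.0] == pytest.approx(2.0, rel=0.03)


class TestKinetics:
    def test_derived_quantities(self):
        kin = Kinetics(D=40.0, rho=10.0, K=K)
        assert kin.velocity == pytest.approx(40.0)
        assert kin.gradient_length == pytest.approx(2.0)
        assert kin.rho_over_D == pytest.approx(0.25)

    @pytest.mark.parametrize("bad", [dict(D=0), dict(rho=-1), dict(K=0)])
    def test_invalid_parameters_rejected(self, bad):
        params = dict(D=10.0, rho=10.0, K=K)
        params.update(bad)
        with pytest.raises(ValueError):
            Kinetics(**params)
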