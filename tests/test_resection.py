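"""Resection, removal margins, and fatal-size survival surrogates."""

import numpy as np
import pytest
from scipy.integrate import quad

from gliomapi import (
    GliomaPIError,
    Kinetics,
    RadialField,
    SolverSettings,
    apply_resection,
    extract_radius,
    front_profile,
    margin_for_fraction_removed,
    resolve_margin,
    simulate,
    time_to_fatal_radius,
    total_cells,
    wavefront_speed,
)
from gliomapi.resection import ResectionEvent

K = 1e5


def ball_field(radius=10.0, dr=0.05, r_max=30.0):
    st = SolverSettings(dr=dr, dt=1.0, r_max=r_max)
    g = st.grid()
    return RadialField(g, np.where(g <= radius, K, 0.0), 0.0, K)


class TestApplyResection:
    def test_biopsy_changes_nothing(self, developed_lesion):
        ev = resolve_margin(developed_lesion, "biopsy")
        out, removed = apply_resection(developed_lesion, ev)
        assert removed == 0.0
        np.testing.assert_array_equal(out.density, developed_lesion.density)

    def test_margin_beyond_tumor_removes_everything(self, developed_lesion):
        ev = ResectionEvent(0.0, "STR", developed_lesion.r_max - 0.5)
        out, removed = apply_resection(developed_lesion, ev)
        # linear-interpolant integral vs finite-volume sum: O(dr^2) apart
        assert removed == pytest.approx(total_cells(developed_lesion), rel=5e-3)

    def test_removed_count_matches_quadrature_oracle(self, kin_mid, settings_mid,
                                                     developed_lesion):
        ev = resolve_margin(developed_lesion, "GTR")
        _, removed = apply_resection(developed_lesion, ev)
        grid, dens = developed_lesion.grid, developed_lesion.density

        def integrand(r):
            return 4.0 * np.pi * r * r * np.interp(r, grid, dens)

        oracle, _ = quad(integrand, 0.0, ev.margin_radius, limit=400)
        assert removed == pytest.approx(oracle, rel=1e-4)

    def test_extent_margins_ordered(self, developed_lesion):
        gtr = resolve_margin(developed_lesion, "GTR")
        strv = resolve_margin(developed_lesion, "STR")
        assert gtr.margin_radius == pytest.approx(15.0, abs=0.5)
        assert 0 < strv.margin_radius < gtr.margin_radius

    def test_tail_untouched(self, developed_lesion):
        ev = resolve_margin(developed_lesion, "GTR")
        out, _ = apply_resection(developed_lesion, ev)
        outside = developed_lesion.grid > ev.margin_radius
        np.testing.assert_array_equal(out.density[outside],
                                      developed_lesion.density[outside])

    def test_residual_floor(self, developed_lesion):
        ev = resolve_margin(developed_lesion, "GTR")
        out, _ = apply_resection(developed_lesion, ev, residual_fraction=0.1)
        inside = developed_lesion.grid <= ev.margin_radius
        np.testing.assert_allclose(out.density[inside],
                                   0.1 * developed_lesion.density[inside])


class TestMarginForFractionRemoved:
    def test_uniform_ball_closed_form(self):
        # 99% of a uniform ball of radius 10 sits within 0.99^(1/3) * 10 mm
        f = ball_field()
        assert margin_for_fraction_removed(f, 0.99) == \
            pytest.approx(0.99 ** (1 / 3) * 10.0, abs=0.06)

    def test_limit_approaches_outermost_cells(self):
        f = ball_field()
        assert margin_for_fraction_removed(f, 0.999999) == pytest.approx(10.0, abs=0.1)

    def test_invalid_fraction_rejected(self):
        f = ball_field()
        for bad in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                margin_for_fraction_removed(f, bad)

    def test_empty_field_rejected(self):
        st = SolverSettings(dr=0.5, dt=1.0, r_max=20.0)
        f = RadialField(st.grid(), np.zeros(st.grid().size), 0.0, K)
        with pytest.raises(GliomaPIError):
            margin_for_fraction_removed(f, 0.5)

    def test_nodular_tumor_has_tighter_99_margin_than_diffuse(self):
        """The iceberg contrast: at equal T1Gd radius, the 99%-removal margin
        hugs the visible lesion for nodular tumors and extends far beyond it
        for diffuse ones."""
        gaps = {}
        for name, (D, rho) in {"nodular": (5.0, 20.0), "diffuse": (20.0, 5.0)}.items():
            kin = Kinetics(D=D, rho=rho, K=K)
            st = SolverSettings.auto(kin, r_max=70.0)
            f = front_profile(kin, st, 15.0, 0.8)
            gaps[name] = margin_for_fraction_removed(f, 0.99) - extract_radius(f, 0.8)
        assert gaps["nodular"] < gaps["diffuse"]


class TestTimeToFatal:
    def test_linear_regime_line_inversion(self):
        # r0 = 20 mm, v = 40 mm/yr, fatal at 30 mm: 10 mm / v = 91.3 d
        # (narrow front, lambda = 1 mm, so curvature drag stays within 5%)
        kin = Kinetics(D=20.0, rho=20.0, K=K)
        st = SolverSettings.auto(kin, r_max=70.0)
        f0 = front_profile(kin, st, 20.0, 0.8)
        surr = time_to_fatal_radius(kin, f0, fatal_radius=30.0, settings=st)
        assert not surr.censored
        assert surr.time_to_fatal == pytest.approx(91.3, rel=0.05)

    def test_already_fatal_flagged(self, kin_mid, settings_mid):
        f0 = front_profile(kin_mid, settings_mid, 20.0, 0.8)
        surr = time_to_fatal_radius(kin_mid, f0, fatal_radius=18.0,
                                    settings=settings_mid)
        assert surr.time_to_fatal == 0.0
        assert surr.already_fatal

    def test_slow_tumor_censored_at_horizon(self):
        kin = Kinetics(D=0.5, rho=0.5, K=K)  # v = 1 mm/yr
        st = SolverSettings.auto(kin, r_max=60.0)
        f0 = front_profile(kin, st, 15.0, 0.8)
        surr = time_to_fatal_radius(kin, f0, fatal_radius=35.0, settings=st,
                                    horizon=365.0)
        assert surr.censored
        assert surr.time_to_fatal == 365.0

    def test_resection_never_shortens_survival(self, kin_mid, settings_mid,
                                               developed_lesion):
        base = time_to_fatal_radius(kin_mid, developed_lesion,
                                    settings=settings_mid).time_to_fatal
        for extent in ("STR", "GTR"):
            ev = resolve_margin(developed_lesion, extent)
            t = time_to_fatal_radius(kin_mid, developed_lesion,
                                     settings=settings_mid,
                                     resection=ev).time_to_fatal
            assert t >= base - 1e-6

    def test_benefit_monotone_in_margin(self, kin_mid, settings_mid,
                                        developed_lesion):
        times = []
        for margin in (0.0, 8.0, 15.0):
            ev = ResectionEvent(0.0, "STR", margin) if margin else \
                ResectionEvent(0.0, "biopsy", 0.0)
            times.append(time_to_fatal_radius(
                kin_mid, developed_lesion, settings=settings_mid,
                resection=ev).time_to_fatal)
        assert times[0] <= times[1] + 1e-9 <= times[2] + 2e-9

    def test_front_regrows_at_model_speed_after_resection(self, kin_mid):
        st = SolverSettings.auto(kin_mid, r_max=80.0)
        f0 = front_profile(kin_mid, st, 15.0, 0.8)
        ev = resolve_margin(f0, "GTR")
        post, _ = apply_resection(f0, ev)
        times = np.linspace(200, 500, 7)
        snaps = simulate(kin_mid, post, 500.0, st, snapshot_times=list(times))
        v = wavefront_speed(snaps, 0.5)
        assert v == pytest.approx(kin_mid.velocity, rel=0.08)


class TestIcebergFraction:
    def test_removed_fraction_increases_with_aggressiveness_ratio(self):
        """Fixed 15 mm T1Gd lesion: the more nodular (higher rho/D), the
        larger the share of all tumor cells the visible lesion contains."""
        fracs = []
        for D, rho in [(30.0, 3.0), (15.0, 7.5), (7.5, 15.0), (3.0, 30.0)]:
            kin = Kinetics(D=D, rho=rho, K=K)
            st = SolverSettings.auto(kin, r_max=70.0)
            f = front_profile(kin, st, 15.0, 0.8)
            ev = resolve_margin(f, "GTR")
            _, removed = apply_resection(f, ev)
            fracs.append(removed / total_cells(f))
        assert all(a < b for a, b in zip(fracs, fracs[1:]))
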