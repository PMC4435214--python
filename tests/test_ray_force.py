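import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from acoustrap.beam_analysis import BeamModel
from acoustrap.core_types import Medium, Particle
from acoustrap.ray_force import (
    RayForceError,
    axial_sweep,
    force_profile,
    fresnel_coefficients,
    integrate_force,
    lateral_sweep,
    q_factors,
    ray_geometry,
    snell_refraction,
    trapping_summary,
    ForceProfile,
)

MEDIUM = Medium()
LIPID = Particle(radius=120e-6, impedance=1.4e6)  # tabulated lipid impedance


class TestSnell:
    @pytest.mark.parametrize(
        "theta_i, c1, c2, expected_deg",
        [
            (0.0, 1500.0, 1450.0, 0.0),
            (math.radians(30), 1500.0, 1500.0, 30.0),
            (math.radians(30), 1500.0, 1450.0, 28.9033),
        ],
    )
    def test_refraction_angles(self, theta_i, c1, c2, expected_deg):
        theta_r, tir = snell_refraction(theta_i, c1, c2)
        assert not np.any(tir)
        assert math.degrees(float(theta_r)) == pytest.approx(
            expected_deg, abs=1e-3
        )

    def test_total_internal_reflection_flagged_for_fast_particle(self):
        theta_r, tir = snell_refraction(math.radians(80), 1500.0, 3000.0)
        assert bool(tir)


class TestFresnel:
    def test_printed_amplitude_quotient_at_normal_incidence(self):
        R, T = fresnel_coefficients(0.0, 0.0, 1.5e6, 1.4e6,
                                    convention="amplitude")
        assert float(R) == pytest.approx(0.1 / 2.9, rel=1e-12)
        assert float(T) == pytest.approx(1 - 0.1 / 2.9, rel=1e-12)

    def test_power_reflectance_is_squared_amplitude_at_normal_incidence(self):
        R, _ = fresnel_coefficients(0.0, 0.0, 1.5e6, 1.4e6)
        assert float(R) == pytest.approx((0.1 / 2.9) ** 2, rel=1e-12)

    def test_matched_interface_reflects_nothing(self):
        for conv in ("power", "amplitude"):
            R, T = fresnel_coefficients(0.3, 0.3, 1.5e6, 1.5e6,
                                        convention=conv)
            assert float(R) == pytest.approx(0.0, abs=1e-15)
            assert float(T) == pytest.approx(1.0)

    def test_grazing_incidence_is_total_reflection(self):
        R, T = fresnel_coefficients(math.pi / 2, 0.5, 1.5e6, 1.4e6)
        assert float(R) == 1.0 and float(T) == 0.0

    @given(
        theta_i=st.floats(0.0, math.radians(89.0)),
        z2=st.floats(0.5e6, 3e6),
        conv=st.sampled_from(["power", "amplitude"]),
    )
    def test_reflectance_bounded_and_complementary(self, theta_i, z2, conv):
        theta_r, tir = snell_refraction(theta_i, 1500.0, 1450.0)
        R, T = fresnel_coefficients(theta_i, theta_r, 1.5e6, z2, tir,
                                    convention=conv)
        assert 0.0 <= float(R) <= 1.0
        assert float(R) + float(T) == pytest.approx(1.0)


class TestQFactors:
    def test_mirror_limit_transfers_double_momentum(self):
        qs, qg = q_factors(0.0, 0.0, R=1.0, T=0.0)
        assert float(qs) == pytest.approx(2.0)
        assert float(qg) == pytest.approx(0.0)

    def test_transparent_matched_particle_is_force_free(self):
        qs, qg = q_factors(0.4, 0.4, R=0.0, T=1.0)
        assert float(qs) == pytest.approx(0.0, abs=1e-15)
        assert float(qg) == pytest.approx(0.0, abs=1e-15)

    def test_against_independent_symbolic_evaluation(self):
        """Cross-check the closed forms with a sympy evaluation at 30 deg."""
        import sympy as sp

        ti = sp.rad(30)
        tr = sp.asin(sp.Rational(1450, 1500) * sp.sin(ti))
        Z1, Z2 = sp.Rational(15, 10), sp.Rational(14, 10)
        r = (Z2 / sp.cos(tr) - Z1 / sp.cos(ti)) / (
            Z2 / sp.cos(tr) + Z1 / sp.cos(ti)
        )
        R = r**2
        T = 1 - R
        D = 1 + R**2 + 2 * R * sp.cos(2 * tr)
        qs_sym = (
            1 + R * sp.cos(2 * ti)
            - T**2 * (sp.cos(2 * ti - 2 * tr) + R * sp.cos(2 * ti)) / D
        )
        qg_sym = (
            R * sp.sin(2 * ti)
            - T**2 * (sp.sin(2 * ti - 2 * tr) + R * sp.sin(2 * ti)) / D
        )
        theta_i = math.radians(30)
        theta_r, tir = snell_refraction(theta_i, 1500.0, 1450.0)
        Rn, Tn = fresnel_coefficients(theta_i, theta_r, 1.5e6, 1.4e6, tir)
        qs, qg = q_factors(theta_i, theta_r, Rn, Tn)
        assert float(qs) == pytest.approx(float(qs_sym.evalf(30)), rel=1e-10)
        assert float(qg) == pytest.approx(float(qg_sym.evalf(30)), rel=1e-10)


class TestRayGeometry:
    BEAM = BeamModel([0, 0, 0], waist=22e-6, wavelength=30e-6,
                     peak_intensity=150e4)

    def test_on_axis_ray_is_axis_parallel(self):
        geo = ray_geometry((100e-6, 0.0), self.BEAM)
        assert geo.s_hat == pytest.approx((1.0, 0.0))
        assert geo.g_hat == pytest.approx((0.0, -1.0))

    def test_plane_wave_limit_for_wide_beams(self):
        wide = BeamModel([0, 0, 0], waist=1e-2, wavelength=30e-6,
                         peak_intensity=150e4)
        geo = ray_geometry((100e-6, 50e-6), wide)
        assert geo.s_hat[0] == pytest.approx(1.0, abs=1e-6)

    @given(
        qz=st.floats(-500e-6, 500e-6),
        qy=st.floats(-80e-6, 80e-6),
    )
    def test_unit_vectors_are_orthonormal(self, qz, qy):
        geo = ray_geometry((qz, qy), self.BEAM)
        s, g = np.array(geo.s_hat), np.array(geo.g_hat)
        if not np.all(np.isfinite(s)):
            return
        assert np.linalg.norm(s) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(g) == pytest.approx(1.0, abs=1e-12)
        assert abs(s @ g) < 1e-12

    def test_entry_beyond_the_wavefront_is_rejected(self):
        zr = self.BEAM.rayleigh_range
        with pytest.raises(RayForceError):
            ray_geometry((zr, 3 * zr), self.BEAM)


class TestIntegrateForce:
    @pytest.mark.parametrize("mode", ["as-printed-2d", "surface-3d"])
    def test_on_axis_sphere_feels_no_lateral_force(self, fitted_beam_like, mode):
        d = integrate_force([0, 0, 300e-6], LIPID, fitted_beam_like, MEDIUM,
                            mode=mode, n_theta=200, n_phi=72)
        # compare against the (uncancelled) component scale
        assert abs(d.force_y) < 1e-13 * max(abs(d.f_sz), abs(d.f_gz))

    @pytest.mark.parametrize("mode", ["as-printed-2d", "surface-3d"])
    def test_acoustically_invisible_particle_feels_nothing(
        self, fitted_beam_like, mode
    ):
        ghost = Particle(radius=120e-6, density=1000.0, sound_speed=1500.0)
        d = integrate_force([0, 30e-6, 300e-6], ghost, fitted_beam_like,
                            MEDIUM, mode=mode, n_theta=200, n_phi=72)
        assert abs(d.force_z) < 1e-20  # machine-level zero
        assert abs(d.force_y) < 1e-20

    def test_force_scales_linearly_with_peak_intensity(self, fitted_beam_like):
        bright = BeamModel(
            fitted_beam_like.focus, fitted_beam_like.waist,
            fitted_beam_like.wavelength,
            2 * fitted_beam_like.peak_intensity,
        )
        d1 = integrate_force([0, 20e-6, 400e-6], LIPID, fitted_beam_like,
                             MEDIUM, n_theta=300)
        d2 = integrate_force([0, 20e-6, 400e-6], LIPID, bright, MEDIUM,
                             n_theta=300)
        assert d2.force_z == pytest.approx(2 * d1.force_z, rel=1e-9)
        assert d2.force_y == pytest.approx(2 * d1.force_y, rel=1e-9)

    @pytest.mark.parametrize("mode", ["as-printed-2d", "surface-3d"])
    def test_quadrature_converged_at_default_resolution(
        self, fitted_beam_like, mode
    ):
        with warnings.catch_warnings():
            warnings.simplefilter("error", RuntimeWarning)
            integrate_force([0, 10e-6, 341e-6], LIPID, fitted_beam_like,
                            MEDIUM, mode=mode, check_convergence=True)


class TestSweepsAndSummary:
    def test_axial_sweep_shows_push_then_pull(self, fitted_beam_like):
        z = np.arange(-0.2e-3, 1.2e-3, 10e-6)
        prof = force_profile(axial_sweep(z), LIPID, fitted_beam_like, MEDIUM,
                             sweep_axis="z")
        fz = prof.force_z
        assert fz[np.argmin(np.abs(z))] > 0  # pushed forward near the focus
        assert fz.min() < 0  # pulled back farther out
        # scattering pushes, gradient carries the restoring force
        assert np.all(prof.f_sz >= -1e-16)
        i_min = np.argmin(fz)
        assert prof.f_gz[i_min] < 0

    def test_lateral_force_is_restoring_and_gradient_dominated(
        self, fitted_beam_like
    ):
        y = np.arange(-0.3e-3, 0.35e-3, 10e-6)
        prof = force_profile(lateral_sweep(y, 240e-6), LIPID,
                             fitted_beam_like, MEDIUM, sweep_axis="y")
        fy = prof.force_y
        assert np.all(fy[y > 1e-9] <= 1e-16)
        assert np.all(fy[y < -1e-9] >= -1e-16)
        assert np.abs(prof.f_sy).max() < 0.05 * np.abs(prof.f_gy).max()

    def test_non_monotone_sweep_rejected(self, fitted_beam_like):
        centers = axial_sweep(np.array([0.0, 2e-4, 1e-4]))
        with pytest.raises(ValueError):
            force_profile(centers, LIPID, fitted_beam_like, MEDIUM)

    def test_summary_of_closed_form_sine_profile(self):
        a = 400e-6
        z = np.linspace(-a / 2, 1.5 * a, 801)
        force = np.where((z > 0) & (z < a), -np.sin(np.pi * z / a), 0.0)
        zeros = np.zeros_like(z)
        prof = ForceProfile(
            positions=np.column_stack([zeros, zeros, z]),
            sweep_axis="z",
            f_sz=zeros, f_gz=force, f_sy=zeros, f_gy=zeros,
        )
        s = trapping_summary(prof)
        assert s.trapped
        assert s.trapping_region == pytest.approx(a, rel=1e-2)
        assert s.trapping_position == pytest.approx(a / 2, abs=1e-6)
        assert s.max_trapping_force == pytest.approx(-1.0, rel=1e-3)
        assert s.balanced_position == pytest.approx(0.0, abs=1e-6)

    def test_all_positive_profile_reports_no_trap(self):
        z = np.linspace(0, 1e-3, 101)
        zeros = np.zeros_like(z)
        prof = ForceProfile(
            positions=np.column_stack([zeros, zeros, z]),
            sweep_axis="z",
            f_sz=np.full_like(z, 1e-10), f_gz=zeros, f_sy=zeros, f_gy=zeros,
        )
        s = trapping_summary(prof)
        assert not s.trapped
        assert s.trapping_region == 0.0
        assert s.balanced_position is None
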