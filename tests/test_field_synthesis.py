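import numpy as np
import pytest

from acoustrap.core_types import ArrayGeometry, ConfigurationError, Medium, WaveParams
from acoustrap.field_synthesis import (
    ControlPointSet,
    ExcitationVector,
    FieldGrid,
    FieldSynthesisError,
    build_propagation_matrix,
    compute_intensity,
    compute_pressure_at,
    compute_pressure_field,
    normalize_to_source_power,
    solve_excitation,
    solve_excitation_weighted,
    source_plane_power,
)

MEDIUM = Medium()
SINGLE = ArrayGeometry(n_elements_x=1, n_elements_y=1, pitch=22e-6, kerf=0.0)
WAVE = WaveParams.from_medium(SINGLE, MEDIUM)


def _single_element_H(n_sub, z=670e-6):
    points = ControlPointSet(np.array([[0.0, 0.0, z]]), np.array([1.0 + 0j]))
    return build_propagation_matrix(SINGLE, WAVE, MEDIUM, points, n_sub=n_sub)


class TestPropagationMatrix:
    def test_single_element_matches_dense_quadrature_oracle(self):
        """Midpoint 4x4 quadrature vs a 10x denser independent evaluation."""
        coarse = _single_element_H(4).entries[0, 0]
        oracle = _single_element_H(40).entries[0, 0]
        assert abs(coarse) == pytest.approx(abs(oracle), rel=5e-3)
        assert np.angle(coarse) == pytest.approx(np.angle(oracle), abs=5e-3)

    def test_on_axis_piston_curve_matches_oracle_everywhere(self):
        from acoustrap.fixtures import piston_on_axis

        curve = piston_on_axis(z=np.linspace(100e-6, 2000e-6, 48))
        np.testing.assert_allclose(
            np.abs(curve.pressure), np.abs(curve.pressure_oracle), rtol=5e-3
        )

    def test_mirror_symmetric_points_have_equal_row_magnitudes(self):
        geometry = ArrayGeometry()
        wave = WaveParams.from_medium(geometry, MEDIUM)
        points = ControlPointSet(
            np.array([[0.1e-3, 0.05e-3, 0.67e-3], [-0.1e-3, -0.05e-3, 0.67e-3]]),
            np.ones(2, dtype=complex),
        )
        H = build_propagation_matrix(geometry, wave, MEDIUM, points).entries
        # reflection through the array centre maps element n -> N-1-n
        np.testing.assert_allclose(
            np.abs(H[0]), np.abs(H[1][::-1]), rtol=1e-12
        )

    def test_doubling_subsources_changes_entries_below_tenth_percent(self):
        H4 = _single_element_H(4).entries
        H8 = _single_element_H(8).entries
        assert np.all(np.abs(np.abs(H4) - np.abs(H8)) < 1e-3 * np.abs(H8))

    def test_control_point_behind_array_refused(self):
        with pytest.raises(FieldSynthesisError):
            ControlPointSet(np.array([[0.0, 0.0, -1e-4]]), np.ones(1))

    def test_subsource_spacing_coarser_than_half_wavelength_refused(self):
        # 22 um / 1 = 22 um > lambda/2 = 15 um
        with pytest.raises(FieldSynthesisError):
            _single_element_H(1)


@pytest.fixture(scope="module")
def four_point_system():
    geometry = ArrayGeometry()
    wave = WaveParams.from_medium(geometry, MEDIUM)
    pts = 0.18e-3 * np.array([[1, -1], [-1, 1], [-1, -1], [1, 1]])
    points = ControlPointSet(
        np.column_stack([pts, np.full(4, 0.67e-3)]), np.ones(4, dtype=complex)
    )
    H = build_propagation_matrix(geometry, wave, MEDIUM, points)
    return geometry, wave, points, H


class TestPseudoinverse:
    def test_plain_solution_satisfies_constraints(self, four_point_system):
        *_, H = four_point_system
        u = solve_excitation(H)
        assert u.residual < 1e-10

    def test_rank_one_solution_is_phase_conjugation(self):
        H = _single_element_H(4)
        u = solve_excitation(H)
        row = H.entries[0]
        expected = row.conj() / (row @ row.conj())
        np.testing.assert_allclose(u.values, expected, rtol=1e-12)

    def test_null_target_gives_null_excitation(self, four_point_system):
        geometry, wave, points, H = four_point_system
        silent = ControlPointSet(points.points, np.zeros(4, dtype=complex))
        u = solve_excitation(H, silent)
        assert np.all(u.values == 0)

    def test_duplicated_control_point_reported_as_rank_deficient(self):
        geometry = ArrayGeometry()
        wave = WaveParams.from_medium(geometry, MEDIUM)
        points = ControlPointSet(
            np.array([[0, 0, 0.67e-3], [0, 0, 0.67e-3]]), np.ones(2)
        )
        H = build_propagation_matrix(geometry, wave, MEDIUM, points)
        with pytest.raises(FieldSynthesisError, match="rank"):
            solve_excitation(H)

    def test_weighted_iteration_zero_reproduces_plain_solve(self, four_point_system):
        *_, H = four_point_system
        plain = solve_excitation(H)
        w0 = solve_excitation_weighted(H, max_iter=0)
        np.testing.assert_array_equal(plain.values, w0.values)

    def test_weighted_solution_keeps_constraints_and_flattens_drive(
        self, four_point_system
    ):
        *_, H = four_point_system
        plain = solve_excitation(H)
        weighted = solve_excitation_weighted(H)
        assert weighted.residual < 1e-10
        assert weighted.amplitude_spread <= plain.amplitude_spread
        assert weighted.converged


class TestFieldRendering:
    def test_field_is_linear_in_the_excitation(self):
        H = _single_element_H(4)
        rng = np.random.default_rng(7)
        ua = ExcitationVector(rng.standard_normal(1) + 0j, np.ones(1))
        ub = ExcitationVector(1j * rng.standard_normal(1), np.ones(1))
        uab = ExcitationVector(ua.values + ub.values, np.ones(1))
        pts = np.array([[10e-6, -5e-6, 300e-6], [0, 0, 900e-6]])
        pa = compute_pressure_at(SINGLE, WAVE, MEDIUM, ua, pts)
        pb = compute_pressure_at(SINGLE, WAVE, MEDIUM, ub, pts)
        pab = compute_pressure_at(SINGLE, WAVE, MEDIUM, uab, pts)
        np.testing.assert_allclose(pab, pa + pb, rtol=1e-12)

    def test_single_element_far_field_decays_as_one_over_z(self):
        unit = ExcitationVector(np.ones(1, dtype=complex), np.ones(1))
        z = np.geomspace(0.5e-3, 5e-3, 40)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        p = np.abs(compute_pressure_at(SINGLE, WAVE, MEDIUM, unit, pts))
        slope = np.polyfit(np.log(z), np.log(p), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.02)

    def test_rendered_field_reproduces_constraints_at_control_points(
        self, four_point_system
    ):
        geometry, wave, points, H = four_point_system
        u = solve_excitation_weighted(H)
        p = compute_pressure_at(geometry, wave, MEDIUM, u, points.points)
        np.testing.assert_allclose(p, points.target_pressures, rtol=5e-3)

    def test_point_on_a_source_is_rejected(self):
        unit = ExcitationVector(np.ones(1, dtype=complex), np.ones(1))
        sub_centre = np.array([[2.75e-6, 2.75e-6, 0.0]])  # a 4x4 midpoint
        with pytest.raises(FieldSynthesisError):
            compute_pressure_at(SINGLE, WAVE, MEDIUM, unit, sub_centre)

    def test_grid_must_be_monotone_and_forward(self):
        unit = ExcitationVector(np.ones(1, dtype=complex), np.ones(1))
        with pytest.raises(FieldSynthesisError):
            compute_pressure_field(
                SINGLE, WAVE, MEDIUM, unit,
                np.array([0.0]), np.array([0.0]), np.array([-1e-4]),
            )
        with pytest.raises(ConfigurationError):
            compute_pressure_field(
                SINGLE, WAVE, MEDIUM, unit,
                np.array([0.0, -1e-5]), np.array([0.0]), np.array([1e-4]),
            )


class TestIntensityAndPower:
    def test_peak_pressure_intensity_pairing(self):
        """2.15 MPa peak pressure in water corresponds to ~150 W/cm^2."""
        I = compute_intensity(np.array([2.15e6 + 0j]), MEDIUM)[0]
        assert I == pytest.approx(150e4, rel=0.03)

    def test_intensity_is_quadratic_and_null_on_silence(self):
        p = np.array([0.0 + 0j, 1e5 + 2e4j])
        I1 = compute_intensity(p, MEDIUM)
        I2 = compute_intensity(2 * p, MEDIUM)
        assert I1[0] == 0.0
        np.testing.assert_allclose(I2, 4 * I1)

    def test_source_power_invariant_under_phase_only_changes(self):
        u = ExcitationVector(np.array([0.3 + 0.1j]), np.ones(1))
        rotated = ExcitationVector(u.values * np.exp(1j * 0.8), np.ones(1))
        p1 = source_plane_power(SINGLE, MEDIUM, u)
        p2 = source_plane_power(SINGLE, MEDIUM, rotated)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_power_normalization_hits_target(self):
        u = ExcitationVector(np.array([0.3 + 0.1j]), np.ones(1))
        scaled = normalize_to_source_power(u, SINGLE, MEDIUM, 4.25e-3)
        assert source_plane_power(SINGLE, MEDIUM, scaled) == pytest.approx(
            4.25e-3, rel=1e-12
        )


class TestFieldGridIO:
    def test_hdf5_round_trip(self, tmp_path):
        from acoustrap.fixtures import gaussian_beam_field

        grid = gaussian_beam_field(half_span=20e-6, spacing=5e-6)
        path = tmp_path / "field.h5"
        grid.to_hdf5(path)
        again = FieldGrid.from_hdf5(path)
        np.testing.assert_array_equal(again.pressure, grid.pressure)
        np.testing.assert_allclose(again.intensity, grid.intensity)
        assert again.frequency == grid.frequency
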