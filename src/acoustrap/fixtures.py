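"""Analytic fixtures with closed-form ground truth.

Each generator returns an object whose expected behaviour is known in
closed form (and embeds it as metadata), so unit tests can check the
measurement and force machinery against an independent answer.  Fixtures
are deterministic; the optional noise is the only use of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beam_analysis import BeamModel
from .core_types import ArrayGeometry, Medium, WaveParams
from .field_synthesis import ExcitationVector, FieldGrid, compute_pressure_at
from .ray_force import ForceProfile

__all__ = [
    "gaussian_beam_field",
    "piston_on_axis",
    "linear_force_profile",
    "PistonCurve",
]


def gaussian_beam_field(
    waist: float = 22e-6,
    peak_intensity: float = 150e4,
    wavelength: float = 30e-6,
    focus=(0.0, 0.0, 670e-6),
    medium: Medium | None = None,
    half_span: float = 80e-6,
    spacing: float = 1e-6,
    z_half_span: float = 0.0,
    z_spacing: float = 5e-6,
    noise: float = 0.0,
    seed: int | None = None,
) -> FieldGrid:
    """Sampled analytic Gaussian beam whose half-power width is known.

    The grid stores the intensity I0 (w/w(z))^2 exp(-2 r^2 / w(z)^2) of a
    :class:`BeamModel` with 1/e^2-style radius parameter ``waist``, so the
    measured focal-plane half-power full width is exactly
    ``waist * HALF_POWER_OVER_1E2_WAIST`` (= 2 sqrt(ln2/2) waist).
    """
    medium = medium or Medium()
    focus = np.asarray(focus, dtype=float)
    beam = BeamModel(
        focus=focus, waist=waist, wavelength=wavelength,
        peak_intensity=peak_intensity,
    )
    x = focus[0] + np.arange(-half_span, half_span + spacing / 2, spacing)
    y = focus[1] + np.arange(-half_span, half_span + spacing / 2, spacing)
    if z_half_span > 0:
        z = focus[2] + np.arange(
            -z_half_span, z_half_span + z_spacing / 2, z_spacing
        )
    else:
        z = np.array([focus[2]])
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    r = np.hypot(X - focus[0], Y - focus[1])
    intensity = beam.intensity(r, Z - focus[2])
    if noise > 0.0:
        rng = np.random.default_rng(seed)
        intensity = np.maximum(
            intensity * (1.0 + noise * rng.standard_normal(intensity.shape)),
            0.0,
        )
    # encode as a (real, zero-phase) pressure so the grid's own intensity
    # derivation reproduces the analytic values exactly
    pressure = np.sqrt(
        2.0 * medium.density * medium.sound_speed * intensity
    ).astype(complex)
    frequency = medium.sound_speed / wavelength
    return FieldGrid(x=x, y=y, z=z, pressure=pressure, frequency=frequency,
                     medium=medium)


@dataclass(frozen=True)
class PistonCurve:
    """On-axis pressure of a single square element at two quadrature depths."""

    z: np.ndarray  # m
    pressure: np.ndarray  # complex Pa, default sub-source density
    pressure_oracle: np.ndarray  # complex Pa, 10x denser quadrature
    element_width: float
    frequency: float


def piston_on_axis(
    element_width: float = 22e-6,
    frequency: float = 50e6,
    medium: Medium | None = None,
    z: np.ndarray | None = None,
    n_sub: int = 4,
    oracle_factor: int = 10,
) -> PistonCurve:
    """Single-element on-axis curve with a dense-quadrature oracle column."""
    medium = medium or Medium()
    if z is None:
        z = np.linspace(100e-6, 2000e-6, 96)
    geometry = ArrayGeometry(
        n_elements_x=1, n_elements_y=1,
        pitch=element_width, kerf=0.0, center_frequency=frequency,
    )
    wave = WaveParams.from_medium(geometry, medium)
    unit = ExcitationVector(values=np.array([1.0 + 0j]), weighting=np.ones(1))
    pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    p = compute_pressure_at(geometry, wave, medium, unit, pts, n_sub=n_sub)
    p_oracle = compute_pressure_at(
        geometry, wave, medium, unit, pts, n_sub=n_sub * oracle_factor
    )
    return PistonCurve(
        z=np.asarray(z, dtype=float), pressure=p, pressure_oracle=p_oracle,
        element_width=element_width, frequency=frequency,
    )


def linear_force_profile(
    stiffness: float = 1e-5,  # N/m
    half_span: float = 300e-6,
    n: int = 301,
    axis: str = "z",
) -> ForceProfile:
    """Linear restoring force F = -k x along one axis (closed-form dynamics).

    A particle released in this profile relaxes as a damped harmonic
    oscillator: m x'' + gamma x' + k x = 0, whose solution is analytic for
    any (m, gamma, k); tests compare the integrator against it.
    """
    coord = np.linspace(-half_span, half_span, n)
    force = -stiffness * coord
    zeros = np.zeros(n)
    if axis == "z":
        positions = np.column_stack([zeros, zeros, coord])
        return ForceProfile(positions, "z", f_sz=zeros, f_gz=force,
                            f_sy=zeros, f_gy=zeros)
    positions = np.column_stack([zeros, coord, zeros])
    return ForceProfile(positions, "y", f_sz=zeros, f_gz=zeros,
                        f_sy=zeros, f_gy=force)
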