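"""Turnkey pipelines tying the stages together.

These functions reproduce the package's reference experiments end to end:
synthesize the four-focus 50 MHz field, normalize it, characterize one
focal beam, sweep radiation forces for several particle sizes, and derive
the trapping summary table.  The command-line interface and the test suite
both drive these entry points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import field_synthesis, ray_force
from .beam_analysis import BeamModel, beam_width_half_power, locate_focal_points
from .core_types import Medium, Particle, SimulationConfig, load_preset
from .field_synthesis import (
    ControlPointSet,
    ExcitationVector,
    FieldGrid,
    PropagationMatrix,
    build_propagation_matrix,
    compute_pressure_at,
    compute_intensity,
    normalize_to_peak_intensity,
    normalize_to_source_power,
    solve_excitation_weighted,
    source_plane_power,
)
from .ray_force import ForceProfile, TrappingSummary, force_profile, trapping_summary

__all__ = [
    "SynthesisResult",
    "TrappingRow",
    "synthesize_multi_focus",
    "measure_focus",
    "trapping_table",
    "off_axis_profiles",
    "PEAK_INTENSITY_TARGET",
    "INPUT_POWER_TARGET",
]

#: Spatial peak intensity the excitation is scaled to in peak mode, W/m^2.
PEAK_INTENSITY_TARGET = 150e4  # 150 W/cm^2

#: Source-plane acoustic power in total-power mode, W.
INPUT_POWER_TARGET = 4.25e-3  # 4.25 mW

#: Default focal-plane render: +-0.30 mm at 2 um spacing.
GRID_HALF_SPAN = 0.30e-3
GRID_SPACING = 2e-6


@dataclass(frozen=True)
class SynthesisResult:
    """Synthesized, normalized multi-focus field and its characterization."""

    config: SimulationConfig
    propagation: PropagationMatrix
    excitation: ExcitationVector  # normalized per ``mode``
    focal_plane: FieldGrid  # normalized focal-plane render
    foci: list  # refined focus positions, brightest first
    focus_intensities: list  # refined peak intensities at the foci, W/m^2
    beam: BeamModel  # fitted model of the characterized focus
    mode: str  # "peak-intensity" or "total-power"
    source_power: float  # W, of the normalized excitation
    peak_intensity: float  # W/m^2, spatial peak of the normalized field
    beam_width_focal_plane: float  # m, half-power width at z = z_focus
    axial_z: np.ndarray = None  # m, local coordinate along the beam axis
    axial_intensity: np.ndarray = None  # W/m^2, measured on-axis intensity

    def streaming_model(self, absorption_coefficient: float | None = None):
        """Streaming closure driven by the *measured* on-axis intensity.

        The fitted Gaussian overestimates the synthesized beam's on-axis
        intensity downstream of the focus (the real beam spreads with the
        aperture cone and interferes with its three neighbours), so the
        absorption-driven flow is evaluated on the measured profile.
        """
        from .dynamics import StreamingModel
        from scipy.interpolate import interp1d

        profile = interp1d(
            self.axial_z, self.axial_intensity,
            bounds_error=False, fill_value=0.0,
        )
        return StreamingModel(
            beam=self.beam,
            medium=self.config.medium,
            absorption_coefficient=absorption_coefficient,
            axial_intensity=profile,
        )


def _fine_profile(
    config: SimulationConfig,
    excitation: ExcitationVector,
    focus: np.ndarray,
    direction: np.ndarray,
    half_span: float = 80e-6,
    step: float = 0.25e-6,
    n_sub: int = field_synthesis.DEFAULT_SUBDIVISION,
):
    """Intensity profile along a line through ``focus`` by direct rendering."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    t = np.arange(-half_span, half_span + step / 2, step)
    pts = focus[None, :] + t[:, None] * direction[None, :]
    p = compute_pressure_at(
        config.geometry, config.wave, config.medium, excitation, pts, n_sub
    )
    return t, compute_intensity(p, config.medium)


def synthesize_multi_focus(
    config: SimulationConfig | None = None,
    mode: str = "peak-intensity",
    grid_half_span: float = GRID_HALF_SPAN,
    grid_spacing: float = GRID_SPACING,
    n_sub: int = field_synthesis.DEFAULT_SUBDIVISION,
    max_iter: int = 20,
) -> SynthesisResult:
    """Full synthesis pipeline for the configured control points.

    Solves the weighted pseudoinverse excitation, renders the focal plane,
    rescales the excitation (spatial peak intensity -> 150 W/cm^2, or
    source-plane power -> 4.25 mW), locates the foci, and fits the Gaussian
    beam model of the focus nearest the +x+y quadrant diagonal.
    """
    if config is None:
        config = load_preset()
    points = ControlPointSet.from_config(config)
    H = build_propagation_matrix(
        config.geometry, config.wave, config.medium, points, n_sub
    )
    excitation = solve_excitation_weighted(H, max_iter=max_iter)

    z_focus = float(np.mean(points.points[:, 2]))
    span = np.arange(-grid_half_span, grid_half_span + grid_spacing / 2, grid_spacing)
    plane = field_synthesis.compute_pressure_field(
        config.geometry, config.wave, config.medium, excitation,
        span, span, np.array([z_focus]), n_sub,
    )

    foci, focus_int = locate_focal_points(plane, return_intensities=True)
    if not foci:
        raise field_synthesis.FieldSynthesisError("no focal points detected")
    # characterize the focus nearest the first configured control point
    target = points.points[0]
    idx = int(np.argmin([np.linalg.norm(f - target) for f in foci]))
    focus = foci[idx]

    # lateral profile along the diagonal through the focus and the array axis
    diag = np.array([focus[0], focus[1], 0.0])
    norm = np.linalg.norm(diag)
    direction = diag / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    t, prof = _fine_profile(config, excitation, focus, direction, n_sub=n_sub)
    # axial refinement of the spatial peak around the focal plane
    t_ax, prof_ax = _fine_profile(
        config, excitation, focus, np.array([0.0, 0.0, 1.0]),
        half_span=100e-6, step=2e-6, n_sub=n_sub,
    )
    raw_peak = max(float(prof.max()), float(prof_ax.max()), float(plane.intensity.max()))
    # on-axis intensity along the (tilted) beam axis, array centre -> focus,
    # used by the streaming closure
    axis_dir = focus / np.linalg.norm(focus)
    z_axis = np.arange(-0.2e-3, 1.8e-3 + 5e-6, 10e-6)
    line = focus[None, :] + z_axis[:, None] * axis_dir[None, :]
    p_axis = compute_pressure_at(
        config.geometry, config.wave, config.medium, excitation, line, n_sub
    )
    I_axis = compute_intensity(p_axis, config.medium)

    if mode == "peak-intensity":
        normalized = normalize_to_peak_intensity(
            excitation, raw_peak, PEAK_INTENSITY_TARGET
        )
    elif mode == "total-power":
        normalized = normalize_to_source_power(
            excitation, config.geometry, config.medium, INPUT_POWER_TARGET
        )
    else:
        raise ValueError("mode must be 'peak-intensity' or 'total-power'")
    factor = abs(normalized.scale / excitation.scale) ** 2

    plane = plane.rescale_pressure(normalized.scale / excitation.scale)
    width = beam_width_half_power(t, prof)
    beam = BeamModel(
        focus=focus,
        waist=width,
        wavelength=config.wave.wavelength,
        peak_intensity=float(prof.max()) * factor,
        axis=axis_dir,
    )
    return SynthesisResult(
        config=config,
        propagation=H,
        excitation=normalized,
        focal_plane=plane,
        foci=foci,
        focus_intensities=[v * factor for v in focus_int],
        beam=beam,
        mode=mode,
        source_power=source_plane_power(
            config.geometry, config.medium, normalized
        ),
        peak_intensity=raw_peak * factor,
        beam_width_focal_plane=width,
        axial_z=z_axis,
        axial_intensity=I_axis * factor,
    )


def measure_focus(
    result: SynthesisResult, focus_index: int = 0
) -> dict:
    """QC record for one detected focus (position, intensity, width)."""
    focus = result.foci[focus_index]
    diag = np.array([focus[0], focus[1], 0.0])
    norm = np.linalg.norm(diag)
    direction = diag / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    t, prof = _fine_profile(
        result.config, result.excitation, focus, direction
    )
    width, left, right = beam_width_half_power(t, prof, return_halves=True)
    return {
        "x_mm": focus[0] * 1e3,
        "y_mm": focus[1] * 1e3,
        "z_mm": focus[2] * 1e3,
        "intensity_w_cm2": result.focus_intensities[focus_index] / 1e4,
        "half_power_width_um": width * 1e6,
        "width_asymmetry": abs(left - right) / max(left, right),
    }


@dataclass(frozen=True)
class TrappingRow:
    """One particle size's sweeps and derived trapping metrics."""

    diameter: float  # m
    axial: ForceProfile
    lateral: ForceProfile | None
    summary: TrappingSummary


def trapping_table(
    beam: BeamModel,
    medium: Medium,
    particle: Particle,
    diameters=(240e-6, 300e-6, 360e-6),
    z_range=(-0.2e-3, 1.2e-3),
    z_step: float = 2e-6,
    y_range=(-0.3e-3, 0.35e-3),
    y_step: float = 2e-6,
    mode: str = ray_force.DEFAULT_FORCE_MODE,
    n_theta: int = ray_force.DEFAULT_N_THETA,
    n_phi: int = ray_force.DEFAULT_N_PHI,
) -> list[TrappingRow]:
    """Axial + lateral sweeps and trapping summaries per particle diameter.

    The axial sweep runs along the local beam axis; the lateral sweep
    crosses the axis through the balanced (stable equilibrium) position of
    that diameter.  Sizes that show no negative axial force anywhere are
    flagged untrapped and skip the lateral sweep.
    """
    z = np.arange(z_range[0], z_range[1] + z_step / 2, z_step)
    y = np.arange(y_range[0], y_range[1] + y_step / 2, y_step)
    rows = []
    for d in diameters:
        p = replace(particle, radius=d / 2.0)
        axial = force_profile(
            ray_force.axial_sweep(z), p, beam, medium,
            sweep_axis="z", n_theta=n_theta, n_phi=n_phi, mode=mode,
        )
        first = trapping_summary(axial)
        lateral = None
        if first.trapped and first.balanced_position is not None:
            lateral = force_profile(
                ray_force.lateral_sweep(y, first.balanced_position),
                p, beam, medium,
                sweep_axis="y", n_theta=n_theta, n_phi=n_phi, mode=mode,
            )
        rows.append(
            TrappingRow(
                diameter=d,
                axial=axial,
                lateral=lateral,
                summary=trapping_summary(axial, lateral),
            )
        )
    return rows


def off_axis_profiles(
    beam: BeamModel,
    medium: Medium,
    particle: Particle,
    offsets=(0.0, 20e-6, 50e-6),
    z_range=(-0.2e-3, 1.2e-3),
    z_step: float = 10e-6,
    mode: str = ray_force.DEFAULT_FORCE_MODE,
    n_theta: int = ray_force.DEFAULT_N_THETA,
    n_phi: int = ray_force.DEFAULT_N_PHI,
) -> dict[float, ForceProfile]:
    """Axial force sweeps at several lateral offsets from the beam axis."""
    z = np.arange(z_range[0], z_range[1] + z_step / 2, z_step)
    return {
        off: force_profile(
            ray_force.axial_sweep(z, offset_y=off), particle, beam, medium,
            sweep_axis="z", n_theta=n_theta, n_phi=n_phi, mode=mode,
        )
        for off in offsets
    }
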