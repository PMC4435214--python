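"""Particle motion under radiation force, viscous drag and streaming drag.

The equation of motion is Newton's second law for the sphere,

    m dv/dt = F_rad(x) + F_streaming_drag(x) - 6 pi mu r0 v,

with the Stokes term opposing motion and (on the axial axis only) a drag
from the steady acoustic streaming flow driven by absorption of the beam.
Radial streaming is omitted: the streaming flow is axial on the beam axis.
Gravity and buoyancy are not modelled.

The streaming velocity uses an Eckart-type absorption-driven closed form on
the beam's axial intensity profile,

    v_s(z) = 2 alpha I(0, z) w0^2 / (sigma c),

with alpha = alpha0 f^2 the small-signal attenuation of water.  The model
lives behind :class:`StreamingModel` so an alternative closure can be
substituted without touching the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .beam_analysis import BeamModel
from .core_types import ConfigurationError, Medium, Particle
from .ray_force import ForceProfile

__all__ = [
    "StreamingModel",
    "TrajectoryResult",
    "stokes_drag",
    "attenuation_coefficient",
    "streaming_velocity",
    "streaming_drag",
    "integrated_axial_force",
    "simulate_trajectory",
    "force_spline",
]

#: Small-signal attenuation of water, dB / (cm MHz^2).
WATER_ALPHA0_DB_CM_MHZ2 = 2.2e-3

_DB_TO_NP = math.log(10.0) / 20.0  # 0.1151...

#: Capture thresholds: residual speed (m/s) and distance to equilibrium (m).
CAPTURE_SPEED = 1e-6
CAPTURE_DISTANCE = 1e-6


def stokes_drag(velocity, r0: float, mu: float):
    """Viscous resistance F = -6 pi mu r0 v on a sphere, opposing motion."""
    if r0 <= 0 or mu <= 0:
        raise ConfigurationError("radius and viscosity must be positive")
    return -6.0 * math.pi * mu * r0 * np.asarray(velocity, dtype=float)


def attenuation_coefficient(
    frequency: float, alpha0_db_cm_mhz2: float = WATER_ALPHA0_DB_CM_MHZ2
) -> float:
    """Plane-wave amplitude attenuation alpha = alpha0 f^2, in Np/m."""
    f_mhz = frequency / 1e6
    db_per_cm = alpha0_db_cm_mhz2 * f_mhz**2
    return db_per_cm * 100.0 * _DB_TO_NP


@dataclass(frozen=True)
class StreamingModel:
    """Absorption-driven axial streaming along a focused beam.

    ``axial_intensity`` optionally supplies the on-axis intensity profile
    I(z) (W/m^2, local beam frame) that drives the flow — e.g. the measured
    profile of a synthesized beam, whose downstream intensity the fitted
    Gaussian model overestimates.  By default the beam model's own axial
    intensity is used.
    """

    beam: BeamModel
    medium: Medium
    absorption_coefficient: float | None = None  # Np/m; default water at f
    axial_intensity: Callable | None = None  # z (m) -> W/m^2

    def __post_init__(self) -> None:
        if self.absorption_coefficient is None:
            f = self.medium.sound_speed / self.beam.wavelength
            object.__setattr__(
                self, "absorption_coefficient", attenuation_coefficient(f)
            )
        if self.absorption_coefficient <= 0:
            raise ConfigurationError("absorption coefficient must be > 0")

    def velocity(self, z) -> np.ndarray:
        """Axial streaming speed v_s(z) >= 0; peaks at the focus."""
        return streaming_velocity(z, self.beam, self.medium, self)

    def drag(self, z) -> np.ndarray:
        """Drag force 3 pi sigma v_s(z) w0 on the particle, along +z (N)."""
        return streaming_drag(
            self.velocity(z), self.medium.dynamic_viscosity, self.beam.waist
        )


def streaming_velocity(
    z, beam: BeamModel, medium: Medium, model: StreamingModel
) -> np.ndarray:
    """Eckart-type closed form v_s(z) = 2 alpha I(0,z) w0^2 / (sigma c)."""
    alpha = model.absorption_coefficient
    if alpha <= 0:
        raise ConfigurationError("absorption coefficient must be > 0")
    z = np.asarray(z, dtype=float)
    if model.axial_intensity is not None:
        I_axis = np.maximum(np.asarray(model.axial_intensity(z), float), 0.0)
    else:
        I_axis = beam.axial_intensity(z)
    return (
        2.0
        * alpha
        * I_axis
        * beam.waist**2
        / (medium.dynamic_viscosity * medium.sound_speed)
    )


def streaming_drag(v_s, sigma: float, w0: float):
    """Drag F_d = 3 pi sigma v_s w0 exerted by the streaming flow (N)."""
    if sigma <= 0 or w0 <= 0:
        raise ConfigurationError("viscosity and beam width must be positive")
    return 3.0 * math.pi * sigma * np.asarray(v_s, dtype=float) * w0


def force_spline(profile: ForceProfile) -> CubicSpline:
    """Cubic interpolant of a profile's total force along its sweep axis."""
    coord = profile.coordinate
    force = profile.force_z if profile.sweep_axis == "z" else profile.force_y
    return CubicSpline(coord, force)


def integrated_axial_force(
    z,
    radiation: ForceProfile | Callable,
    streaming: StreamingModel | None = None,
) -> np.ndarray:
    """Total axial force: radiation force plus (optionally) streaming drag.

    With ``streaming=None`` this is exactly the radiation force.
    """
    fn = force_spline(radiation) if isinstance(radiation, ForceProfile) else radiation
    z = np.asarray(z, dtype=float)
    total = np.asarray(fn(z), dtype=float)
    if streaming is not None:
        total = total + streaming.drag(z)
    return total


@dataclass(frozen=True)
class TrajectoryResult:
    """Integrated particle motion along one axis of the local beam frame."""

    times: np.ndarray  # s, strictly increasing
    positions: np.ndarray  # m
    velocities: np.ndarray  # m/s
    capture_time: float | None  # s, first time the capture criteria hold
    balanced_position: float | None  # m, equilibrium the particle settled at
    escaped: bool  # left the force-profile domain (truncated)

    @property
    def captured(self) -> bool:
        return self.capture_time is not None


def _stable_zeros(spline: CubicSpline) -> np.ndarray:
    """Force zero-crossings with negative slope (stable equilibria)."""
    roots = spline.roots(extrapolate=False)
    if len(roots) == 0:
        return roots
    slope = spline(roots, 1)
    return roots[slope < 0.0]


def simulate_trajectory(
    profile: ForceProfile,
    particle: Particle,
    medium: Medium,
    initial_position: float,
    initial_velocity: float = 0.0,
    streaming: StreamingModel | None = None,
    duration: float = 4.0,
    max_step: float = 1e-3,
    n_eval: int = 4000,
) -> TrajectoryResult:
    """Integrate m dv/dt = F(x) - 6 pi mu r0 v from rest or a given state.

    ``profile`` supplies the radiation force along its sweep axis (cubic
    interpolant); ``streaming`` adds the axial streaming drag and is only
    meaningful for an axial profile.  Integration uses adaptive Runge-Kutta
    (RK45, absolute tolerances 1e-9 m and 1e-9 m/s, max step 1e-3 s).

    Capture is declared at the first sample where |v| < 1 um/s and the
    particle sits within 1 um of a stable force zero; leaving the profile
    domain truncates the trajectory with ``escaped=True``.
    """
    if streaming is not None and profile.sweep_axis != "z":
        raise ConfigurationError(
            "streaming drag applies to axial trajectories only"
        )
    spline = force_spline(profile)
    coord = profile.coordinate
    lo, hi = float(coord.min()), float(coord.max())
    if not (lo <= initial_position <= hi):
        raise ConfigurationError("initial position outside the force domain")

    gamma = 6.0 * math.pi * medium.shear_viscosity * particle.radius
    mass = particle.mass

    def total_force(x: float) -> float:
        f = float(spline(x))
        if streaming is not None:
            f += float(streaming.drag(x))
        return f

    def rhs(t, state):
        x, v = state
        return [v, (total_force(x) - gamma * v) / mass]

    def leave_domain(t, state):
        return min(state[0] - lo, hi - state[0])

    leave_domain.terminal = True
    leave_domain.direction = -1

    t_eval = np.linspace(0.0, duration, n_eval)
    sol = solve_ivp(
        rhs,
        (0.0, duration),
        [initial_position, initial_velocity],
        method="RK45",
        t_eval=t_eval,
        events=[leave_domain],
        max_step=max_step,
        rtol=1e-8,
        atol=[1e-9, 1e-9],
    )
    escaped = sol.status == 1
    times = sol.t
    x = sol.y[0]
    v = sol.y[1]

    if streaming is None:
        total = spline
        zeros = _stable_zeros(spline)
    else:
        zs = np.linspace(lo, hi, len(coord))
        total = CubicSpline(zs, integrated_axial_force(zs, spline, streaming))
        zeros = _stable_zeros(total)

    capture_time = None
    balanced = None
    if len(zeros) > 0 and len(x) > 0:
        dist = np.min(np.abs(x[:, None] - zeros[None, :]), axis=1)
        ok = (np.abs(v) < CAPTURE_SPEED) & (dist < CAPTURE_DISTANCE)
        hits = np.nonzero(ok)[0]
        if len(hits) > 0:
            i0 = hits[0]
            capture_time = float(times[i0])
            balanced = float(zeros[np.argmin(np.abs(zeros - x[-1]))])
    return TrajectoryResult(
        times=times,
        positions=x,
        velocities=v,
        capture_time=capture_time,
        balanced_position=balanced,
        escaped=escaped,
    )
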