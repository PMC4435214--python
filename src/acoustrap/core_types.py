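"""Physical configuration types shared by every stage of the simulation.

All quantities are strict SI internally (metres, seconds, Pa, Rayl, W/m^2).
Configuration files may use the field-customary units (um, MHz, MRayl,
W/cm^2); conversion happens only at the YAML boundary in :func:`load_config`.

Coordinate convention: right-handed, the phased array lies in the z = 0
plane centred on the origin, +z is the propagation direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ArrayGeometry",
    "Medium",
    "Particle",
    "WaveParams",
    "SimulationConfig",
    "ConfigurationError",
    "MieRegimeWarning",
    "validate_config",
    "load_config",
    "save_config",
    "load_preset",
    "DEFAULT_PRESET",
]

#: Minimum particle diameter, in wavelengths, for the ray (Mie) force model.
MIE_DIAMETER_WAVELENGTHS = 6.0

DEFAULT_PRESET = "water_lipid_50mhz"


class ConfigurationError(ValueError):
    """A physical configuration violates an invariant."""


class MieRegimeWarning(UserWarning):
    """Particle too small for the ray-acoustics force model to be trusted."""


@dataclass(frozen=True)
class ArrayGeometry:
    """2-D phased-array layout in the z = 0 plane, centred on the origin.

    The element width/height is ``pitch - kerf`` (square elements).
    """

    n_elements_x: int = 25
    n_elements_y: int = 25
    pitch: float = 27e-6  # m, centre-to-centre
    kerf: float = 5e-6  # m, gap between elements
    center_frequency: float = 50e6  # Hz

    def __post_init__(self) -> None:
        if self.n_elements_x < 1 or self.n_elements_y < 1:
            raise ConfigurationError("element counts must be >= 1")
        if self.pitch <= 0 or self.center_frequency <= 0:
            raise ConfigurationError("pitch and frequency must be positive")
        if self.kerf < 0:
            raise ConfigurationError("kerf must be non-negative")
        if self.element_width <= 0:
            raise ConfigurationError(
                f"element width pitch - kerf = {self.element_width:g} m must be "
                "positive"
            )

    @property
    def element_width(self) -> float:
        return self.pitch - self.kerf

    @property
    def element_height(self) -> float:
        return self.pitch - self.kerf

    @property
    def n_elements(self) -> int:
        return self.n_elements_x * self.n_elements_y

    @property
    def aperture_x(self) -> float:
        """Full aperture extent along x (outer edge to outer edge)."""
        return (self.n_elements_x - 1) * self.pitch + self.element_width

    @property
    def aperture_y(self) -> float:
        return (self.n_elements_y - 1) * self.pitch + self.element_height

    def element_centers(self) -> np.ndarray:
        """(N, 3) element-centre coordinates, x fastest, z = 0."""
        ix = np.arange(self.n_elements_x) - (self.n_elements_x - 1) / 2.0
        iy = np.arange(self.n_elements_y) - (self.n_elements_y - 1) / 2.0
        xx, yy = np.meshgrid(ix * self.pitch, iy * self.pitch, indexing="xy")
        centers = np.column_stack(
            [xx.ravel(), yy.ravel(), np.zeros(self.n_elements)]
        )
        return centers


@dataclass(frozen=True)
class Medium:
    """Propagation medium (water by default, Table-value properties)."""

    density: float = 1000.0  # kg/m^3
    sound_speed: float = 1500.0  # m/s
    shear_viscosity: float = 8.9e-4  # Pa s, Stokes-drag mu
    dynamic_viscosity: float | None = None  # Pa s, streaming-drag sigma
    impedance: float | None = None  # Rayl; default rho * c

    def __post_init__(self) -> None:
        if self.density <= 0 or self.sound_speed <= 0:
            raise ConfigurationError("medium density and sound speed must be > 0")
        if self.shear_viscosity <= 0:
            raise ConfigurationError("viscosity must be > 0")
        if self.dynamic_viscosity is None:
            object.__setattr__(self, "dynamic_viscosity", self.shear_viscosity)
        if self.dynamic_viscosity <= 0:
            raise ConfigurationError("viscosity must be > 0")
        rho_c = self.density * self.sound_speed
        if self.impedance is None:
            object.__setattr__(self, "impedance", rho_c)
        elif abs(self.impedance - rho_c) > 0.01 * rho_c:
            raise ConfigurationError(
                f"impedance {self.impedance:g} inconsistent with rho*c = "
                f"{rho_c:g} (>1% off)"
            )


@dataclass(frozen=True)
class Particle:
    """Spherical target particle (lipid/fat sphere by default)."""

    radius: float = 120e-6  # m
    density: float = 950.0  # kg/m^3
    sound_speed: float = 1450.0  # m/s
    impedance: float | None = None  # Rayl; default rho * c

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError("particle radius must be > 0")
        if self.density <= 0 or self.sound_speed <= 0:
            raise ConfigurationError("particle density and sound speed must be > 0")
        rho_c = self.density * self.sound_speed
        if self.impedance is None:
            object.__setattr__(self, "impedance", rho_c)
        elif abs(self.impedance - rho_c) > 0.02 * rho_c:
            # particle impedance in the source table (1.4 MRayl) is rounded
            # relative to rho*c = 1.3775 MRayl; accept a 2% band
            raise ConfigurationError(
                f"particle impedance {self.impedance:g} inconsistent with "
                f"rho*c = {rho_c:g}"
            )

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def mass(self) -> float:
        """Sphere mass m = (4/3) pi r0^3 rho."""
        return 4.0 / 3.0 * math.pi * self.radius**3 * self.density


@dataclass(frozen=True)
class WaveParams:
    """Derived wave quantities for a (frequency, medium) pair."""

    frequency: float  # Hz
    sound_speed: float  # m/s

    @property
    def wavelength(self) -> float:
        return self.sound_speed / self.frequency

    @property
    def wavenumber(self) -> float:
        return 2.0 * math.pi / self.wavelength

    @property
    def angular_frequency(self) -> float:
        return 2.0 * math.pi * self.frequency

    @classmethod
    def from_medium(cls, geometry: ArrayGeometry, medium: Medium) -> "WaveParams":
        return cls(geometry.center_frequency, medium.sound_speed)


@dataclass(frozen=True)
class SimulationConfig:
    """A validated (geometry, medium, particle) triple with derived wave data."""

    geometry: ArrayGeometry
    medium: Medium
    particle: Particle
    wave: WaveParams
    control_points: np.ndarray | None = None  # (M, 3) m
    target_pressures: np.ndarray | None = None  # (M,) complex, Pa


def validate_config(
    geometry: ArrayGeometry,
    medium: Medium,
    particle: Particle,
    control_points: Sequence[Sequence[float]] | None = None,
    target_pressures: Sequence[complex] | None = None,
) -> SimulationConfig:
    """Validate a configuration and fill in derived quantities.

    Raises :class:`ConfigurationError` on violated invariants; emits a
    :class:`MieRegimeWarning` (not fatal) when the particle diameter is below
    six wavelengths, outside the validity range of the ray force model.
    """
    wave = WaveParams.from_medium(geometry, medium)
    if particle.diameter < MIE_DIAMETER_WAVELENGTHS * wave.wavelength:
        warnings.warn(
            f"particle diameter {particle.diameter * 1e6:.1f} um is below "
            f"{MIE_DIAMETER_WAVELENGTHS:g} wavelengths "
            f"({MIE_DIAMETER_WAVELENGTHS * wave.wavelength * 1e6:.1f} um); "
            "the ray-acoustics force model is unreliable in this regime",
            MieRegimeWarning,
            stacklevel=2,
        )
    cp = None
    tp = None
    if control_points is not None:
        cp = np.atleast_2d(np.asarray(control_points, dtype=float))
        if cp.shape[1] != 3:
            raise ConfigurationError("control points must be (M, 3)")
        if np.any(cp[:, 2] <= 0):
            raise ConfigurationError("control points must lie at z > 0")
        if len(cp) > geometry.n_elements:
            raise ConfigurationError(
                f"{len(cp)} control points exceed the {geometry.n_elements} "
                "array degrees of freedom"
            )
        if target_pressures is None:
            tp = np.ones(len(cp), dtype=complex)
        else:
            tp = np.asarray(target_pressures, dtype=complex)
            if tp.shape != (len(cp),):
                raise ConfigurationError(
                    "target_pressures must have one entry per control point"
                )
    return SimulationConfig(geometry, medium, particle, wave, cp, tp)


# ---------------------------------------------------------------------------
# YAML boundary: customary units in files, SI in memory
# ---------------------------------------------------------------------------

_UM = 1e-6
_MHZ = 1e6
_MRAYL = 1e6


def _config_to_dict(config: SimulationConfig) -> dict:
    g, m, p = config.geometry, config.medium, config.particle
    out = {
        "array": {
            "n_elements_x": g.n_elements_x,
            "n_elements_y": g.n_elements_y,
            "pitch_um": g.pitch / _UM,
            "kerf_um": g.kerf / _UM,
            "center_frequency_mhz": g.center_frequency / _MHZ,
        },
        "medium": {
            "density_kg_m3": m.density,
            "sound_speed_m_s": m.sound_speed,
            "shear_viscosity_pa_s": m.shear_viscosity,
            "dynamic_viscosity_pa_s": m.dynamic_viscosity,
            "impedance_mrayl": m.impedance / _MRAYL,
        },
        "particle": {
            "diameter_um": p.diameter / _UM,
            "density_kg_m3": p.density,
            "sound_speed_m_s": p.sound_speed,
            "impedance_mrayl": p.impedance / _MRAYL,
        },
    }
    if config.control_points is not None:
        out["focal_points"] = {
            "points_mm": (config.control_points / 1e-3).tolist(),
            "target_pressures": [
                [float(z.real), float(z.imag)] for z in config.target_pressures
            ],
        }
    return out


def _config_from_dict(data: dict) -> SimulationConfig:
    try:
        a = data["array"]
        m = data["medium"]
        p = data["particle"]
    except KeyError as exc:  # pragma: no cover - message clarity only
        raise ConfigurationError(f"missing configuration section: {exc}") from exc
    geometry = ArrayGeometry(
        n_elements_x=int(a.get("n_elements_x", 25)),
        n_elements_y=int(a.get("n_elements_y", 25)),
        pitch=float(a["pitch_um"]) * _UM,
        kerf=float(a["kerf_um"]) * _UM,
        center_frequency=float(a["center_frequency_mhz"]) * _MHZ,
    )
    medium = Medium(
        density=float(m["density_kg_m3"]),
        sound_speed=float(m["sound_speed_m_s"]),
        shear_viscosity=float(m["shear_viscosity_pa_s"]),
        dynamic_viscosity=(
            float(m["dynamic_viscosity_pa_s"])
            if m.get("dynamic_viscosity_pa_s") is not None
            else None
        ),
        impedance=(
            float(m["impedance_mrayl"]) * _MRAYL
            if m.get("impedance_mrayl") is not None
            else None
        ),
    )
    particle = Particle(
        radius=float(p["diameter_um"]) * _UM / 2.0,
        density=float(p["density_kg_m3"]),
        sound_speed=float(p["sound_speed_m_s"]),
        impedance=(
            float(p["impedance_mrayl"]) * _MRAYL
            if p.get("impedance_mrayl") is not None
            else None
        ),
    )
    cp = None
    tp = None
    if "focal_points" in data:
        fp = data["focal_points"]
        cp = np.asarray(fp["points_mm"], dtype=float) * 1e-3
        raw = fp.get("target_pressures")
        if raw is not None:
            tp = np.asarray([complex(re, im) for re, im in raw])
    return validate_config(geometry, medium, particle, cp, tp)


def save_config(config: SimulationConfig, path) -> None:
    """Write a configuration to YAML (customary units)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _config_from_dict(data)


def load_preset(name: str = DEFAULT_PRESET) -> SimulationConfig:
    """Load a packaged preset configuration by name.

    ``water_lipid_50mhz`` pins the 50 MHz, 25x25-element array with a lipid
    sphere in water (the study conditions used throughout the docs).
    """
    ref = resources.files("acoustrap.presets").joinpath(f"{name}.yaml")
    with ref.open() as fh:
        data = yaml.safe_load(fh)
    return _config_from_dict(data)
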