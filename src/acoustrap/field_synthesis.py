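"""Multi-focus field synthesis for a 2-D phased array.

Pipeline: discretize each array element into sub-sources, assemble the
Rayleigh-Sommerfeld propagation matrix H mapping per-element excitations
(uniform normal velocities, steady-state phasors with the e^{j omega t}
factor dropped and e^{-jkr} propagation) to complex pressures at the control
points, solve the underdetermined system p = H U by the SVD pseudoinverse
(plain, and iteratively re-weighted to equalize element drive), and render
pressure / intensity on arbitrary grids by the same discretized integral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from .core_types import (
    ArrayGeometry,
    ConfigurationError,
    Medium,
    SimulationConfig,
    WaveParams,
)

__all__ = [
    "ControlPointSet",
    "PropagationMatrix",
    "ExcitationVector",
    "FieldGrid",
    "FieldSynthesisError",
    "build_propagation_matrix",
    "solve_excitation",
    "solve_excitation_weighted",
    "compute_pressure_field",
    "compute_pressure_at",
    "compute_intensity",
    "source_plane_power",
    "normalize_to_peak_intensity",
    "normalize_to_source_power",
]

#: Default sub-sources per element edge: 22 um / 4 = 5.5 um <= lambda/4 at 50 MHz.
DEFAULT_SUBDIVISION = 4

#: Relative singular-value cutoff below which H is treated as rank deficient.
SV_CUTOFF = 1e-8

_POINT_CHUNK = 512  # grid points per distance-matrix block (memory bound)


class FieldSynthesisError(RuntimeError):
    """Geometry or solver failure during field synthesis."""


@dataclass(frozen=True)
class ControlPointSet:
    """Focal control points q_m (z > 0) and their target pressures p (Pa)."""

    points: np.ndarray  # (M, 3) m
    target_pressures: np.ndarray  # (M,) complex

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        tp = np.atleast_1d(np.asarray(self.target_pressures, dtype=complex))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ConfigurationError("control points must be (M, 3)")
        if np.any(pts[:, 2] <= 0):
            raise FieldSynthesisError("control points must lie at z > 0")
        if tp.shape != (len(pts),):
            raise ConfigurationError("one target pressure per control point")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "target_pressures", tp)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "ControlPointSet":
        if config.control_points is None:
            raise ConfigurationError("configuration has no focal_points section")
        return cls(config.control_points, config.target_pressures)


def _sub_sources(
    geometry: ArrayGeometry, wave: WaveParams, n_sub: int
) -> tuple[np.ndarray, float]:
    """Midpoint-rule sub-source centres for every element.

    Returns ``(points, area)`` with ``points`` of shape (N, n_sub^2, 3) and
    ``area`` the quadrature patch area. Refuses spacings coarser than
    lambda/2 (spatial aliasing of the discretized integral).
    """
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    spacing = geometry.element_width / n_sub
    if spacing > wave.wavelength / 2.0:
        raise FieldSynthesisError(
            f"sub-source spacing {spacing * 1e6:.2f} um exceeds lambda/2 = "
            f"{wave.wavelength / 2 * 1e6:.2f} um; increase the subdivision"
        )
    w = geometry.element_width
    offsets_1d = (np.arange(n_sub) + 0.5) / n_sub * w - w / 2.0
    ox, oy = np.meshgrid(offsets_1d, offsets_1d, indexing="xy")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), np.zeros(n_sub * n_sub)])
    centers = geometry.element_centers()  # (N, 3)
    points = centers[:, None, :] + offsets[None, :, :]
    return points, spacing * spacing


def _rayleigh_coefficient(wave: WaveParams, medium: Medium) -> complex:
    # j rho0 c / lambda, the monopole strength of a baffled velocity source
    return 1j * medium.density * medium.sound_speed / wave.wavelength


@dataclass(frozen=True)
class PropagationMatrix:
    """Discretized forward operator H (M x N) plus its quadrature layout."""

    entries: np.ndarray  # (M, N) complex
    control_points: ControlPointSet
    geometry: ArrayGeometry
    wave: WaveParams
    medium: Medium
    n_sub: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


def build_propagation_matrix(
    geometry: ArrayGeometry,
    wave: WaveParams,
    medium: Medium,
    points: ControlPointSet,
    n_sub: int = DEFAULT_SUBDIVISION,
) -> PropagationMatrix:
    """Assemble H(m, n): propagation from element n to control point m.

    Each entry is the midpoint-quadrature Rayleigh integral
    ``j rho0 c / lambda * sum_s e^{-jk r_ms} / r_ms * dS`` over element n's
    surface.
    """
    sub, area = _sub_sources(geometry, wave, n_sub)  # (N, S, 3)
    q = points.points  # (M, 3)
    flat = sub.reshape(-1, 3)
    d = np.sqrt(
        np.maximum(
            (q**2).sum(1)[:, None]
            + (flat**2).sum(1)[None, :]
            - 2.0 * q @ flat.T,
            0.0,
        )
    )
    if np.any(d == 0.0):
        raise FieldSynthesisError("control point coincides with a source point")
    kern = np.exp(-1j * wave.wavenumber * d) / d
    kern = kern.reshape(len(q), sub.shape[0], sub.shape[1]).sum(axis=2)
    H = _rayleigh_coefficient(wave, medium) * area * kern
    return PropagationMatrix(H, points, geometry, wave, medium, n_sub)


@dataclass(frozen=True)
class ExcitationVector:
    """Per-element complex drive (normal velocity, m/s) solved from p = H U."""

    values: np.ndarray  # (N,) complex
    weighting: np.ndarray  # (N,) positive diagonal of W
    scale: float = 1.0  # global amplitude factor applied after solving
    residual: float = 0.0  # ||H u - p|| / ||p|| at solve time
    n_iterations: int = 0
    converged: bool = True

    @property
    def amplitude_spread(self) -> float:
        """max |u_n| / min |u_n| -- 1.0 means perfectly uniform drive."""
        a = np.abs(self.values)
        lo = a.min()
        return float(a.max() / lo) if lo > 0 else math.inf

    def scaled(self, factor: float) -> "ExcitationVector":
        return ExcitationVector(
            self.values * factor,
            self.weighting,
            self.scale * factor,
            self.residual,
            self.n_iterations,
            self.converged,
        )


def _min_norm_solve(H: np.ndarray, p: np.ndarray, cutoff: float) -> np.ndarray:
    """Minimum-norm solution U = H^H (H H^H)^{-1} p through the SVD."""
    U_l, s, Vh = np.linalg.svd(H, full_matrices=False)
    if s[0] == 0.0:
        raise FieldSynthesisError("propagation matrix is identically zero")
    ok = s > cutoff * s[0]
    rank = int(ok.sum())
    if rank < H.shape[0]:
        raise FieldSynthesisError(
            f"propagation matrix is rank deficient: rank {rank} < "
            f"{H.shape[0]} control points (singular values below cutoff)"
        )
    return Vh.conj().T @ ((U_l.conj().T @ p) / s)


def _residual(H: np.ndarray, u: np.ndarray, p: np.ndarray) -> float:
    denom = np.linalg.norm(p)
    if denom == 0.0:
        return float(np.linalg.norm(H @ u))
    return float(np.linalg.norm(H @ u - p) / denom)


def solve_excitation(
    H: PropagationMatrix,
    points: ControlPointSet | None = None,
    sv_cutoff: float = SV_CUTOFF,
) -> ExcitationVector:
    """Unweighted generalized-inverse excitation U = H^H (H H^H)^{-1} p."""
    pts = points if points is not None else H.control_points
    p = pts.target_pressures
    u = _min_norm_solve(H.entries, p, sv_cutoff)
    return ExcitationVector(
        values=u,
        weighting=np.ones(H.shape[1]),
        residual=_residual(H.entries, u, p),
    )


def _efficiency_weights(u: np.ndarray) -> np.ndarray:
    """One re-weighting step toward uniform element drive.

    Weighted minimum-norm with W = diag(w) minimizes sum |u_n|^2 / w_n, so
    weights inversely proportional to the previous amplitudes penalize the
    loudest elements hardest and drive the solution toward equal |u_n|
    (the excitation-efficiency-maximizing weighting). Normalized to unit
    trace; the floor guards elements that solve to ~zero drive.
    """
    a = np.abs(u)
    floor = 1e-6 * a.max()
    w = 1.0 / np.maximum(a, floor)
    return w / w.sum() * len(w)


def solve_excitation_weighted(
    H: PropagationMatrix,
    points: ControlPointSet | None = None,
    max_iter: int = 20,
    tol: float = 1e-4,
    sv_cutoff: float = SV_CUTOFF,
) -> ExcitationVector:
    """Iteratively weighted pseudoinverse U = W H^H (H W H^H)^{-1} p.

    W starts as the identity (iteration 0 reproduces
    :func:`solve_excitation` exactly) and is re-estimated from the previous
    iterate by :func:`_efficiency_weights` until the amplitude spread
    max|u|/min|u| stops changing by more than ``tol`` (relatively) or
    ``max_iter`` is reached.  Every iterate satisfies H U = p by
    construction; the returned iterate is the one with the smallest spread.
    """
    pts = points if points is not None else H.control_points
    p = pts.target_pressures
    A = H.entries
    w = np.ones(A.shape[1])
    u = _min_norm_solve(A, p, sv_cutoff)
    best_u, best_w = u, w
    best_spread = _spread(u)
    converged = max_iter == 0
    n_done = 0
    for it in range(max_iter):
        w = _efficiency_weights(u)
        sqrt_w = np.sqrt(w)
        v = _min_norm_solve(A * sqrt_w[None, :], p, sv_cutoff)
        u = sqrt_w * v
        n_done = it + 1
        spread = _spread(u)
        if spread < best_spread:
            best_u, best_w, prev_best = u, w, best_spread
            if abs(prev_best - spread) <= tol * prev_best:
                best_spread = spread
                converged = True
                break
            best_spread = spread
        else:
            # spread no longer improving -> converged to the uniform-drive
            # fixed point within the achievable limit
            converged = True
            break
    return ExcitationVector(
        values=best_u,
        weighting=best_w,
        residual=_residual(A, best_u, p),
        n_iterations=n_done,
        converged=converged,
    )


def _spread(u: np.ndarray) -> float:
    a = np.abs(u)
    lo = a.min()
    return float(a.max() / lo) if lo > 0 else math.inf


# ---------------------------------------------------------------------------
# Field rendering
# ---------------------------------------------------------------------------


@dataclass
class FieldGrid:
    """Complex pressure sampled on a separable (x, y, z) grid.

    ``pressure`` has shape (len(x), len(y), len(z)); intensity is derived
    pointwise as |p|^2 / (2 rho0 c) and therefore always satisfies the
    non-negativity and quadratic-scaling invariants.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    pressure: np.ndarray
    frequency: float
    medium: Medium
    _intensity: np.ndarray | None = field(default=None, repr=False)

    @property
    def intensity(self) -> np.ndarray:
        """Time-averaged intensity |p|^2 / (2 rho0 c), W/m^2."""
        if self._intensity is None:
            self._intensity = compute_intensity(self.pressure, self.medium)
        return self._intensity

    def rescale_pressure(self, factor: float) -> "FieldGrid":
        return FieldGrid(
            self.x, self.y, self.z, self.pressure * factor,
            self.frequency, self.medium,
        )

    def to_hdf5(self, path, **attrs) -> None:
        """Write axes, complex pressure and intensity with unit attributes."""
        with h5py.File(path, "w") as fh:
            for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
                d = fh.create_dataset(name, data=arr)
                d.attrs["units"] = "m"
            d = fh.create_dataset("pressure", data=self.pressure)
            d.attrs["units"] = "Pa"
            d = fh.create_dataset("intensity", data=self.intensity)
            d.attrs["units"] = "W/m^2"
            fh.attrs["frequency_hz"] = self.frequency
            fh.attrs["medium_density_kg_m3"] = self.medium.density
            fh.attrs["medium_sound_speed_m_s"] = self.medium.sound_speed
            for k, v in attrs.items():
                fh.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "FieldGrid":
        with h5py.File(path, "r") as fh:
            medium = Medium(
                density=float(fh.attrs["medium_density_kg_m3"]),
                sound_speed=float(fh.attrs["medium_sound_speed_m_s"]),
            )
            return cls(
                x=fh["x"][:], y=fh["y"][:], z=fh["z"][:],
                pressure=fh["pressure"][:],
                frequency=float(fh.attrs["frequency_hz"]),
                medium=medium,
            )


def compute_pressure_at(
    geometry: ArrayGeometry,
    wave: WaveParams,
    medium: Medium,
    excitation: ExcitationVector,
    points: np.ndarray,
    n_sub: int = DEFAULT_SUBDIVISION,
) -> np.ndarray:
    """Steady-state complex pressure at arbitrary points (P, 3), in Pa.

    Sums the sub-source Rayleigh kernels weighted by the element
    excitations; linear in the excitation vector.
    """
    sub, area = _sub_sources(geometry, wave, n_sub)
    n_elem, n_s, _ = sub.shape
    sources = sub.reshape(-1, 3)
    weights = (
        _rayleigh_coefficient(wave, medium)
        * area
        * np.repeat(excitation.values, n_s)
    )
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    s2 = (sources**2).sum(1)
    k = wave.wavenumber
    out = np.empty(len(pts), dtype=complex)
    for i in range(0, len(pts), _POINT_CHUNK):
        q = pts[i : i + _POINT_CHUNK]
        d2 = (q**2).sum(1)[:, None] + s2[None, :] - 2.0 * q @ sources.T
        d = np.sqrt(np.maximum(d2, 0.0))
        if np.any(d == 0.0):
            raise FieldSynthesisError(
                "field point coincides with a source point (r = 0)"
            )
        out[i : i + _POINT_CHUNK] = (np.exp(-1j * k * d) / d) @ weights
    return out


def compute_pressure_field(
    geometry: ArrayGeometry,
    wave: WaveParams,
    medium: Medium,
    excitation: ExcitationVector,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    n_sub: int = DEFAULT_SUBDIVISION,
) -> FieldGrid:
    """Render the pressure field on the separable grid x cross y cross z."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    for ax in (x, y, z):
        if len(ax) > 1 and np.any(np.diff(ax) <= 0):
            raise ConfigurationError("grid axes must be strictly increasing")
    if np.any(z <= 0):
        raise FieldSynthesisError("field grid must lie in the z > 0 half-space")
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    p = compute_pressure_at(geometry, wave, medium, excitation, pts, n_sub)
    return FieldGrid(
        x=x, y=y, z=z,
        pressure=p.reshape(len(x), len(y), len(z)),
        frequency=wave.frequency,
        medium=medium,
    )


def compute_intensity(pressure: np.ndarray, medium: Medium) -> np.ndarray:
    """Pointwise plane-progressive intensity I = p p* / (2 rho0 c), W/m^2."""
    return (pressure * np.conj(pressure)).real / (
        2.0 * medium.density * medium.sound_speed
    )


# ---------------------------------------------------------------------------
# Normalization modes
# ---------------------------------------------------------------------------


def source_plane_power(
    geometry: ArrayGeometry, medium: Medium, excitation: ExcitationVector
) -> float:
    """Radiated acoustic power, W, in the baffled plane-piston approximation.

    P = sum_n (1/2) rho0 c |u_n|^2 A_n.  Invariant under phase-only changes
    of the excitation; mutual radiation impedance between elements is
    neglected (elements are ~0.7 lambda across).
    """
    area = geometry.element_width * geometry.element_height
    return float(
        0.5
        * medium.density
        * medium.sound_speed
        * area
        * np.sum(np.abs(excitation.values) ** 2)
    )


def normalize_to_peak_intensity(
    excitation: ExcitationVector,
    peak_intensity: float,
    target: float = 150e4,  # W/m^2  (150 W/cm^2)
) -> ExcitationVector:
    """Rescale so the given spatial peak intensity becomes ``target``."""
    if peak_intensity <= 0:
        raise ValueError("peak intensity must be positive")
    return excitation.scaled(math.sqrt(target / peak_intensity))


def normalize_to_source_power(
    excitation: ExcitationVector,
    geometry: ArrayGeometry,
    medium: Medium,
    target_power: float = 4.25e-3,  # W
) -> ExcitationVector:
    """Rescale so the source-plane acoustic power equals ``target_power``."""
    p0 = source_plane_power(geometry, medium, excitation)
    if p0 <= 0:
        raise ValueError("excitation radiates no power")
    return excitation.scaled(math.sqrt(target_power / p0))
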