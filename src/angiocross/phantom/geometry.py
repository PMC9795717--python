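"""Analytic primitives for vessel phantoms.

All coordinates are world coordinates in micrometres.  A phantom is built
from implicit "inside" functions f(p) that are negative inside the solid,
zero on its surface and positive outside (a signed-distance-like field;
exact distances are not required, only monotone behaviour near the
surface).  The endothelial signal is the shell of the union solid:
``-wall_thickness < f_union <= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SproutSpec",
    "EllipsoidSpec",
    "analytic_mean_curvature",
    "unit",
    "rotation_matrix",
]


def unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


def rotation_matrix(axis, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation about ``axis`` by ``angle_rad``."""
    u = unit(axis)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


@dataclass
class SproutSpec:
    """A sprout branching from the parent vessel wall.

    The sprout is a capped cone from ``base_point`` (on the outer vessel
    surface) along ``direction`` with linearly interpolated radius and an
    optional sinusoidal radial roughness term::

        r(s) = base_radius + (tip_radius - base_radius) * s / length
               + roughness_amplitude * sin(2 pi s / roughness_wavelength)

    Units: micrometres throughout.
    """

    base_point: tuple[float, float, float]
    direction: tuple[float, float, float]
    length: float
    base_radius: float = 40.0
    tip_radius: float = 25.0
    roughness_amplitude: float = 0.0
    roughness_wavelength: float = 40.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("sprout length must be positive")
        if self.base_radius <= 0 or self.tip_radius <= 0:
            raise ValueError("sprout radii must be positive")
        if self.roughness_amplitude < 0:
            raise ValueError("roughness amplitude must be non-negative")
        if self.roughness_amplitude >= min(self.base_radius, self.tip_radius):
            raise ValueError("roughness amplitude must be smaller than the radii")
        self.direction = tuple(unit(self.direction))

    def radius_at(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        r = self.base_radius + (self.tip_radius - self.base_radius) * s / self.length
        if self.roughness_amplitude > 0:
            r = r + self.roughness_amplitude * np.sin(
                2 * np.pi * s / self.roughness_wavelength
            )
        return r

    def radius_slope_at(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        dr = np.full_like(s, (self.tip_radius - self.base_radius) / self.length)
        if self.roughness_amplitude > 0:
            dr = dr + (
                self.roughness_amplitude
                * 2
                * np.pi
                / self.roughness_wavelength
                * np.cos(2 * np.pi * s / self.roughness_wavelength)
            )
        return dr

    def implicit(self, pts: np.ndarray) -> np.ndarray:
        """Inside function; ``pts`` is (..., 3) world μm."""
        b = np.asarray(self.base_point, dtype=float)
        u = np.asarray(self.direction, dtype=float)
        d = pts - b
        s = d @ u
        rho = np.linalg.norm(d - s[..., None] * u, axis=-1)
        f = rho - self.radius_at(np.clip(s, 0.0, self.length))
        return np.maximum(f, np.maximum(-s, s - self.length))


@dataclass
class EllipsoidSpec:
    """A rigid MSC body: an ellipsoid with principal semi-axes in μm.

    ``axis`` and ``angle_deg`` orient the ellipsoid: the body frame is the
    world frame rotated by ``angle_deg`` about ``axis``.  ``attached_to``
    records (as ground truth only) which structure the cell sits on:
    ``None``, ``"parent"`` or ``"sprout_<i>"``.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    angle_deg: float = 0.0
    attached_to: str | None = None

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("ellipsoid semi-axes must be positive")

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.axis, np.deg2rad(self.angle_deg))

    def contains(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        q = (pts - c) @ self.rotation  # world -> body frame
        a = np.asarray(self.semi_axes, dtype=float)
        return np.sum((q / a) ** 2, axis=-1) <= 1.0


def analytic_mean_curvature(kind: str, radius: float | None = None) -> float:
    """Closed-form mean curvature of a primitive surface, in μm⁻¹.

    Sign convention (matching the mesh curvature pipeline): a surface
    bulging outward from the enclosed solid (convex) has negative mean
    curvature, a concave pit positive, a plane zero.  Hence a solid sphere
    of radius r has H = -1/r on its surface and the lateral surface of a
    solid cylinder has H = -1/(2r).

    Parameters
    ----------
    kind : {"plane", "sphere", "cylinder"}
    radius : float, required for sphere and cylinder, μm.
    """
    if kind == "plane":
        return 0.0
    if kind not in ("sphere", "cylinder"):
        raise ValueError(f"unknown primitive kind: {kind!r}")
    if radius is None or radius <= 0:
        raise ValueError("radius must be positive for curved primitives")
    if kind == "sphere":
        return -1.0 / radius
    return -1.0 / (2.0 * radius)
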