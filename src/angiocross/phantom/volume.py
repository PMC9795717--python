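"""Synthetic 3D vessel phantoms with voxel-level ground truth.

The phantom emulates the geometry of a needle-templated microvessel chip:
a horizontal parent vessel (~200 μm diameter endothelial tube), sprouts
branching from its wall, and ellipsoidal MSC bodies resting on the
surfaces.  The red channel is the endothelial wall shell (a hollow tube,
not a filled cylinder), green the MSC solids, blue nuclei.  Optics are a
Gaussian PSF followed by Poisson photon noise and Gaussian read noise.

Everything is derived from implicit solids, so the generator can also
report exact ground truth: voxel labels, analytic curvatures, and the
true MSC-contact fraction of every surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..containers import VolumeStack
from .geometry import EllipsoidSpec, SproutSpec, analytic_mean_curvature, unit

LABEL_BACKGROUND = 0
LABEL_LUMEN = 1
LABEL_PARENT_WALL = 2
LABEL_SPROUT_BASE = 3  # sprout i -> 3 + i; MSC j -> 3 + n_sprouts + j


@dataclass
class PhantomSpec3D:
    """Parameters of a 3D vessel phantom.

    Lengths in μm.  ``domain_size`` and ``voxel_size`` are (x, y, z).
    The parent vessel runs along ``vessel_axis`` through the domain
    centre; its outer radius is ``vessel_radius`` (default 100 μm, the
    needle template radius) and the endothelium is rendered as a
    ``wall_thickness``-thick shell.
    """

    vessel_radius: float = 100.0
    vessel_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    domain_size: tuple[float, float, float] = (400.0, 400.0, 400.0)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    wall_thickness: float = 10.0
    sprouts: list[SproutSpec] = field(default_factory=list)
    msc_objects: list[EllipsoidSpec] = field(default_factory=list)
    psf_sigma: float = 0.0
    noise: tuple[float, float] = (0.0, 0.0)  # (gaussian_sd, poisson_scale)
    n_ec_nuclei: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vessel_radius <= 0 or self.wall_thickness <= 0:
            raise ValueError("vessel radius and wall thickness must be positive")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel sizes must be positive")
        if min(self.domain_size) <= 0:
            raise ValueError("domain sizes must be positive")
        if self.psf_sigma < 0 or min(self.noise) < 0:
            raise ValueError("psf sigma and noise levels must be non-negative")
        self.vessel_axis = tuple(unit(self.vessel_axis))

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.domain_size, dtype=float) / 2.0

    def grid_shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx) voxel counts."""
        nx = int(round(self.domain_size[0] / self.voxel_size[0]))
        ny = int(round(self.domain_size[1] / self.voxel_size[1]))
        nz = int(round(self.domain_size[2] / self.voxel_size[2]))
        return nz, ny, nx

    def nearest_structure(self, points: np.ndarray) -> np.ndarray:
        """Classify world points by nearest primitive: 0 parent, 1+i sprout i.

        Uses the implicit inside-functions, so it is an analytic ground
        truth for which structure a surface point belongs to.
        """
        pts = np.asarray(points, dtype=float)
        u = np.asarray(self.vessel_axis)
        d = pts - self.center
        s = d @ u
        best = np.linalg.norm(d - s[..., None] * u, axis=-1) - self.vessel_radius
        out = np.zeros(pts.shape[:-1], dtype=int)
        for i, sp in enumerate(self.sprouts):
            f = sp.implicit(pts)
            closer = f < best
            out[closer] = i + 1
            best = np.minimum(best, f)
        return out

    def validate_geometry(self) -> None:
        u = np.asarray(self.vessel_axis)
        c = self.center
        tol = max(self.voxel_size)
        for i, sp in enumerate(self.sprouts):
            b = np.asarray(sp.base_point, dtype=float)
            d = b - c
            rho = np.linalg.norm(d - (d @ u) * u)
            if abs(rho - self.vessel_radius) > tol:
                raise ValueError(
                    f"sprout {i}: base point is {rho:.1f} μm from the axis, "
                    f"not on the vessel surface (R={self.vessel_radius:.1f} μm)"
                )
            tip = b + sp.length * np.asarray(sp.direction)
            margin = sp.tip_radius
            if np.any(tip - margin < 0) or np.any(
                tip + margin > np.asarray(self.domain_size)
            ):
                raise ValueError(
                    f"sprout {i} extends outside the domain (tip at {tip})"
                )


@dataclass
class GroundTruth3D:
    """Exact ground truth accompanying a rasterized 3D phantom.

    ``labels`` partitions the voxel grid: 0 background, 1 lumen,
    2 parent wall, 3+i the wall of sprout i, followed by one label per
    MSC body (outside the vessel solid).  Curvatures are the closed-form
    values of the underlying primitives.  Coverage fractions are
    area-weighted fractions of each outer surface lying inside an MSC
    ellipsoid, computed from the analytic geometry (not from voxels).
    """

    labels: np.ndarray
    label_names: dict[int, str]
    voxel_size: tuple[float, float, float]
    curvature: dict[str, float]
    coverage_fraction: dict[str, float]
    surface_area: dict[str, float]
    covered_area: dict[str, float]
    sprout_tips: list[np.ndarray]
    msc_centers: np.ndarray

    @property
    def overall_coverage(self) -> float:
        """Area-weighted MSC-contact fraction of the whole outer surface."""
        total = sum(self.surface_area.values())
        return sum(self.covered_area.values()) / total if total > 0 else 0.0

    def label_id(self, name: str) -> int:
        for k, v in self.label_names.items():
            if v == name:
                return k
        raise KeyError(name)


def _world_axes(spec: PhantomSpec3D):
    nz, ny, nx = spec.grid_shape()
    dx, dy, dz = spec.voxel_size
    x = (np.arange(nx, dtype=np.float32) + 0.5) * dx
    y = (np.arange(ny, dtype=np.float32) + 0.5) * dy
    z = (np.arange(nz, dtype=np.float32) + 0.5) * dz
    return (
        x.reshape(1, 1, nx),
        y.reshape(1, ny, 1),
        z.reshape(nz, 1, 1),
    )


def vessel_implicit(spec: PhantomSpec3D, X, Y, Z) -> np.ndarray:
    """Inside function of the solid parent vessel (negative inside)."""
    u = np.asarray(spec.vessel_axis, dtype=np.float32)
    c = spec.center.astype(np.float32)
    px, py, pz = X - c[0], Y - c[1], Z - c[2]
    s = px * u[0] + py * u[1] + pz * u[2]
    rho2 = (px - s * u[0]) ** 2 + (py - s * u[1]) ** 2 + (pz - s * u[2]) ** 2
    return np.sqrt(rho2) - np.float32(spec.vessel_radius)


def _sprout_implicit(sp: SproutSpec, X, Y, Z) -> np.ndarray:
    b = np.asarray(sp.base_point, dtype=np.float32)
    u = np.asarray(sp.direction, dtype=np.float32)
    px, py, pz = X - b[0], Y - b[1], Z - b[2]
    s = px * u[0] + py * u[1] + pz * u[2]
    rho2 = (px - s * u[0]) ** 2 + (py - s * u[1]) ** 2 + (pz - s * u[2]) ** 2
    r = sp.radius_at(np.clip(s, 0.0, sp.length)).astype(np.float32)
    f = np.sqrt(rho2) - r
    return np.maximum(f, np.maximum(-s, s - np.float32(sp.length)))


def _ellipsoid_inside(e: EllipsoidSpec, X, Y, Z) -> np.ndarray:
    R = e.rotation.astype(np.float32)  # columns: body axes in world frame
    c = np.asarray(e.center, dtype=np.float32)
    a = np.asarray(e.semi_axes, dtype=np.float32)
    px, py, pz = X - c[0], Y - c[1], Z - c[2]
    q = np.zeros(np.broadcast_shapes(px.shape, py.shape, pz.shape), np.float32)
    for k in range(3):
        comp = (px * R[0, k] + py * R[1, k] + pz * R[2, k]) / a[k]
        q += comp * comp
    return q <= 1.0


def _sphere_inside(center, radius, X, Y, Z) -> np.ndarray:
    c = np.asarray(center, dtype=np.float32)
    d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
    return d2 <= np.float32(radius) ** 2


def apply_imaging(
    img: np.ndarray,
    voxel_size,
    psf_sigma: float,
    noise: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian PSF blur, then Poisson photon noise, then Gaussian read noise."""
    out = img.astype(np.float32)
    if psf_sigma > 0:
        dx, dy, dz = voxel_size
        out = ndimage.gaussian_filter(
            out, sigma=(psf_sigma / dz, psf_sigma / dy, psf_sigma / dx)
        )
    gaussian_sd, poisson_scale = noise
    if poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * poisson_scale).astype(
            np.float32
        ) / np.float32(poisson_scale)
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, size=out.shape).astype(np.float32)
    return out


def _surface_coverage(spec: PhantomSpec3D, n_axial: int = 240, n_theta: int = 96):
    """Area-weighted MSC contact on each outer surface, analytically.

    Surfaces are sampled on (axial, angular) grids: the parent lateral
    surface with area element R dθ ds, excluding patches engulfed by a
    sprout solid or outside the domain; each sprout lateral surface with
    element r(s)·sqrt(1 + r'(s)²) dθ ds, excluding the part inside the
    parent solid.  Returns (fraction, area μm², covered area μm²) dicts
    keyed by structure.
    """
    u = np.asarray(spec.vessel_axis, dtype=float)
    c = spec.center
    # orthonormal frame (u, e1, e2)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(ref @ u) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(u, ref))
    e2 = np.cross(u, e1)

    def covered(pts):
        hit = np.zeros(pts.shape[:-1], dtype=bool)
        for e in spec.msc_objects:
            hit |= e.contains(pts)
        return hit

    frac: dict[str, float] = {}
    area: dict[str, float] = {}
    cov: dict[str, float] = {}

    half = min(np.asarray(spec.domain_size) @ np.abs(u), max(spec.domain_size)) / 2.0
    s_par = np.linspace(-half, half, n_axial)
    ds_par = s_par[1] - s_par[0]
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    dth = th[1] - th[0]
    S, T = np.meshgrid(s_par, th, indexing="ij")
    pts = (
        c
        + S[..., None] * u
        + spec.vessel_radius
        * (np.cos(T)[..., None] * e1 + np.sin(T)[..., None] * e2)
    )
    keep = np.ones(pts.shape[:-1], dtype=bool)
    for sp in spec.sprouts:
        b = np.asarray(sp.base_point, dtype=float)
        us = np.asarray(sp.direction, dtype=float)
        d = pts - b
        ss = d @ us
        rho = np.linalg.norm(d - ss[..., None] * us, axis=-1)
        inside = (ss >= 0) & (ss <= sp.length) & (
            rho <= sp.radius_at(np.clip(ss, 0, sp.length))
        )
        keep &= ~inside
    keep &= np.all((pts >= 0) & (pts <= np.asarray(spec.domain_size)), axis=-1)
    hit = covered(pts)
    cell = spec.vessel_radius * dth * ds_par
    area["parent"] = float(keep.sum() * cell)
    cov["parent"] = float((keep & hit).sum() * cell)
    frac["parent"] = cov["parent"] / area["parent"] if area["parent"] > 0 else 0.0

    # the imaging volume cuts the vessel at two domain faces; the meshed
    # solid closes there with disk caps, which belong to the total area
    area["caps"] = float(2.0 * np.pi * spec.vessel_radius**2)
    cov["caps"] = 0.0
    frac["caps"] = 0.0

    for i, sp in enumerate(spec.sprouts):
        b = np.asarray(sp.base_point, dtype=float)
        us = np.asarray(sp.direction, dtype=float)
        ref2 = e1 if abs(e1 @ us) < 0.9 else e2
        f1 = unit(np.cross(us, ref2))
        f2 = np.cross(us, f1)
        s = np.linspace(0, sp.length, n_axial)
        ds = s[1] - s[0]
        S, T = np.meshgrid(s, th, indexing="ij")
        r = sp.radius_at(S)
        pts = (
            b
            + S[..., None] * us
            + r[..., None] * (np.cos(T)[..., None] * f1 + np.sin(T)[..., None] * f2)
        )
        w = r * np.sqrt(1.0 + sp.radius_slope_at(S) ** 2) * dth * ds
        d = pts - c
        ss = d @ u
        rho = np.linalg.norm(d - ss[..., None] * u, axis=-1)
        keep = rho > spec.vessel_radius  # outside the parent solid
        hit = covered(pts)
        key = f"sprout_{i}"
        area[key] = float(w[keep].sum())
        cov[key] = float(w[keep & hit].sum())
        # flat tip cap at s = length
        r_tip = float(sp.radius_at(sp.length))
        rho = np.linspace(0, r_tip, 32)
        Rho, T = np.meshgrid(rho, th, indexing="ij")
        tip_pts = (
            b
            + sp.length * us
            + Rho[..., None] * (np.cos(T)[..., None] * f1 + np.sin(T)[..., None] * f2)
        )
        w_tip = Rho * (rho[1] - rho[0]) * dth
        tip_hit = covered(tip_pts)
        area[key] += float(w_tip.sum())
        cov[key] += float(w_tip[tip_hit].sum())
        frac[key] = cov[key] / area[key] if area[key] > 0 else 0.0
    return frac, area, cov


def solid_sphere_mask(radius: float, voxel_size: float, margin: float = 5.0):
    """Voxelized solid sphere (oracle phantom); returns a (z, y, x) bool array."""
    n = int(np.ceil(2 * (radius + margin) / voxel_size))
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(np.float32)
    c = n / 2.0
    d2 = (xx + 0.5 - c) ** 2 + (yy + 0.5 - c) ** 2 + (zz + 0.5 - c) ** 2
    return d2 * voxel_size**2 <= radius**2


def solid_cylinder_mask(
    radius: float, length: float, voxel_size: float, margin: float = 5.0
):
    """Voxelized solid cylinder along x (oracle phantom), (z, y, x) bool."""
    nyz = int(np.ceil(2 * (radius + margin) / voxel_size))
    nx = int(np.ceil(length / voxel_size))
    zz, yy = np.mgrid[0:nyz, 0:nyz].astype(np.float32)
    c = nyz / 2.0
    d2 = (yy + 0.5 - c) ** 2 + (zz + 0.5 - c) ** 2
    disk = d2 * voxel_size**2 <= radius**2
    return np.broadcast_to(disk[:, :, None], (nyz, nyz, nx)).copy()


def make_vessel_phantom_3d(spec: PhantomSpec3D) -> tuple[VolumeStack, GroundTruth3D]:
    """Rasterize a 3D phantom and its exact ground truth.

    The red channel is the wall shell of the union solid
    (vessel ∪ sprouts): voxels with ``-wall_thickness < f_union <= 0``.
    Deterministic given ``spec.seed``.
    """
    spec.validate_geometry()
    rng = np.random.default_rng(spec.seed)
    X, Y, Z = _world_axes(spec)

    f_union = vessel_implicit(spec, X, Y, Z)
    which = np.zeros(f_union.shape, dtype=np.uint8)  # 0 = parent vessel
    for i, sp in enumerate(spec.sprouts):
        f_sp = _sprout_implicit(sp, X, Y, Z)
        closer = f_sp < f_union
        which[closer] = i + 1
        np.minimum(f_union, f_sp, out=f_union)

    shell = (f_union > -spec.wall_thickness) & (f_union <= 0)
    lumen = f_union <= -spec.wall_thickness

    labels = np.zeros(f_union.shape, dtype=np.uint8)
    labels[lumen] = LABEL_LUMEN
    labels[shell & (which == 0)] = LABEL_PARENT_WALL
    for i in range(len(spec.sprouts)):
        labels[shell & (which == i + 1)] = LABEL_SPROUT_BASE + i

    green_mask = np.zeros(f_union.shape, dtype=bool)
    n_spr = len(spec.sprouts)
    msc_centers = []
    for j, e in enumerate(spec.msc_objects):
        inside = _ellipsoid_inside(e, X, Y, Z)
        green_mask |= inside
        labels[inside & (labels == LABEL_BACKGROUND)] = LABEL_SPROUT_BASE + n_spr + j
        msc_centers.append(np.asarray(e.center, dtype=float))

    blue_mask = np.zeros(f_union.shape, dtype=bool)
    for e in spec.msc_objects:
        blue_mask |= _sphere_inside(e.center, 0.4 * min(e.semi_axes), X, Y, Z)
    if spec.n_ec_nuclei > 0:
        u = np.asarray(spec.vessel_axis)
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = unit(np.cross(u, ref))
        e2 = np.cross(u, e1)
        half = max(spec.domain_size) / 2.0
        for _ in range(spec.n_ec_nuclei):
            s = rng.uniform(-half, half)
            th = rng.uniform(0, 2 * np.pi)
            p = (
                spec.center
                + s * u
                + (spec.vessel_radius - spec.wall_thickness / 2.0)
                * (np.cos(th) * e1 + np.sin(th) * e2)
            )
            if np.all(p >= 0) and np.all(p <= np.asarray(spec.domain_size)):
                blue_mask |= _sphere_inside(p, 4.0, X, Y, Z)

    red = apply_imaging(
        shell.astype(np.float32), spec.voxel_size, spec.psf_sigma, spec.noise, rng
    )
    green = apply_imaging(
        green_mask.astype(np.float32), spec.voxel_size, spec.psf_sigma, spec.noise, rng
    )
    blue = apply_imaging(
        blue_mask.astype(np.float32), spec.voxel_size, spec.psf_sigma, spec.noise, rng
    )

    label_names = {
        LABEL_BACKGROUND: "background",
        LABEL_LUMEN: "lumen",
        LABEL_PARENT_WALL: "parent_wall",
    }
    curvature = {
        "parent": analytic_mean_curvature("cylinder", spec.vessel_radius),
    }
    tips = []
    for i, sp in enumerate(spec.sprouts):
        label_names[LABEL_SPROUT_BASE + i] = f"sprout_{i}"
        mean_r = 0.5 * (sp.base_radius + sp.tip_radius)
        curvature[f"sprout_{i}"] = analytic_mean_curvature("cylinder", mean_r)
        tips.append(
            np.asarray(sp.base_point, dtype=float)
            + sp.length * np.asarray(sp.direction, dtype=float)
        )
    for j in range(len(spec.msc_objects)):
        label_names[LABEL_SPROUT_BASE + n_spr + j] = f"msc_{j}"

    frac, area, cov = _surface_coverage(spec)
    gt = GroundTruth3D(
        labels=labels,
        label_names=label_names,
        voxel_size=spec.voxel_size,
        curvature=curvature,
        coverage_fraction=frac,
        surface_area=area,
        covered_area=cov,
        sprout_tips=tips,
        msc_centers=np.asarray(msc_centers, dtype=float).reshape(-1, 3),
    )
    vol = VolumeStack(red=red, green=green, blue=blue, voxel_size=spec.voxel_size)
    return vol, gt
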