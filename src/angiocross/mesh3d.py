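"""3D preprocessing, surface reconstruction and vertex tagging.

The 3D stage turns a confocal z-stack into a tagged triangular surface:
median filtering and global thresholding of the red channel, extraction
of the connected vessel-plus-sprouts structure, iso-surface meshing,
then two per-vertex segmentations — parent vessel vs sprout (via a
morphological parent-region estimate and a 10-voxel erosion of its
complement) and MSC-covered vs uncovered (via the binarized green
channel at each vertex's voxel).

Volumes are resampled to isotropic voxels before filtering and meshing
so that voxel-denominated operations (median neighbourhoods, the
"eroded by ten pixels" rule) are direction-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import filters, measure

from .containers import VolumeStack

C26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity structuring element


@dataclass
class BinaryMask:
    """A boolean 3D mask, indexed (z, y, x), with isotropic voxel size."""

    mask: np.ndarray
    voxel_size: float  # μm, isotropic

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)


@dataclass
class SurfaceMesh:
    """Triangular surface in world μm with per-vertex tags and curvature.

    ``region`` is 0 (parent) / 1 (sprout); ``covered`` marks vertices
    whose voxel holds positive binarized MSC signal; ``mean_curvature``
    is in μm⁻¹ with NaN at boundary/non-manifold vertices.  Tags default
    to all-parent / all-uncovered until the tagging passes run.
    """

    mesh: trimesh.Trimesh
    voxel_size: float
    region: np.ndarray = field(default=None)
    covered: np.ndarray = field(default=None)
    mean_curvature: np.ndarray = field(default=None)

    REGION_PARENT = 0
    REGION_SPROUT = 1

    def __post_init__(self) -> None:
        n = len(self.mesh.vertices)
        if self.region is None:
            self.region = np.zeros(n, dtype=np.uint8)
        if self.covered is None:
            self.covered = np.zeros(n, dtype=bool)
        if self.mean_curvature is None:
            self.mean_curvature = np.full(n, np.nan)

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self.mesh.faces)

    def vertex_voxels(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Map vertices to (z, y, x) voxel indices: floor(coord/size), clamped.

        Vertices of border-touching surfaces overshoot the grid by up to
        one voxel (meshing pads the volume); only overshoots beyond that
        are worth a warning.
        """
        idx = np.floor(self.vertices / self.voxel_size).astype(int)
        nz, ny, nx = shape
        lim = np.array([nx, ny, nz])
        far = (idx < -1) | (idx > lim)
        if far.any():
            warnings.warn(
                f"{int(far.any(axis=1).sum())} vertices map more than one voxel "
                "outside the grid; clamped"
            )
        out = np.empty_like(idx)
        out[:, 0] = np.clip(idx[:, 2], 0, nz - 1)
        out[:, 1] = np.clip(idx[:, 1], 0, ny - 1)
        out[:, 2] = np.clip(idx[:, 0], 0, nx - 1)
        return out


# ---------------------------------------------------------------------------
# mask construction


def resample_isotropic(vol: VolumeStack) -> VolumeStack:
    """Linearly resample all channels to the smallest voxel dimension."""
    dx, dy, dz = vol.voxel_size
    t = min(dx, dy, dz)
    if dx == dy == dz:
        return vol
    zoom = (dz / t, dy / t, dx / t)
    return VolumeStack(
        red=ndimage.zoom(vol.red, zoom, order=1),
        green=ndimage.zoom(vol.green, zoom, order=1),
        blue=ndimage.zoom(vol.blue, zoom, order=1),
        voxel_size=(t, t, t),
    )


def preprocess_volume(
    vol: VolumeStack,
    channel: str = "red",
    median_radius: int = 1,
    threshold: str | float = "otsu",
) -> BinaryMask:
    """3D median filter then global threshold of one channel.

    ``threshold`` is ``"otsu"`` or a fixed intensity; a fixed value can
    be reused across samples for comparable binarization settings.
    """
    iso = resample_isotropic(vol)
    img = iso.channel(channel).astype(np.float32)
    if median_radius > 0:
        img = ndimage.median_filter(img, size=2 * median_radius + 1)
    if threshold == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("constant channel; Otsu threshold undefined")
        thr = filters.threshold_otsu(img)
    else:
        thr = float(threshold)
    mask = img > thr
    if not mask.any():
        raise ValueError("thresholding produced an all-background mask")
    return BinaryMask(mask=mask, voxel_size=iso.voxel_size[0])


def fill_solid(bm: BinaryMask) -> BinaryMask:
    """Fill the lumen of a tubular wall mask, yielding the solid structure.

    A vessel-wall shell is hollow and its lumen opens at the volume
    faces, so plain 3D hole filling cannot close it.  Cross-sections
    perpendicular to the vessel axis (x by convention) are closed
    annuli, so each (z, y) slice is hole-filled in 2D first; a final 3D
    pass closes any remaining enclosed pockets (e.g. sprout lumens).
    """
    out = bm.mask.copy()
    for i in range(out.shape[2]):
        out[:, :, i] = ndimage.binary_fill_holes(out[:, :, i])
    out = ndimage.binary_fill_holes(out)
    return BinaryMask(mask=out, voxel_size=bm.voxel_size)


def largest_component(bm: BinaryMask) -> BinaryMask:
    """Keep only the largest 26-connected foreground component."""
    if not bm.mask.any():
        raise ValueError("empty mask has no components")
    lab, n = ndimage.label(bm.mask, structure=C26)
    if n == 1:
        return bm
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return BinaryMask(mask=lab == sizes.argmax(), voxel_size=bm.voxel_size)


# ---------------------------------------------------------------------------
# Euclidean-ball morphology (fast via distance transforms)


def erode_ball(mask: np.ndarray, radius: float) -> np.ndarray:
    """Binary erosion with a Euclidean ball of ``radius`` (voxel units)."""
    if radius <= 0:
        return mask.copy()
    d = ndimage.distance_transform_edt(mask)
    return d > radius


def dilate_ball(mask: np.ndarray, radius: float) -> np.ndarray:
    if radius <= 0:
        return mask.copy()
    d = ndimage.distance_transform_edt(~mask)
    return d <= radius


def open_ball(mask: np.ndarray, radius: float) -> np.ndarray:
    return dilate_ball(erode_ball(mask, radius), radius)


# ---------------------------------------------------------------------------
# meshing


def mesh_from_mask(
    bm: BinaryMask, smooth_sigma: float = 1.0, pad: int = 2
) -> SurfaceMesh:
    """Iso-surface of the binary field at level 0.5 (marching cubes).

    The binary field is padded (so border-touching masks still close)
    and optionally Gaussian-smoothed by ``smooth_sigma`` voxels before
    contouring; smoothing suppresses the voxel staircase so that areas
    and curvatures of smooth phantoms converge to their closed forms.
    Vertex coordinates are world μm with voxel centres at (i+0.5)·d.
    """
    if not bm.mask.any():
        raise ValueError("cannot mesh an empty mask")
    touches = (
        bm.mask[0].any()
        or bm.mask[-1].any()
        or bm.mask[:, 0].any()
        or bm.mask[:, -1].any()
        or bm.mask[:, :, 0].any()
        or bm.mask[:, :, -1].any()
    )
    pad = max(pad, int(np.ceil(2 * smooth_sigma))) if touches or pad else pad
    field3 = np.pad(bm.mask, pad).astype(np.float32)
    if smooth_sigma > 0:
        field3 = ndimage.gaussian_filter(field3, smooth_sigma)
        if field3.max() <= 0.5:
            field3 = np.pad(bm.mask, pad).astype(np.float32)  # tiny mask: skip smoothing
    d = bm.voxel_size
    verts, faces, _, _ = measure.marching_cubes(field3, level=0.5, spacing=(d, d, d))
    # index space -> world: voxel centres at (i+0.5)d, minus the padding
    verts = verts[:, ::-1] + (0.5 - pad) * d  # (z,y,x) -> (x,y,z)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces[:, ::-1], process=False)
    if mesh.volume < 0:
        mesh.invert()
    return SurfaceMesh(mesh=mesh, voxel_size=bm.voxel_size)


# ---------------------------------------------------------------------------
# segmentations


def define_parent_region(bm: BinaryMask, nominal_radius: float) -> BinaryMask:
    """Estimate the parent-vessel voxel region of a tubular mask.

    Morphological opening of the hole-filled mask with a Euclidean ball
    of radius 0.6·``nominal_radius`` (μm): thin appendages (sprouts) are
    removed, the thick tube survives.  The largest component is kept.
    ``nominal_radius`` defaults to the 100 μm needle template radius in
    the drivers.
    """
    if nominal_radius <= 0:
        raise ValueError("nominal radius must be positive")
    filled = fill_solid(bm).mask
    r_vox = 0.6 * nominal_radius / bm.voxel_size
    opened = open_ball(filled, r_vox)
    if not opened.any():
        raise ValueError(
            "opening removed the whole mask; use a smaller nominal radius"
        )
    lab, n = ndimage.label(opened, structure=C26)
    if n > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        opened = lab == sizes.argmax()
    return BinaryMask(mask=opened, voxel_size=bm.voxel_size)


def tag_parent_vs_sprout(
    smesh: SurfaceMesh, parent_region: BinaryMask, erosion_px: int = 10
) -> SurfaceMesh:
    """Tag vertices parent vs sprout.

    The voxel region outside the parent vessel (the complement of
    ``parent_region``) is eroded by ``erosion_px`` voxels with a
    Euclidean ball; vertices whose voxel falls inside the eroded
    outside-region are sprout, the rest parent.  The erosion removes
    the ambiguous junction collar around the parent wall, so parent-
    surface vertices (which sit on the region boundary) stay parent.
    """
    if erosion_px < 0:
        raise ValueError("erosion must be non-negative")
    outside = ~parent_region.mask
    eroded = erode_ball(outside, float(erosion_px))
    vox = smesh.vertex_voxels(parent_region.mask.shape)
    sprout = eroded[vox[:, 0], vox[:, 1], vox[:, 2]]
    smesh.region = np.where(sprout, SurfaceMesh.REGION_SPROUT, SurfaceMesh.REGION_PARENT).astype(
        np.uint8
    )
    return smesh


def tag_msc_coverage(smesh: SurfaceMesh, green: BinaryMask) -> SurfaceMesh:
    """Tag vertices covered/uncovered by MSC signal at their voxel."""
    vox = smesh.vertex_voxels(green.mask.shape)
    smesh.covered = green.mask[vox[:, 0], vox[:, 1], vox[:, 2]]
    return smesh


# ---------------------------------------------------------------------------
# PLY export with per-vertex scalars


def write_ply(path, smesh: SurfaceMesh) -> None:
    """Binary little-endian PLY with region/covered/mean_curvature scalars."""
    v = np.asarray(smesh.mesh.vertices, dtype="<f4")
    f = np.asarray(smesh.mesh.faces, dtype="<i4")
    n_v, n_f = len(v), len(f)
    header = "\n".join(
        [
            "ply",
            "format binary_little_endian 1.0",
            f"element vertex {n_v}",
            "property float x",
            "property float y",
            "property float z",
            "property uchar region",
            "property uchar covered",
            "property float mean_curvature",
            f"element face {n_f}",
            "property list uchar int vertex_indices",
            "end_header",
            "",
        ]
    )
    vrec = np.zeros(
        n_v,
        dtype=[
            ("x", "<f4"),
            ("y", "<f4"),
            ("z", "<f4"),
            ("region", "u1"),
            ("covered", "u1"),
            ("H", "<f4"),
        ],
    )
    vrec["x"], vrec["y"], vrec["z"] = v[:, 0], v[:, 1], v[:, 2]
    vrec["region"] = smesh.region
    vrec["covered"] = smesh.covered.astype(np.uint8)
    vrec["H"] = np.nan_to_num(smesh.mean_curvature, nan=0.0)
    frec = np.zeros(n_f, dtype=[("n", "u1"), ("idx", "<i4", (3,))])
    frec["n"] = 3
    frec["idx"] = f
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(vrec.tobytes())
        fh.write(frec.tobytes())
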