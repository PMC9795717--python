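"""Morphometric indices of tagged vessel surfaces.

Sprout range, tag-filtered surface areas, enclosed volume, the
area-per-volume surface-roughness maturity index, MSC coverage ratios,
and curvature histograms.  All quantities are in μm-based units and are
computed directly from the triangle data: areas as the sum of triangle
areas, volumes as the sum of signed tetrahedron volumes formed with the
origin (the divergence-theorem formula), so a closed outward-wound mesh
gives the enclosed volume exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curvature import attach_mean_curvature
from .mesh3d import SurfaceMesh

TAG_FILTERS = ("all", "parent", "sprout", "covered", "uncovered")


def _vertex_filter(smesh: SurfaceMesh, tag_filter: str) -> np.ndarray:
    if tag_filter == "all":
        return np.ones(len(smesh.vertices), dtype=bool)
    if tag_filter == "parent":
        return smesh.region == SurfaceMesh.REGION_PARENT
    if tag_filter == "sprout":
        return smesh.region == SurfaceMesh.REGION_SPROUT
    if tag_filter == "covered":
        return smesh.covered
    if tag_filter == "uncovered":
        return ~smesh.covered
    raise ValueError(f"unknown tag filter {tag_filter!r}; use one of {TAG_FILTERS}")


def _face_mask(smesh: SurfaceMesh, tag_filter: str) -> np.ndarray:
    """Majority rule: a face counts if >= 2 of its vertices match."""
    vmask = _vertex_filter(smesh, tag_filter)
    return vmask[smesh.faces].sum(axis=1) >= 2


def surface_area(smesh: SurfaceMesh, tag_filter: str = "all") -> float:
    """Sum of triangle areas (μm²) whose vertices satisfy the filter.

    Degenerate (zero-area) faces are skipped; their count is available
    via :func:`degenerate_face_count`.
    """
    areas = np.asarray(smesh.mesh.area_faces)
    return float(areas[_face_mask(smesh, tag_filter)].sum())


def degenerate_face_count(smesh: SurfaceMesh) -> int:
    return int(np.sum(np.asarray(smesh.mesh.area_faces) == 0.0))


def enclosed_volume(smesh: SurfaceMesh) -> float:
    """Enclosed volume (μm³) from the signed-tetrahedron sum.

    Requires a watertight mesh; raises with the open-edge count
    otherwise.  The absolute value is returned so the result is
    independent of global winding.
    """
    mesh = smesh.mesh
    if not mesh.is_watertight:
        edges = mesh.edges_sorted
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        raise ValueError(
            f"mesh is not watertight ({int(np.sum(counts != 2))} open/odd edges); "
            "enclosed volume is undefined"
        )
    v = np.asarray(mesh.vertices)
    f = np.asarray(mesh.faces)
    v0, v1, v2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    vol = np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0
    return float(abs(vol))


@dataclass
class SproutRange:
    range_um: float
    one_sided: bool  # sprout vertices found on only one side of the axis
    no_sprout: bool = False


def sprout_range(smesh: SurfaceMesh) -> SproutRange:
    """Extent of sprout-tagged vertices along Y (the cross-vessel axis).

    The parent vessel runs along X by convention, so sprout tips spread
    along Y; the range is max(y) − min(y) over sprout vertices.  With
    sprouts on only one side of the parent axis the one-sided flag is
    set; with no sprout vertices the range is 0 and flagged.
    """
    sel = smesh.region == SurfaceMesh.REGION_SPROUT
    if not sel.any():
        return SproutRange(range_um=0.0, one_sided=True, no_sprout=True)
    y = smesh.vertices[sel, 1]
    axis_y = float(np.median(smesh.vertices[~sel, 1])) if (~sel).any() else float(
        np.median(y)
    )
    one_sided = not ((y > axis_y).any() and (y < axis_y).any())
    return SproutRange(range_um=float(y.max() - y.min()), one_sided=one_sided)


def coverage_ratio(smesh: SurfaceMesh, scope: str = "all") -> float:
    """Covered surface area / total surface area within ``scope``.

    ``scope`` is ``"all"`` or ``"sprout"``.  Covered area is the area of
    faces that are both covered and (for sprout scope) sprout-tagged.
    """
    if scope not in ("all", "sprout"):
        raise ValueError("scope must be 'all' or 'sprout'")
    areas = np.asarray(smesh.mesh.area_faces)
    in_scope = (
        np.ones(len(areas), dtype=bool)
        if scope == "all"
        else _face_mask(smesh, "sprout")
    )
    total = float(areas[in_scope].sum())
    if total == 0:
        raise ValueError(f"scope {scope!r} selects zero surface area")
    covered = float(areas[in_scope & _face_mask(smesh, "covered")].sum())
    return covered / total


def roughness(smesh: SurfaceMesh) -> float:
    """Surface area per enclosed volume (μm⁻¹), the maturity index."""
    return surface_area(smesh, "all") / enclosed_volume(smesh)


def sprout_roughness(smesh: SurfaceMesh, parent_mesh: SurfaceMesh) -> float:
    """Roughness of the neovascularization: sprout area / sprout volume.

    Sprout volume is the total enclosed volume minus the parent-region
    mesh volume (the reconstruction route to the sprout compartment).
    """
    vol = enclosed_volume(smesh) - enclosed_volume(parent_mesh)
    if vol <= 0:
        raise ValueError("non-positive sprout volume; no sprout compartment")
    return surface_area(smesh, "sprout") / vol


@dataclass
class CurvatureHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    median: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def curvature_values(smesh: SurfaceMesh, tag_filter: str = "all") -> np.ndarray:
    """Valid per-vertex H values passing the tag filter."""
    if np.all(np.isnan(smesh.mean_curvature)):
        attach_mean_curvature(smesh)
    sel = _vertex_filter(smesh, tag_filter)
    H = smesh.mean_curvature[sel]
    return H[~np.isnan(H)]


def curvature_histogram(
    smesh: SurfaceMesh, tag_filter: str = "all", bins=50
) -> CurvatureHistogram:
    vals = curvature_values(smesh, tag_filter)
    if vals.size == 0:
        raise ValueError(f"no valid curvature values for filter {tag_filter!r}")
    counts, edges = np.histogram(vals, bins=bins)
    return CurvatureHistogram(
        bin_edges=edges, counts=counts, median=float(np.median(vals)), n=vals.size
    )


@dataclass
class MorphometryReport:
    """Per-sample geometric indices (μm-based units)."""

    sample_id: str
    sprout_range_um: float
    sprout_range_one_sided: bool
    surface_area_total: float
    surface_area_parent: float
    surface_area_sprout: float
    enclosed_volume: float
    sprout_volume: float | None
    roughness: float
    coverage_ratio_all: float
    coverage_ratio_sprout: float | None

    def to_row(self) -> dict:
        return self.__dict__.copy()


def morphometry_report(
    smesh: SurfaceMesh,
    sample_id: str = "sample",
    parent_mesh: SurfaceMesh | None = None,
) -> MorphometryReport:
    """Assemble the per-sample report.

    Sprout volume, when a parent-region mesh is supplied, is the total
    enclosed volume minus the parent-region enclosed volume.
    """
    rng = sprout_range(smesh)
    area_total = surface_area(smesh, "all")
    area_sprout = surface_area(smesh, "sprout")
    vol = enclosed_volume(smesh)
    sprout_vol = None
    if parent_mesh is not None:
        sprout_vol = max(0.0, vol - enclosed_volume(parent_mesh))
    try:
        cov_sprout = coverage_ratio(smesh, "sprout") if area_sprout > 0 else None
    except ValueError:
        cov_sprout = None
    return MorphometryReport(
        sample_id=sample_id,
        sprout_range_um=rng.range_um,
        sprout_range_one_sided=rng.one_sided,
        surface_area_total=area_total,
        surface_area_parent=surface_area(smesh, "parent"),
        surface_area_sprout=area_sprout,
        enclosed_volume=vol,
        sprout_volume=sprout_vol,
        roughness=area_total / vol,
        coverage_ratio_all=coverage_ratio(smesh, "all"),
        coverage_ratio_sprout=cov_sprout,
    )
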