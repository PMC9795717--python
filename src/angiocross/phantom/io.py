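"""Reading/writing phantoms as OME-TIFF with physical-size metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from ..containers import ImageSeries2D, VolumeStack
from .series import GroundTruth2D
from .volume import GroundTruth3D


def write_volume(path, vol: VolumeStack) -> None:
    """Write a 3-channel stack as OME-TIFF (axes CZYX, sizes in μm)."""
    dx, dy, dz = vol.voxel_size
    tifffile.imwrite(
        str(path),
        vol.to_array().astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeY": dy,
            "PhysicalSizeZ": dz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        },
    )


def read_volume(path) -> VolumeStack:
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        meta = tf.ome_metadata
    if arr.ndim != 4 or arr.shape[0] != 3:
        raise ValueError(f"expected a CZYX stack with 3 channels, got {arr.shape}")
    voxel = (1.0, 1.0, 1.0)
    if meta:
        import re

        m = {
            k: float(v)
            for k, v in re.findall(r'PhysicalSize([XYZ])="([\d.eE+-]+)"', meta)
        }
        voxel = (m.get("X", 1.0), m.get("Y", 1.0), m.get("Z", 1.0))
    return VolumeStack(red=arr[0], green=arr[1], blue=arr[2], voxel_size=voxel)


def write_series(path, series: ImageSeries2D) -> None:
    """Write a 2-channel time series as OME-TIFF (axes TCYX)."""
    arr = np.stack(
        [np.stack([r, g], axis=0) for r, g in zip(series.red, series.green)], axis=0
    ).astype(np.float32)
    tifffile.imwrite(
        str(path),
        arr,
        ome=True,
        metadata={
            "axes": "TCYX",
            "PhysicalSizeX": series.pixel_size,
            "PhysicalSizeY": series.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
        },
    )


def read_series(path, pixel_size: float | None = None) -> ImageSeries2D:
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        meta = tf.ome_metadata
    if arr.ndim != 4 or arr.shape[1] < 2:
        raise ValueError(f"expected a TCYX series with >= 2 channels, got {arr.shape}")
    if pixel_size is None:
        pixel_size = 1.0
        if meta:
            import re

            m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', meta)
            if m:
                pixel_size = float(m.group(1))
    return ImageSeries2D(
        red=[f[0] for f in arr], green=[f[1] for f in arr], pixel_size=pixel_size
    )


def write_ground_truth_3d(out_dir, gt: GroundTruth3D, name: str = "phantom") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(out_dir / f"{name}_labels.tif"), gt.labels)
    side = {
        "label_names": {str(k): v for k, v in gt.label_names.items()},
        "voxel_size_um": list(gt.voxel_size),
        "analytic_curvature_per_um": gt.curvature,
        "coverage_fraction": gt.coverage_fraction,
        "surface_area_um2": gt.surface_area,
        "covered_area_um2": gt.covered_area,
        "overall_coverage": gt.overall_coverage,
        "sprout_tips_um": [t.tolist() for t in gt.sprout_tips],
        "msc_centers_um": gt.msc_centers.tolist(),
    }
    (out_dir / f"{name}_truth.json").write_text(json.dumps(side, indent=2))


def write_ground_truth_2d(out_dir, gt: GroundTruth2D, name: str = "series") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    side = {
        "center_y_um": gt.center_y,
        "vessel_radius_um": gt.vessel_radius,
        "centroids_um": gt.centroids.tolist(),
        "tilt_deg": gt.angles.tolist(),
        "labels": gt.labels,
        "edge_distance_um": gt.edge_distance.tolist(),
    }
    (out_dir / f"{name}_truth.json").write_text(json.dumps(side, indent=2))
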