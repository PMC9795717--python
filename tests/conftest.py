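"""Shared fixtures: phantoms and reconstructions reused across test modules.

Heavy 3D phantoms are session-scoped; everything is generated at test
time from the synthetic generators (no stored image data).
"""

from __future__ import annotations

import numpy as np
import pytest

from angiocross import mesh3d
from angiocross.phantom import (
    PhantomSpec2D,
    coculture_spec_2d,
    coculture_spec_3d,
    make_coculture_series_2d,
    make_vessel_phantom_3d,
    monoculture_spec_3d,
    solid_cylinder_mask,
    solid_sphere_mask,
)
from angiocross.pipeline import reconstruct

PHANTOM_EROSION_PX = 5  # 10 μm junction collar at the 2 μm phantom voxel


@pytest.fixture(scope="session")
def co_phantom():
    """Noise-free co-culture-like 3D phantom (smooth sprouts, MSCs)."""
    spec = coculture_spec_3d(seed=1)
    vol, gt = make_vessel_phantom_3d(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def co_recon(co_phantom):
    _, vol, _ = co_phantom
    return reconstruct(vol, erosion_px=PHANTOM_EROSION_PX)


@pytest.fixture(scope="session")
def mono_phantom():
    """Monoculture-like 3D phantom (short rough sprouts, no MSCs)."""
    spec = monoculture_spec_3d(seed=11)
    vol, gt = make_vessel_phantom_3d(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def mono_recon(mono_phantom):
    _, vol, _ = mono_phantom
    return reconstruct(vol, erosion_px=PHANTOM_EROSION_PX)


@pytest.fixture(scope="session")
def series2d():
    """Noise-free default 10-day 2D series with ground truth."""
    spec = coculture_spec_2d(seed=5)
    series, gt = make_coculture_series_2d(spec)
    return spec, series, gt


@pytest.fixture(scope="session")
def series2d_noisy():
    spec = coculture_spec_2d(seed=5, noise=True)
    series, gt = make_coculture_series_2d(spec)
    return spec, series, gt


ORACLE_MESH_SIGMA = 1.5  # field pre-smoothing for 1 μm curvature oracles


@pytest.fixture(scope="session")
def sphere_mesh_1um():
    """Voxelized solid sphere r=25 μm at 1 μm voxels, meshed."""
    bm = mesh3d.BinaryMask(solid_sphere_mask(25.0, 1.0), 1.0)
    return mesh3d.mesh_from_mask(bm, smooth_sigma=ORACLE_MESH_SIGMA)


@pytest.fixture(scope="session")
def cylinder_mesh_1um():
    """Voxelized solid cylinder r=100 μm, L=300 μm at 1 μm voxels, meshed."""
    bm = mesh3d.BinaryMask(solid_cylinder_mask(100.0, 300.0, 1.0), 1.0)
    return mesh3d.mesh_from_mask(bm, smooth_sigma=ORACLE_MESH_SIGMA)


@pytest.fixture()
def single_ellipse_frame():
    """One MSC ellipse at 30° in an otherwise standard 2D frame."""
    from angiocross.phantom import MSC2D

    spec = PhantomSpec2D(
        image_shape=(400, 400),
        pixel_size=1.0,
        frames=1,
        mscs=[MSC2D(center=(200, 80), semi_axes=(30, 10), angle_deg=30)],
        migration_rate=0,
        alignment_rate=0,
    )
    series, gt = make_coculture_series_2d(spec)
    return spec, series, gt
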