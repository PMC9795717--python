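"""Standard phantom configurations emulating the chip experiments.

Two 3D archetypes mirror the day-10 cultures:

* **co-culture-like** — long smooth-walled sprouts (mature morphology)
  with MSC bodies wrapped around them and resting on the parent wall;
* **monoculture-like** — short, thin sprouts with sinusoidal wall
  roughness (immature morphology) and no MSCs.

Geometry: parent vessel of 200 μm diameter along x (the needle
template), two sprouts branching perpendicular (one up, one down, so
the sprout range spans both sides), 2 μm isotropic voxels.  Sample-to-
sample variability for group comparisons comes from seeded jitter of
sprout lengths and radii.
"""

from __future__ import annotations

import numpy as np

from .geometry import EllipsoidSpec, SproutSpec
from .series import PhantomSpec2D
from .volume import PhantomSpec3D

DOMAIN = (500.0, 600.0, 300.0)
VOXEL = 2.0
VESSEL_RADIUS = 100.0


def _sprouts(rng, length, base_radius, tip_radius, roughness_amplitude, wavelength):
    """Two opposing perpendicular sprouts.

    Sample-to-sample variability jitters the lengths (±10%) only; wall
    calibre is kept fixed so that the mono/co roughness contrast
    reflects wall texture, not random sprout thickness.
    """
    jit = lambda v: float(v * rng.uniform(0.9, 1.1))  # noqa: E731
    cy = DOMAIN[1] / 2.0
    cz = DOMAIN[2] / 2.0
    return [
        SproutSpec(
            base_point=(180.0, cy + VESSEL_RADIUS, cz),
            direction=(0, 1, 0),
            length=jit(length),
            base_radius=base_radius,
            tip_radius=tip_radius,
            roughness_amplitude=roughness_amplitude,
            roughness_wavelength=wavelength,
        ),
        SproutSpec(
            base_point=(330.0, cy - VESSEL_RADIUS, cz),
            direction=(0, -1, 0),
            length=jit(length),
            base_radius=base_radius,
            tip_radius=tip_radius,
            roughness_amplitude=roughness_amplitude,
            roughness_wavelength=wavelength,
        ),
    ]


def coculture_spec_3d(seed: int = 0, noise: bool = False) -> PhantomSpec3D:
    """Mature co-culture archetype: long smooth sprouts, wrapped MSCs.

    Each sprout carries one MSC wrapped around its mid-section (a large
    ellipsoid centred on the sprout axis) — the configuration in which
    perivascular cells ensheath sprouts — plus one MSC pad resting on
    the parent wall.
    """
    rng = np.random.default_rng(seed)
    sprouts = _sprouts(rng, 150.0, 35.0, 22.0, 0.0, 40.0)
    cy, cz = DOMAIN[1] / 2.0, DOMAIN[2] / 2.0
    mscs = []
    for i, sp in enumerate(sprouts):
        b = np.asarray(sp.base_point)
        u = np.asarray(sp.direction)
        c = b + 0.5 * sp.length * u
        # radial semi-axes well beyond the sprout calibre so the contact
        # band ends cut the wall steeply (sharp, resolvable patch rims)
        mscs.append(
            EllipsoidSpec(
                center=tuple(c),
                semi_axes=(60.0, 45.0, 60.0),
                attached_to=f"sprout_{i}",
            )
        )
    mscs.append(
        EllipsoidSpec(
            center=(430.0, cy, cz + VESSEL_RADIUS - 4.0),
            semi_axes=(30.0, 16.0, 14.0),
            attached_to="parent",
        )
    )
    return PhantomSpec3D(
        vessel_radius=VESSEL_RADIUS,
        domain_size=DOMAIN,
        voxel_size=(VOXEL, VOXEL, VOXEL),
        sprouts=sprouts,
        msc_objects=mscs,
        psf_sigma=1.0 if noise else 0.0,
        noise=(0.05, 50.0) if noise else (0.0, 0.0),
        seed=seed,
    )


def monoculture_spec_3d(seed: int = 0, noise: bool = False) -> PhantomSpec3D:
    """Immature monoculture archetype: short rough-walled sprouts, no MSCs."""
    rng = np.random.default_rng(seed)
    sprouts = _sprouts(rng, 80.0, 30.0, 18.0, 7.0, 35.0)
    return PhantomSpec3D(
        vessel_radius=VESSEL_RADIUS,
        domain_size=DOMAIN,
        voxel_size=(VOXEL, VOXEL, VOXEL),
        sprouts=sprouts,
        msc_objects=[],
        psf_sigma=1.0 if noise else 0.0,
        noise=(0.05, 50.0) if noise else (0.0, 0.0),
        seed=seed,
    )


def coculture_spec_2d(seed: int = 0, noise: bool = False) -> PhantomSpec2D:
    """Default 10-day 2D series: MSCs migrate to the wall and align."""
    return PhantomSpec2D(
        psf_sigma=1.0 if noise else 0.0,
        noise=(0.03, 100.0) if noise else (0.0, 0.0),
        seed=seed,
    )
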