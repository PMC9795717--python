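"""Shared in-memory containers for image data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNEL_ROLES = ("red", "green", "blue")


@dataclass
class VolumeStack:
    """Multi-channel 3D fluorescence stack.

    Arrays are indexed ``(z, y, x)``; ``voxel_size`` is ``(dx, dy, dz)``
    in μm.  Channel roles follow the staining scheme: red = endothelium
    (UEA I / CD31), green = MSC (GFP), blue = nuclei (Hoechst).
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {self.red.shape, self.green.shape, self.blue.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.red.shape

    def channel(self, role: str) -> np.ndarray:
        if role not in CHANNEL_ROLES:
            raise KeyError(role)
        return getattr(self, role)

    def to_array(self) -> np.ndarray:
        """Stack channels into a (C, Z, Y, X) array (C order: R, G, B)."""
        return np.stack([self.red, self.green, self.blue], axis=0)


@dataclass
class ImageSeries2D:
    """Ordered two-channel 2D frames (red = vessel, green = MSC).

    ``frames`` maps to day indices via ``frame_times`` (day 1 first by
    convention); all frames share one shape and pixel size (μm/px).
    """

    red: list[np.ndarray] = field(default_factory=list)
    green: list[np.ndarray] = field(default_factory=list)
    pixel_size: float = 0.89
    frame_times: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.red) != len(self.green):
            raise ValueError("red and green frame counts differ")
        shapes = {f.shape for f in self.red} | {f.shape for f in self.green}
        if len(shapes) > 1:
            raise ValueError(f"frame shapes differ: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if not self.frame_times:
            self.frame_times = list(range(1, len(self.red) + 1))

    def __len__(self) -> int:
        return len(self.red)
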