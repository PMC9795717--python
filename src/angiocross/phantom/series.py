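"""Synthetic 2D co-culture time series.

Emulates the day-by-day wide-field view of the chip: a horizontal parent
vessel imaged as two bright wall stripes (red) and GFP-labelled MSC
bodies in the surrounding gel (green) that migrate toward the vessel and
progressively align with its axis once they reach the near-wall band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..containers import ImageSeries2D

DEFAULT_PIXEL_SIZE = 0.89  # μm/px; a 50 px kernel window is then 44.5 μm


@dataclass
class MSC2D:
    """One MSC in the 2D phantom: an ellipse in world μm coordinates."""

    center: tuple[float, float]  # (x, y) μm; image y increases downward
    semi_axes: tuple[float, float] = (25.0, 10.0)
    angle_deg: float = 45.0  # major-axis angle vs vessel axis, [0, 90]

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass
class PhantomSpec2D:
    """Parameters of the 2D time-series phantom.

    One frame per "day".  ``migration_rate`` moves each MSC centroid
    toward the nearest vessel edge per frame; ``alignment_rate`` decays
    the tilt angle toward 0° (the vessel axis) for MSCs inside the
    near-wall band of width ``neighbor_band``.
    """

    image_shape: tuple[int, int] = (560, 720)  # (H, W) px
    pixel_size: float = DEFAULT_PIXEL_SIZE
    vessel_radius: float = 100.0
    wall_thickness: float = 10.0
    frames: int = 10
    migration_rate: float = 15.0  # μm/frame
    alignment_rate: float = 8.0  # deg/frame
    neighbor_band: float = 25.0  # μm from the outer edge
    mscs: list[MSC2D] = field(default_factory=list)
    allow_intraluminal: bool = False
    psf_sigma: float = 0.0  # μm
    noise: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames < 1:
            raise ValueError("need at least one frame")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.migration_rate < 0 or self.alignment_rate < 0:
            raise ValueError("rates must be non-negative")

    @property
    def center_y(self) -> float:
        return self.image_shape[0] * self.pixel_size / 2.0

    def edge_distance(self, y: float) -> float:
        """Signed distance (μm) from the outer vessel edge; negative inside."""
        return abs(y - self.center_y) - self.vessel_radius


@dataclass
class GroundTruth2D:
    """Per-frame true MSC state: centroid (μm), tilt (deg), location label."""

    centroids: np.ndarray  # (frames, n_msc, 2) in μm, (x, y)
    angles: np.ndarray  # (frames, n_msc) degrees in [0, 90]
    labels: list[list[str]]  # "neighbor" | "distant" per frame per MSC
    edge_distance: np.ndarray  # (frames, n_msc) μm from outer edge
    center_y: float
    vessel_radius: float


def default_msc_layout(
    n: int, spec: PhantomSpec2D, rng: np.random.Generator
) -> list[MSC2D]:
    """Scatter MSCs in the gel above/below the vessel, tilted 30°–80°.

    Initial edge distances sit on a half-step-offset grid of the
    migration step beyond the neighbor band, so no trajectory ever lands
    on the neighbor/distant boundary (location labels stay unambiguous);
    x positions are jittered grid slots so cells do not overlap.
    """
    H, W = spec.image_shape
    w_um = W * spec.pixel_size
    h_um = H * spec.pixel_size
    out = []
    margin = 35.0
    step = max(spec.migration_rate, 10.0)
    d_max = h_um / 2 - spec.vessel_radius - margin
    k_max = max(1, int((d_max - spec.neighbor_band - step / 2) // step))
    slot_w = (w_um - 2 * margin) / n
    for i in range(n):
        x = margin + (i + rng.uniform(0.25, 0.75)) * slot_w
        side = rng.choice([-1.0, 1.0])
        k = rng.integers(1, k_max + 1)
        dist = spec.neighbor_band + step * k + step / 2.0
        y = spec.center_y + side * (spec.vessel_radius + dist)
        out.append(
            MSC2D(
                center=(x, y),
                semi_axes=(rng.uniform(20, 30), rng.uniform(7, 12)),
                angle_deg=rng.uniform(30, 80),
            )
        )
    return out


def _render_frame(spec: PhantomSpec2D, mscs_state, rng) -> tuple[np.ndarray, np.ndarray]:
    H, W = spec.image_shape
    px = spec.pixel_size
    yy = (np.arange(H, dtype=np.float32) + 0.5) * px
    xx = (np.arange(W, dtype=np.float32) + 0.5) * px
    Ygrid = yy[:, None]
    Xgrid = xx[None, :]

    dist = np.abs(Ygrid - np.float32(spec.center_y)) - np.float32(spec.vessel_radius)
    red = ((dist > -spec.wall_thickness) & (dist <= 0)).astype(np.float32)
    red = np.broadcast_to(red, (H, W)).copy()

    green = np.zeros((H, W), dtype=np.float32)
    for (cx, cy), (a, b), ang in mscs_state:
        th = np.deg2rad(ang)
        # image y grows downward: a +angle tilt vs the x axis
        ux = (Xgrid - cx) * np.cos(th) - (Ygrid - cy) * np.sin(th)
        uy = (Xgrid - cx) * np.sin(th) + (Ygrid - cy) * np.cos(th)
        green[(ux / a) ** 2 + (uy / b) ** 2 <= 1.0] = 1.0

    def image_noise(img):
        out = img
        if spec.psf_sigma > 0:
            out = ndimage.gaussian_filter(out, sigma=spec.psf_sigma / px)
        g_sd, p_scale = spec.noise
        if p_scale > 0:
            out = rng.poisson(np.clip(out, 0, None) * p_scale).astype(
                np.float32
            ) / np.float32(p_scale)
        if g_sd > 0:
            out = out + rng.normal(0, g_sd, out.shape).astype(np.float32)
        return out

    return image_noise(red), image_noise(green)


def make_coculture_series_2d(
    spec: PhantomSpec2D,
) -> tuple[ImageSeries2D, GroundTruth2D]:
    """Generate the day-series phantom plus exact ground truth.

    Kinematics per frame t (t = 0 is day 1): each MSC has moved
    ``migration_rate * t`` μm toward the nearest outer vessel edge,
    stopping at the edge; once inside the neighbor band its tilt decays
    by ``alignment_rate`` deg/frame toward 0°.
    """
    rng = np.random.default_rng(spec.seed)
    mscs = spec.mscs
    if not mscs:
        mscs = default_msc_layout(12, spec, rng)
    for k, m in enumerate(mscs):
        if spec.edge_distance(m.center[1]) < 0 and not spec.allow_intraluminal:
            raise ValueError(
                f"MSC {k} is initialised inside the lumen (y={m.center[1]:.1f} μm) "
                "and allow_intraluminal is False"
            )

    n = len(mscs)
    cents = np.zeros((spec.frames, n, 2))
    angs = np.zeros((spec.frames, n))
    dists = np.zeros((spec.frames, n))
    labels: list[list[str]] = []

    # iterate the kinematics so alignment starts on band arrival
    cur = [
        [list(m.center), list(m.semi_axes), float(m.angle_deg)] for m in mscs
    ]
    red_frames, green_frames = [], []
    for t in range(spec.frames):
        if t > 0:
            for st in cur:
                (cx, cy), ang = st[0], st[2]
                d = spec.edge_distance(cy)
                if d > 0:
                    step = min(spec.migration_rate, d)
                    cy += -step if cy > spec.center_y else step
                    st[0] = [cx, cy]
                if spec.edge_distance(st[0][1]) <= spec.neighbor_band:
                    st[2] = max(0.0, ang - spec.alignment_rate)
        frame_labels = []
        for k, st in enumerate(cur):
            cents[t, k] = st[0]
            angs[t, k] = st[2]
            d = spec.edge_distance(st[0][1])
            dists[t, k] = d
            frame_labels.append("neighbor" if d <= spec.neighbor_band else "distant")
        labels.append(frame_labels)
        r, g = _render_frame(
            spec, [(tuple(s[0]), tuple(s[1]), s[2]) for s in cur], rng
        )
        red_frames.append(r)
        green_frames.append(g)

    series = ImageSeries2D(
        red=red_frames,
        green=green_frames,
        pixel_size=spec.pixel_size,
        frame_times=list(range(1, spec.frames + 1)),
    )
    gt = GroundTruth2D(
        centroids=cents,
        angles=angs,
        labels=labels,
        edge_distance=dists,
        center_y=spec.center_y,
        vessel_radius=spec.vessel_radius,
    )
    return series, gt
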