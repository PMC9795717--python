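"""Kernel-window correlation, edge extraction, particle/orientation analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angiocross import image2d
from angiocross.image2d import (
    DISTANT,
    INTRALUMINAL,
    NEIGHBOR,
    EdgeParams,
    MarginSpec,
    VesselEdges,
    classify_particles,
    density_correlation,
    derive_margins,
    detect_msc_particles,
    extract_vessel_edges,
    fold_angle,
    kernel_density_maps,
    orientation_distribution,
)
from angiocross.phantom import MSC2D, PhantomSpec2D, make_coculture_series_2d

# ---------------------------------------------------------------------------
# density maps


def test_density_map_allones_window50():
    img = np.ones((100, 100))
    mr, mg = kernel_density_maps(img, img, 50)
    assert mr.grid.shape == (2, 2)
    assert np.all(mr.grid == 2500.0)


def test_density_map_window1_is_identity():
    rng = np.random.default_rng(0)
    img = rng.uniform(size=(17, 23))
    mr, _ = kernel_density_maps(img, img, 1)
    assert np.allclose(mr.grid, img)


def test_density_map_matches_hand_summed_oracle():
    """6×6 ramp, window 3: compare against explicit double-loop summation."""
    img = np.arange(36, dtype=float).reshape(6, 6)
    mr, _ = kernel_density_maps(img, img, 3)
    oracle = np.zeros((2, 2))
    for bi in range(2):
        for bj in range(2):
            for i in range(3):
                for j in range(3):
                    oracle[bi, bj] += img[3 * bi + i, 3 * bj + j]
    assert np.array_equal(mr.grid, oracle)


def test_density_map_discards_partial_windows():
    img = np.ones((7, 11))
    mr, _ = kernel_density_maps(img, img, 3)
    assert mr.grid.shape == (2, 3)


def test_density_map_window_larger_than_image_rejected():
    img = np.ones((20, 20))
    with pytest.raises(ValueError):
        kernel_density_maps(img, img, 21)


# ---------------------------------------------------------------------------
# correlation


def test_correlation_identical_channels_is_one():
    rng = np.random.default_rng(1)
    img = rng.uniform(size=(100, 100))
    mr, mg = kernel_density_maps(img, img, 10)
    res = density_correlation(mr, mg)
    assert res.r == pytest.approx(1.0, abs=1e-12)
    assert res.correlated


def test_correlation_negated_channel_is_minus_one():
    rng = np.random.default_rng(2)
    img = rng.uniform(size=(100, 100))
    mr, _ = kernel_density_maps(img, img, 10)
    mg = image2d.DensityMap(10, -mr.grid + 7.0)
    res = density_correlation(mr, mg)
    assert res.r == pytest.approx(-1.0, abs=1e-12)
    assert not res.correlated


def test_correlation_matches_textbook_formula():
    a = np.array([[1.0, 2.0], [3.0, 4.0]])
    b = np.array([[1.0, 2.0], [3.0, 5.0]])
    # hand Pearson: r = cov / (sd_a sd_b), population moments
    am, bm = a.mean(), b.mean()
    r_hand = ((a - am) * (b - bm)).sum() / np.sqrt(
        ((a - am) ** 2).sum() * ((b - bm) ** 2).sum()
    )
    res = density_correlation(image2d.DensityMap(1, a), image2d.DensityMap(1, b))
    assert res.r == pytest.approx(r_hand, abs=1e-12)


def test_correlation_zero_variance_is_flagged_not_silent_zero():
    mr = image2d.DensityMap(1, np.ones((3, 3)))
    mg = image2d.DensityMap(1, np.arange(9.0).reshape(3, 3))
    res = density_correlation(mr, mg)
    assert res.degenerate
    assert np.isnan(res.r)
    assert not res.correlated


def test_independent_noise_channels_near_zero_r():
    rng = np.random.default_rng(11)
    a = rng.normal(size=(500, 500))
    b = rng.normal(size=(500, 500))
    mr, mg = kernel_density_maps(a, b, 25)
    res = density_correlation(mr, mg)
    assert res.n >= 400
    assert abs(res.r) < 0.1


def test_correlation_nondecreasing_with_window_size(series2d_noisy):
    """Coarser windows raise r on a correlated (late) co-culture frame."""
    _, series, _ = series2d_noisy
    rs = [
        res.r
        for res in image2d.correlation_vs_window_size(
            series.red[-1], series.green[-1], (10, 25, 50)
        )
    ]
    assert rs[0] <= rs[1] <= rs[2]


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    gain_r=st.floats(0.1, 50),
    gain_g=st.floats(0.1, 50),
    off_r=st.floats(-5, 5),
    off_g=st.floats(-5, 5),
)
def test_correlation_invariant_under_positive_affine_rescaling(
    gain_r, gain_g, off_r, off_g
):
    rng = np.random.default_rng(3)
    a = rng.uniform(size=(60, 60))
    b = a + 0.3 * rng.uniform(size=(60, 60))
    mr, mg = kernel_density_maps(a, b, 10)
    base = density_correlation(mr, mg).r
    mr2, mg2 = kernel_density_maps(gain_r * a + off_r, gain_g * b + off_g, 10)
    res2 = density_correlation(mr2, mg2)
    assert res2.r == pytest.approx(base, abs=1e-9)


# ---------------------------------------------------------------------------
# edges


def test_edge_separation_on_noise_free_vessel(series2d):
    """200 μm vessel: separation within 2 px on ≥98% of columns."""
    spec, series, _ = series2d
    edges = extract_vessel_edges(series.red[0])
    target_px = 2 * spec.vessel_radius / spec.pixel_size
    err = np.abs(edges.separation() - target_px)
    assert (err <= 2.0).mean() >= 0.98


def test_edge_extraction_constant_image_raises():
    with pytest.raises(ValueError):
        extract_vessel_edges(np.zeros((64, 64)))


def test_edge_bump_recovered_within_smoothing_tolerance():
    """A bump of known height on the upper wall shows up in the edge trace."""
    spec = PhantomSpec2D(frames=1, mscs=[], seed=0)
    series, _ = make_coculture_series_2d(spec)
    img = series.red[0].copy()
    h_um = 30.0
    h_px = h_um / spec.pixel_size
    cy_px = spec.center_y / spec.pixel_size
    r_px = spec.vessel_radius / spec.pixel_size
    top = int(round(cy_px - r_px))
    img[int(top - h_px) : top + 2, 300:380] = 1.0  # rectangular bump, 80 px wide
    edges = extract_vessel_edges(img)
    baseline = np.median(edges.upper_y)
    excursion = baseline - edges.upper_y.min()
    assert excursion == pytest.approx(h_px, abs=4.0)


def test_vessel_edges_invariant_violation_detected():
    with pytest.raises(ValueError):
        VesselEdges(
            upper_y=np.array([10.0, 30.0]),
            lower_y=np.array([20.0, 20.0]),
            center_y=15.0,
            valid=np.array([True, True]),
        )


# ---------------------------------------------------------------------------
# particles


def test_single_ellipse_detected_with_tilt(single_ellipse_frame):
    _, series, _ = single_ellipse_frame
    parts = detect_msc_particles(series.green[0])
    assert len(parts) == 1
    assert parts.tilt_deg.iloc[0] == pytest.approx(30.0, abs=2.0)
    assert parts.major_px.iloc[0] == pytest.approx(60.0, rel=0.05)


@pytest.mark.parametrize("angle,expected", [(120.0, 60.0), (150.0, 30.0)])
def test_obtuse_image_angle_folds_to_tilt(angle, expected):
    spec = PhantomSpec2D(
        image_shape=(400, 400),
        pixel_size=1.0,
        frames=1,
        mscs=[MSC2D(center=(200, 80), semi_axes=(30, 10), angle_deg=angle)],
        migration_rate=0,
        alignment_rate=0,
    )
    series, _ = make_coculture_series_2d(spec)
    parts = detect_msc_particles(series.green[0])
    assert parts.tilt_deg.iloc[0] == pytest.approx(expected, abs=2.0)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(theta=st.floats(0.0, 180.0))
def test_fold_angle_symmetric_about_90(theta):
    assert fold_angle(theta) == pytest.approx(fold_angle(180.0 - theta), abs=1e-9)
    assert 0.0 <= fold_angle(theta) <= 90.0


def test_two_blobs_and_subthreshold_speck_gives_two_objects():
    img = np.zeros((200, 200))
    img[20:50, 20:50] = 1.0
    img[120:160, 120:150] = 1.0
    img[90, 90] = 1.0  # single-pixel speck, below min_area
    parts = detect_msc_particles(
        img, image2d.ParticleParams(tophat_radius=0, min_area=20)
    )
    assert len(parts) == 2


def test_empty_green_frame_yields_empty_particle_table():
    parts = detect_msc_particles(np.zeros((64, 64)))
    assert len(parts) == 0


# ---------------------------------------------------------------------------
# margins and classification


def _flat_edges(width=200, upper=80.0, lower=120.0):
    return VesselEdges(
        upper_y=np.full(width, upper),
        lower_y=np.full(width, lower),
        center_y=100.0,
        valid=np.ones(width, dtype=bool),
    )


def _particles(coords):
    return pd.DataFrame(
        {
            "centroid_x": [c[0] for c in coords],
            "centroid_y": [c[1] for c in coords],
            "major_px": 20.0,
            "minor_px": 8.0,
            "tilt_deg": 45.0,
            "area_px2": 150.0,
        }
    )


def test_margin_is_max_intraluminal_depth():
    """Day-1 objects 5 and 12 px inside the upper edge give d_in = 12."""
    parts = _particles([(50, 85.0), (60, 92.0), (70, 30.0)])  # depths 5, 12, outside
    margins = derive_margins(parts, _flat_edges(), pixel_size=1.0)
    assert margins.d_in == pytest.approx(12.0)
    assert margins.d_out == pytest.approx(12.0)
    assert not margins.fallback_used


def test_margin_fallback_is_mean_major_axis():
    parts = _particles([(50, 30.0), (60, 170.0)])  # nothing intraluminal
    margins = derive_margins(parts, _flat_edges(), pixel_size=1.0)
    assert margins.fallback_used
    assert margins.d_in == pytest.approx(20.0)  # mean major axis


def test_margins_frozen_contract():
    parts = _particles([(50, 85.0)])
    margins = derive_margins(parts, _flat_edges(), pixel_size=1.0)
    assert margins.frozen_from_day == 1  # same object reused on later days


def test_classification_boundary_inclusive_toward_neighbor():
    margins = MarginSpec(d_in=10.0, d_out=10.0)
    parts = _particles([(50, 70.0)])  # exactly on the outer margin (10 px out)
    out = classify_particles(parts, _flat_edges(), margins, pixel_size=1.0)
    assert out.label.iloc[0] == NEIGHBOR


def test_classification_matches_ground_truth_on_phantom(series2d):
    spec, series, gt = series2d
    edges = extract_vessel_edges(series.red[0])
    margins = MarginSpec(d_in=spec.neighbor_band, d_out=spec.neighbor_band)
    for t in (0, len(series) - 1):
        parts = detect_msc_particles(series.green[t])
        out = classify_particles(parts, edges, margins, spec.pixel_size)
        # match detected particles to ground-truth MSCs by nearest centroid
        px = spec.pixel_size
        for _, row in out.iterrows():
            d2 = np.sum(
                (gt.centroids[t] - np.array([row.centroid_x * px, row.centroid_y * px]))
                ** 2,
                axis=1,
            )
            assert out.loc[_, "label"] == gt.labels[t][int(np.argmin(d2))]


def test_far_particles_are_distant():
    margins = MarginSpec(d_in=10.0, d_out=10.0)
    parts = _particles([(50, 600.0), (80, 700.0)])
    out = classify_particles(parts, _flat_edges(), margins, pixel_size=1.0)
    assert (out.label == DISTANT).all()


def test_deep_intraluminal_excluded():
    margins = MarginSpec(d_in=5.0, d_out=5.0)
    parts = _particles([(50, 100.0)])  # lumen centre, 20 px deep
    out = classify_particles(parts, _flat_edges(), margins, pixel_size=1.0)
    assert out.label.iloc[0] == INTRALUMINAL


def test_label_partition_counts(series2d):
    spec, series, _ = series2d
    edges = extract_vessel_edges(series.red[0])
    parts = detect_msc_particles(series.green[0])
    margins = derive_margins(parts, edges, spec.pixel_size)
    out = classify_particles(parts, edges, margins, spec.pixel_size)
    assert out.label.isin([NEIGHBOR, DISTANT, INTRALUMINAL]).all()
    assert len(out) == len(parts)


# ---------------------------------------------------------------------------
# orientation distribution


def test_orientation_histogram_conserves_counts():
    parts = _particles([(10, 60), (20, 60), (30, 60)])
    parts["label"] = NEIGHBOR
    hist = orientation_distribution(parts)
    assert hist[NEIGHBOR].sum() == 3
    assert hist[DISTANT].sum() == 0


def test_orientation_all_zero_angles_single_bin():
    parts = _particles([(10, 60), (20, 60)])
    parts["tilt_deg"] = 0.0
    parts["label"] = DISTANT
    hist = orientation_distribution(parts)
    assert hist[DISTANT].iloc[0] == 2
    assert (hist[DISTANT].iloc[1:] == 0).all()


def test_neighbors_align_more_than_distant_in_aligned_series(series2d):
    """Phantom alignment: neighbor median tilt < distant median tilt."""
    spec, series, _ = series2d
    edges = extract_vessel_edges(series.red[0])
    margins = MarginSpec(d_in=spec.neighbor_band, d_out=spec.neighbor_band)
    neighbor_angles, distant_angles = [], []
    for t in range(len(series)):
        parts = detect_msc_particles(series.green[t])
        out = classify_particles(parts, edges, margins, spec.pixel_size)
        neighbor_angles += list(out[out.label == NEIGHBOR].tilt_deg)
        distant_angles += list(out[out.label == DISTANT].tilt_deg)
    assert np.median(neighbor_angles) < np.median(distant_angles)
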