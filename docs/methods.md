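# Methods

This note documents the models, parameter choices and numerical behaviour
of the package; it states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic phantoms

**3D geometry.** A phantom is a union of implicit solids: a parent
cylinder of outer radius R (default 100 μm — the needle-template radius,
i.e. a 200 μm vessel) along an axis through the domain centre, plus capped
conical sprouts rooted on the vessel surface with linearly interpolated
radius and an optional sinusoidal radial modulation
r(s) = r_base + (r_tip − r_base)s/L + A·sin(2πs/λ). The endothelial (red)
signal is the *wall shell* of the union solid — voxels with
−t < f_union ≤ 0 for wall thickness t = 10 μm — so the lumen is dark, as
in the stained chip. MSCs are rigid ellipsoids (green); nuclei are small
spheres (blue). Imaging is modelled as Gaussian PSF blur, then Poisson
photon noise, then Gaussian read noise; all randomness flows from one
integer seed and regenerating with the same spec is bit-identical.

Ground truth is computed from the analytic primitives, not from the
rasterization: voxel labels (background / lumen / parent wall / sprout i /
MSC j), closed-form curvatures, sprout tips, and the MSC-contact fraction
of every surface obtained by sampling each lateral surface with its exact
area element (r(s)·√(1+r′(s)²) dθ ds for sprouts) plus the domain-face
vessel caps and sprout tip caps — the meshed solid necessarily closes
there, so a coverage denominator without caps would be ~15% off.

**Study archetypes** (`phantom.presets`, 2 μm isotropic voxels,
500×600×300 μm domain): *co-culture-like* — two opposing perpendicular
sprouts of 150 μm nominal length (smooth walls, base/tip radii 35/22 μm),
one large MSC wrapped around each sprout mid-section and one pad on the
parent wall; *monoculture-like* — 80 μm sprouts with sinusoidal wall
roughness (A = 7 μm, λ = 35 μm, radii 30/18 μm) and no MSCs. Seeds jitter
sprout lengths ±10% only; calibre is fixed so the mono/co roughness
contrast reflects wall texture rather than random thickness. The wrap
MSCs' radial semi-axes (60 μm) exceed the sprout calibre so contact-band
rims cut the wall steeply; grazing-tangent rims would leave sub-voxel
green shells that binarization cannot resolve.

**2D series.** One frame per "day": the vessel appears as two horizontal
wall stripes (shell of the band |y − c_y| ≤ R), MSCs as tilted ellipses.
Kinematics per frame: centroids move `migration_rate` (15 μm/frame
default) toward the nearest outer edge and stop there; once inside the
neighbor band (25 μm) the tilt decays by `alignment_rate` (8°/frame)
toward the vessel axis. Pixel size is fixed at 0.89 μm/px so the default
50 px kernel window is 44.5 μm. Initial edge distances sit on a
half-step-offset grid beyond the band so no trajectory ever lands on the
neighbor/distant boundary — location labels are unambiguous by
construction, which is what makes exact label-recovery testing meaningful.
What the phantoms deliberately do **not** model: cell shape change,
crawling along the wall, division/death, optical aberrations beyond a
Gaussian PSF, or flow. Passing tests therefore validate the measurement
pipeline, not biological realism.

**Expression phantoms.** Per cell type, background genes with co/mono
log₂ fold changes inside ±0.8 plus DEG clusters planted on temporal
templates (early/late/sustained, |FC| ≈ 2.2–2.6) with N(0, 0.15) jitter;
baselines are log-normal. Candidate-interaction tables carry three
confidence scores per edge with planted keepers (all scores > 0.9, cross
cell type) and decoys violating exactly one rule.

## 2D pipeline choices

Background subtraction is a morphological white top-hat (disk radius
50 px, sequence decomposition); the band-pass along x keeps wavelengths
in [8 px, width/2] **and retains the DC component** — removing DC would
null any structure constant along the vessel axis, including a straight
vessel. Binarization is standard Otsu. Edges are the per-column extreme
foreground pixels on each side of the (first-frame, then pinned) centre
row, median-smoothed over 15 columns; gaps are interpolated. Particles:
Otsu → 8-connected components → area ≥ 20 px² → ellipse by second central
moments; the tilt is the undirected major-axis angle vs the vessel axis
folded into [0°, 90°]. Margins: d_in = deepest day-1 intraluminal
centroid, d_out = d_in, frozen for the chip; fallback when day 1 has no
intraluminal object = mean day-1 major axis (logged on the margin spec).
Boundary ties classify as neighbor.

## 3D pipeline choices

Volumes are resampled to isotropic voxels (linear) before filtering so
voxel-denominated operations are direction-independent. The wall mask is
median-filtered (3³) and thresholded (Otsu, or a fixed value reusable
across samples). The lumen opens at the volume faces, so 3D hole-filling
alone cannot close the tube: `fill_solid` hole-fills every (z, y) slice
first, then runs a 3D pass (closing sprout lumens). Meshing is marching
cubes at level 0.5 of the (optionally Gaussian pre-smoothed) binary
field, padded so border-touching masks close; winding is fixed so the
enclosed volume is positive.

*Pre-smoothing:* σ = 1 voxel suppresses the staircase on smooth
biological shapes (cylinder area error 0.02% vs +4% raw); for sharp
polyhedral masks it must be disabled — it rounds corners (a 10 μm cube
loses ~10% volume). Note that the 0.5-level iso-surface of a binary cube
chamfers each edge regardless: its exact area is 6L² − 12L(1−√2/2), about
6% below 6L².

*Parent region:* morphological opening of the filled mask with a
Euclidean ball of radius 0.6·R_nominal (EDT-based, exact), keeping the
largest component — thin sprouts are removed, the tube survives. This is
an explicit, documented stand-in for an interactive step whose original
definition is not published. *Sprout tagging:* the complement of the
parent region is eroded by `erosion_px` voxels (Euclidean ball) and
vertices whose voxel lies inside the eroded complement are sprout. The
erosion trims the ambiguous junction collar; parent-surface vertices sit
on the region boundary and stay parent. The default is 10 voxels (the
simplest isotropic reading of a ten-pixel erosion); the 2 μm-voxel
phantom studies pass 5 (a 10 μm collar), since 20 μm would consume ~20%
of an 80–150 μm sprout. *Coverage tagging:* a vertex is covered when its
containing voxel (floor(coord/voxel), clamped; border-touching caps
legitimately clamp by one voxel) holds positive binarized green signal.

## Curvature

Per-vertex mean curvature uses the cotangent Laplace–Beltrami operator
with mixed Voronoi areas; the sign compares the mean-curvature normal
with the outward vertex normal (convex → negative). The estimator is
exact to rounding on clean parametric meshes (a regular cylinder grid
gives −1/(2r) to 13 digits). On marching-cubes meshes of voxel data the
*pointwise* values are noisy — the correct total curvature concentrates
on irregular vertex strips — so the stored per-vertex H averages the
curvature measure H·dA over a Gaussian ambient kernel (σ = 5 voxels,
deposited on a 2-voxel grid). The scale is far below the radii of
interest; with it, the 1 μm-voxel oracles give sphere (r = 25 μm) median
H within 0.6% of −1/r, cylinder (r = 100 μm) lateral median within 2% of
−1/(2r), and a flat plate |H| ~ 1e−4 μm⁻¹. Boundary and non-manifold
vertices are NaN and excluded from histograms. Curvature histograms and
medians are computed over tag-filtered valid vertices; tag-filtered areas
use a ≥2-of-3 vertex majority per face, which keeps parent + sprout within
1% of the total on phantom meshes.

## Morphometry

Sprout range = max(y) − min(y) over sprout vertices (vessel along x);
one-sided configurations are flagged rather than doubled. Enclosed volume
uses the signed-tetrahedron sum and demands watertightness (the error
message reports the open-edge count). Roughness = A/V; the mono/co
contrast is evaluated on the sprout compartment (sprout-tagged area over
sprout volume = total − parent-region mesh volume), since whole-structure
A/V is dominated by the unchanged parent tube and thin appendages raise
it regardless of texture. Sprout volume is total minus the parent-region
mesh volume.

## Statistics

Mann–Whitney U is exact when both groups have n ≤ 8 without ties,
otherwise the tie-corrected normal approximation; Bonferroni m is always
explicit (the drivers use m = 3 for the three morphometric endpoints).
KS uses the asymptotic two-sided p. ANOVA is type-II with per-day
location t-contrasts Bonferroni-adjusted over days; the observational
unit is the detected object, as in the original time-lapse design (n = 1
chip), which is documented rather than remodelled. Null calibration in
the acceptance script draws 2000 pairs: MWU at n = 25/group, KS at
n = 80/group — the asymptotic KS p is conservative below that (true
rejection ≈ 0.03 at n = 25) and its rate settles at α only for larger
groups. OLS handles the degenerate constant-y case (slope 0, r² = 0) and
rejects constant x.

## Transcriptomic screen

Fold changes are log₂((co+ε)/(mono+ε)) with ε = 1 for count-like data,
half the smallest positive value otherwise. DEG thresholds are strict
(FC = 1.0 exactly is not a DEG); direction comes from the timepoint of
largest |FC|. Clustering input is the z-normalized profile; because
z-scoring erases profile sign (a down-early profile equals an up-late
one), up- and down-DEGs are clustered separately per cell type and labels
follow the <cell>-<U|D><rank> scheme with ranks ordered by the
cluster-mean peak time. The dendrogram (Ward linkage on cosine distances)
is cut at the smallest k where every cluster's mean pairwise Pearson
correlation exceeds 0.6 (singletons pass vacuously); if no such k < n
exists the result is all singletons with a warning. The interaction
filter is a pure row predicate (three strict score thresholds, cross
cell type, no both-cell-type DEGs) over a local TSV contract; no live
database is queried, and the named ligand–receptor trio in driver 06 is a
synthetic stand-in (suffix `_syn`) with generated scores.

## Problem sizes and limitations

Phantom studies run at 2 μm voxels (11M-voxel stacks, ~15 s per
reconstruction on one CPU); curvature/geometry oracles at 1 μm. Known
limitations: no mesh repair beyond dropping degenerate faces; no cell
tracking across 2D frames; no centerline/branch-point analysis; the
parent-region rule and the erosion interpretation are this package's own
documented choices where the original interactive workflow is not
reproducible; μm-calibrated curvature cannot be compared with published
curvature magnitudes whose unit convention is unstated.
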