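# angiocross

Image-based morphometry of sprouting angiogenesis in microvessel-on-a-chip
cultures, and of the crosstalk between the endothelium and perivascular
mesenchymal stem cells (MSCs).

## The problem

In a needle-templated chip, a ~200 μm-diameter endothelial tube (HUVECs,
imaged in red) sprouts into a collagen gel seeded with GFP-labelled MSCs
(green). Co-culture with MSCs matures the sprouts: they grow longer and
their walls become smoother. This package quantifies that maturation from
fluorescence images:

* **2D time series** — block-wise ("kernel window") colocalization of the
  red and green channels by Pearson correlation (a sample is called
  *correlated* when r > 0.6); vessel-edge extraction; MSC particle analysis
  with ellipse fitting; classification of MSCs into *neighbor* vs *distant*
  relative to a margin band frozen on day 1; tilt-angle statistics
  (two-way ANOVA, day × location, Bonferroni post hocs).
* **3D z-stacks** — median filter + global threshold, largest connected
  component, lumen filling, marching-cubes surface reconstruction; vertex
  tagging into *parent vessel* vs *sprout* (morphological parent-region
  estimate, complement eroded by ten voxels) and *MSC-covered* vs
  *uncovered* (positive binarized green signal at the vertex voxel).
* **Morphometry** — sprout range (tip-to-tip extent across the vessel
  axis), tag-filtered surface areas A = Σ triangle areas, enclosed volume
  V = |Σ v₀·(v₁×v₂)|/6, surface roughness A/V (μm⁻¹, the maturity index),
  MSC coverage ratio, and per-vertex mean curvature H (μm⁻¹) via the
  cotangent Laplace–Beltrami operator with mixed Voronoi areas. Sign
  convention: convex bulges negative (sphere: H = −1/r; cylinder wall:
  H = −1/(2r)), concave pits positive, flat ≈ 0.
* **Statistics** — Mann–Whitney U (exact for small groups) with Bonferroni
  adjustment, two-sample Kolmogorov–Smirnov for curvature distributions,
  two-way ANOVA (type-II), OLS regression.
* **Transcriptomic screen** — co- vs mono-culture log₂ fold changes,
  DEG calling at |log₂FC| > 1 (strict), Ward clustering of z-normalized
  temporal profiles on cosine distances cut at the smallest k with every
  cluster's mean within-cluster Pearson correlation > 0.6, and screening
  of candidate EC–MSC interactions: keep an edge only when its database,
  experimental and text-mining confidence scores all exceed 0.9, the
  endpoints are DEGs of different cell types, and neither gene is a DEG
  in both.

Because no raw imaging data is publicly deposited for this kind of
experiment, the package ships a first-class synthetic generator
(`angiocross.phantom`): parametric vessel+sprout+MSC phantoms in 2D and 3D
with exact ground truth (voxel labels, analytic curvatures, true MSC
positions/orientations, true surface-contact fractions, planted DEG
structure). Every pipeline stage is validated against that ground truth.

## Worked example

Reconstruct and measure a co-culture-like phantom:

```python
from angiocross.phantom import coculture_spec_3d, make_vessel_phantom_3d
from angiocross.pipeline import reconstruct
from angiocross import morphometry as mm

vol, truth = make_vessel_phantom_3d(coculture_spec_3d(seed=1))
rec = reconstruct(vol, erosion_px=5)          # 10 μm collar at 2 μm voxels
rep = mm.morphometry_report(rec.surface, "co-1", parent_mesh=rec.parent_surface)
print(round(rep.sprout_range_um), round(rep.coverage_ratio_all, 3),
      round(truth.overall_coverage, 3))
```

prints `514 0.069 0.068`: the two opposing sprouts (150 μm nominal, seeded
length jitter) span 514 μm tip-to-tip across the 200 μm vessel, and the
measured MSC coverage ratio 0.069 recovers the analytic ground-truth
contact fraction 0.068 to within 1%.

The analysis drivers reproduce the full study flow on the phantoms:

```bash
python analysis/01_simulate_phantoms.py   # 2D series + 4 mono / 5 co stacks
python analysis/02_colocalization_2d.py   # daily r, window-size sweep
python analysis/03_orientation_2d.py      # edges, margins, tilt ANOVA
python analysis/04_reconstruct_3d.py      # meshes, tags, morphometry table
python analysis/05_morphometry_stats.py   # MWU + KS + coverage regression
python analysis/06_ppi_screen.py          # DEGs, clusters, network
```

Step 02 prints the day-by-day correlation, which rises as MSCs migrate to
the wall and crosses the r > 0.6 threshold late in culture (day 9–10 with
the default kinematics), and confirms that coarser windows give higher r
(0.42 → 0.65 → 0.69 for 10/25/50 px on the final day). Step 05 finds the
monoculture-like group rougher on the sprouts (median A/V 0.080 vs
0.064 μm⁻¹, Bonferroni-adjusted p ≈ 0.048 with n = 4 vs 5) with the
curvature distributions separated at p ≪ 0.001 (KS).

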