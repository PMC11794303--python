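# Methods

This note records the models, parameter choices and numerical conventions
behind `soycloud`, and what the synthetic validation does and does not
establish.

## Synthetic field model

Each plant is a vertical stem carrying `n` planar elliptical leaves.  A
leaf is parameterized by attachment height (uniform over the upper 65% of
the stem), azimuth, inclination from horizontal (20–60°), and semi-axes
(a, b = 0.62a); its center sits one semi-axis out from the stem, so the
horizontal canopy reach is `a(1 + cos θ)` per leaf.  True one-sided leaf
area is exactly `Σ π a b`, which makes plot LAI (leaf area over plot
ground area) available analytically — the regression stage is validated
against an exact target, not a measured proxy.

Defaults emulate soybean 35–46 days after sowing in a row-planted trial:
stem height 0.30 m at size scale 1, 40–55 leaflets per plant (a narrow
range, as appropriate for uniform bred-line material; widening it mostly
injects leaf-count variance that no structural trait can see), in-row
spacing 0.15 m, ridge spacing 0.8 m, 10,000–20,000 returns per plant.
With these defaults a default scene's true LAI falls in the agronomic
1–6 range.

Sampling and noise:

- Points are sampled uniformly per unit leaf area (polar inversion on each
  ellipse); 4% of returns come from the stem, restricted to its upper 70%
  because the lower stem is occluded from a nadir-viewing scanner.
- Ranging noise is Gaussian with sd `noise_sd` (default 0.03 m, the
  scanner's ranging accuracy) applied along z, with a 0.15× horizontal
  component: for a nadir flight the beam is near-vertical, so ranging
  error is predominantly vertical while horizontal precision is set by the
  angular encoders.
- The ground is a smooth random surface of ≤ 1 cm amplitude (three
  incommensurate sinusoids with seeded phases), sampled at 50,000
  returns/m².  The density is chosen to be of the same order as the
  projected canopy density: a scanner that returns 10⁴ points from a
  0.04 m² canopy also densely samples the bare soil between ridges, and a
  ground stratum far sparser than the canopy would make robust ground
  extraction ill-posed.
- Outliers (class −1) are uniform in the scene bounding box, 1% of surface
  returns by default.

Canopy adhesion categories control the per-category plant size scale and a
hard cap on canopy radius: *simple* caps the radius at 0.45× the plant
spacing (guaranteed XY gap between neighbors), *ordinary* at spacing/1.75
(pairwise overlap ≤ 25% of the radius), *complex* at 0.92× spacing, which
produces chains of three or more strongly interpenetrating canopies.
Strict mutual overlap of second-neighbors (0.3 m apart) would require
0.3 m canopies, outside soybean plausibility at this stage, so "complex"
is realized as consecutive-chain overlap.

**What the generator does not model:** occlusion and multi-echo physics,
leaf curvature and petioles, wind motion, weeds, within-field soil slope
beyond centimeter roughness, and any correlation between neighboring
plants' sizes.  Passing the synthetic benchmark therefore demonstrates
algorithmic correctness under controlled geometry and noise — not field
performance, where occlusion and annotation ambiguity dominate.

## Preprocessing

Statistical outlier removal follows the classic recipe: per-point mean
distance to its `n_neighbors = 10` nearest neighbors; retain points within
`std_ratio = 1.0` standard deviations above the cloud mean (the ratio is
configurable; 1.0 is the conventional default).

Ground removal is RANSAC plane fitting (500 iterations, 5 cm inlier
threshold = ranging noise plus margin) with two refinements:

1. **Lowest-stratum selection.**  In a crop field several planar strata can
   be strongly supported — the soil, but also a dense canopy layer when
   plants carry an order of magnitude more returns than the soil beneath
   them.  Among candidates with support ≥ 70% of the best, we take the
   lowest near-horizontal stratum (plane heights within one threshold of
   the lowest candidate at ≤ 35° tilt) and, inside it, the best-supported
   plane.  Taking the lowest plane outright would bias the fit below the
   true surface; taking max support outright can return the canopy.
   Support is counted on a 30k-point subsample during iteration; the
   final classification uses every point.
2. **Post-removal denoising.**  Soil returns that ride > 5 cm above the
   plane survive the split, but once the dense soil layer beneath them is
   removed they are isolated, and a second statistical pass removes them
   with the same criterion as sensor outliers.

Points within the threshold of, or below, the refined plane are ground —
the "below" clause keeps roughness pits and deep-noise returns out of the
plant set.

## Segmentation

**Watershed.**  XY occupancy raster at 1 cm (one empty cell of padding;
binning anchored at the coordinate minima to avoid float boundary
artifacts), Euclidean distance transform in meters, markers from the
h-maxima of the distance map (depth 0.02 m suppresses per-leaf wiggle;
regional-maximum *regions* are labeled as connected components — taking
pointwise local maxima instead yields several markers per flat plateau
and splits single plants), greedy minimum-separation suppression at
0.08 m ≈ half the plant spacing (the higher peak wins), then watershed
flooding of the negative distance map restricted to occupied cells.
Points in cells left unlabeled (ridge lines, marker-free islands) take
the label of the nearest labeled cell, so every point is assigned.
Known limitation: when the footprint pinch between two canopies is
shallower than the h-maxima depth (heavy adhesion), the plants merge into
one basin; merges are scored as failures in plot accuracy.

**Max–Min k-means.**  Farthest-point initialization exactly as specified
(seeded random first center; each next center maximizes its minimum
distance to the chosen set), then Lloyd iterations until no point moves;
ties go to the lowest center index and an emptied cluster is re-seeded at
the point farthest from its assigned center.  Clustering operates on
(x, y, λz) with λ = 0.25: these plants are taller than their in-row
spacing, so under an isotropic metric the farthest-point rule can place
two seeds inside one plant (its top and bottom are farther apart than two
neighbors); plants separate horizontally, never vertically, so z is
down-weighted rather than dropped (λ = 1 restores the isotropic metric,
λ = 0 a pure planimetric one).

**Evaluation.**  Predicted instances are matched to true plants greedily
by descending point overlap, one-to-one.  A plant is *truly segmented* iff
its matched prediction covers > 50% of the plant's points and the plant
provides > 50% of the prediction's points; a prediction fed > 30% by each
of ≥ 2 plants marks them *merged*.  The 50/50 and 30% constants are the
standard dual-majority convention; the matching rule itself is a package
choice (only the outcome taxonomy is prescribed by the evaluation design).
Precision/recall/F1 are point-level, per truly segmented plant;
method comparisons use paired two-sided t-tests over per-scene means.

## Traits

- **Height**: mean z of the top 20% of points (ranked by z) minus the
  ground reference — the RANSAC plane height when the pipeline supplies
  one.  The ranked-points reading (rather than the top 20% of the z-range)
  is adopted.
- **Canopy roughness**: per-point ambiguity = orthogonal distance to the
  total-least-squares plane of the neighborhood within 0.03 m (chosen so
  the fit stays within a single leaf; neighborhoods with < 3 points get
  ambiguity 0), then CR = IQR/median with type-7 (linear interpolation)
  quartiles and CR = 0 when the median is below 1e-9 (planar cloud).  The
  ratio is dimensionless.
- **Cover**: x-extent split into 30 bins; per-bin width = y-extent of the
  bin's points; trapezoidal integration over bin centers.  The bin-center
  rule slightly under-integrates the end bins (≈ 1/n_bins relative); at
  100 bins the dense-rectangle limit is recovered within 2%.
- **Volume**: Σ over occupied 5 cm XY cells of cell² × per-cell z-range.
- **Surface area**: 2.5D Delaunay mesh with triangles dropped when any 3D
  edge exceeds 0.06 m.  Mesh vertices are per-XY-cell centroids (2 cm
  cells) rather than raw points: with 3 cm ranging noise on ~5 mm point
  spacing a raw-point mesh measures noise texture, not canopy geometry
  (its correlation with true leaf area collapses); averaging restores a
  surface-model reading.  Raw-point meshing remains available
  (`smooth_cell=None`).
- **Voxel occupancy (VOG)**: layers of edge `VOS` (default 0.05 m) from
  Z_min; `P = int(z_extent / VOS)`; `n1 = ceil(dx/VOS) · ceil(dy/VOS)`.
  The printed form of the occupancy formula is typographically ambiguous;
  the implemented canonical reading is
  `VOG = (1/(P·n1)) Σ_p min(n_T(p) + π k²/2, n1)`, which preserves every
  symbol, bounds VOG in [0, 1], and interprets the `π k²/2` term as a
  half-disc of interior voxels invisible to the beam; `k` uses the
  empirical 0.59 m constant (configurable) and clamps at 0 for narrow
  clouds.  The correction is monotone (never decreases VOG) and can be
  disabled.  The voxel-size sweep (0.008–0.14 in 0.02 steps) treats all
  lengths as meters; the centimeter units printed alongside these numbers
  are not plausible at this flight scale.

## LAI regression

Features are the six traits, z-scored with training statistics only.
Default hyperparameters — SVM: RBF kernel, C = 10, ε = 0.1; RF: 500
trees; boosting: 300 rounds, depth 4, learning rate 0.1 — are exposed in
the API; no hyperparameter search is performed (a single 3:7 random split
is the study design).  The split takes `floor(n · 0.3)` training rows (at
least 2 per side).  RRMSE divides RMSE by the mean of the observed LAI;
the gradient-boosting backend is XGBoost but any boosted-tree regressor
satisfying the scikit-learn API can be substituted.  "Feature selection"
is reported as per-feature univariate correlation with LAI
(`feature_correlations`), not automated pruning.

For the zero-variance observation edge case R² is defined as 0; RRMSE is
reported missing when the observed mean is ~ 0.

## Benchmark problem sizes

The packaged study uses 15/18/9 scenes (8 plants each, 2 ridges × 4) for
segmentation and 140 single-plot scenes (one plant on a 0.15 × 0.8 m
cell, size scale uniform in [0.7, 1.4]) for the LAI study — sizes chosen
to mirror the plot counts of the emulated experimental design while
keeping a full run in the minutes range on one CPU.  All randomness is
seeded; a fixed seed reproduces every output byte-for-byte.

## Numerical conventions

- Coordinates are meters throughout; unit conversion is the caller's job.
- Quartiles: linear interpolation (type 7).
- Distance-tie in point-to-cell reassignment and in Lloyd assignment:
  lowest label/index wins (nearest-cell lookup uses a KD-tree, whose
  exact-tie order is platform-deterministic).
- RANSAC degenerate (collinear) samples are skipped; a fully collinear
  cloud raises a fit error, as does a least-squares refit on a degenerate
  consensus set (the sampled plane is then kept).
- Instance labels are compacted to 0..n−1 in first-appearance order;
  −1 marks unassigned points.
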