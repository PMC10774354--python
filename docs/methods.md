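# Methods

`grasshh` implements the analysis chain behind the height variation
hypothesis (HVH) for grasslands: vertical vegetation structure, measured
remotely as the heterogeneity of a canopy height model (CHM), is used as a
proxy for flower diversity and for bee diversity and abundance. The chain
has four stages — surface modeling, heterogeneity indexing, regression,
and (because the field and UAV data of such studies are rarely released) a
synthetic data generator that makes the entire chain testable.

## Surface models

The input is a dense photogrammetric point cloud (LAS or XYZ text, planar
projected coordinates in meters; densities around 700 points/m² are
typical for low-altitude UAV surveys of grassland).

* **DSM** — within each target-resolution cell the highest point is
  selected, the selected points are Delaunay-triangulated in (x, y), and
  each cell center inside the convex hull receives the barycentric
  (linear) interpolation of its containing triangle. Selecting per-cell
  maxima before triangulating keeps the surface on the canopy top; a TIN
  over *all* ~700 pts/m² would interleave ground and canopy returns.
* **DTM** — the cloud is first thinned to the lowest point per 0.5 m
  filter cell (in a short sward the lowest return per half meter is
  almost surely ground), then TIN-rasterized onto the *same* grid as the
  DSM so the two can be differenced cell-wise.
* **CHM** = DSM − DTM, with negative cells clamped to 0 by default
  (vegetation height cannot be negative; clamping can be switched off for
  diagnostics). Nodata in either parent propagates.

Numerical conventions: rasters are north-up with values attributed to
cell centers; grids for one scene share an origin snapped to a multiple
of the coarsest resolution so the 10/25/50 cm grids nest; per-cell
min/max ties break to the smallest x then smallest y; cell centers
exactly on the hull boundary count as inside; fewer than three or
collinear points raise a degenerate-geometry error.

Height recovery through the chain is exact only where a cell contains
both strike types. A cell whose points are all ground strikes contributes
a ground-level vertex to the DSM TIN and locally zeroes the CHM; at
700 pts/m² and 15 % ground fraction this affects an expected
`exp(−0.85·7) ≈ 0.26 %` of 10 cm cells, and the recovery checks are
scoped accordingly.

## Heterogeneity indices

Let `x_1..x_N` be the CHM values of all non-nodata cells whose centers
fall in a transect rectangle (default 150 m × 1 m, optionally split into
three 50 m sections). Four height-heterogeneity (HH) statistics:

* **Rao's Q** `= Σ_ij d_ij p_i p_j` with uniform weights `p_i = 1/N` and
  `d_ij = |x_i − x_j|` (the 1-D Euclidean distance on a single raster
  layer); the diagonal is zero and ordered-pair normalization `1/N²` is
  used. This is the mean absolute pairwise difference, computed by the
  sorted identity `Σ_{i<j}(x_(j) − x_(i)) = Σ_k (2k − N − 1) x_(k)` in
  O(N log N); the test suite pins it to the O(N²) double sum at 1e-9
  relative. Replacing `d_ij` by `½(x_i − x_j)²` collapses Q exactly to
  the population variance — an identity also asserted in the tests.
  `N = 1` returns 0 (no pairs) rather than erroring.
* **CV** `= 100·SD/mean`, with the sample (N−1) standard deviation — the
  ecology convention; at transect N (thousands of cells) the difference
  from the population SD is negligible. Undefined (error) for N < 2 or
  non-positive mean.
* **Berger–Parker** `= n_max/N` and **Simpson's D** `= Σ p_i²` are
  abundance-based dominance measures and need categories. Continuous CHM
  values are first binned at a fixed width (default 1 cm, matching the
  ~15 mm vertical precision of photogrammetric clouds); without binning
  nearly every float value is unique and both indices collapse to 1/N.
  D is reported in its dominance form (1 = fully homogeneous), with an
  optional complement `1 − D`. Rao's Q and CV are computed unbinned.

Indices are computed per whole transect by default (the correlation unit
of the study design); per-section computation is available.

## Regression layer

Plain ordinary least squares with closed-form estimates and a two-sided
t-test (n − 2 df) on the slope — deliberately no mixed models or spatial
corrections. Two applications:

* **Raster-pair validation**: sample both rasters of a co-registered pair
  at seeded random cell centers (cell centers, so no interpolation),
  drop nodata pairs, fit `b ~ a`, and report slope, R², p and the mean
  offset `mean(b) − mean(a)` between the surfaces.
* **HH–diversity grid**: for every combination of index (4) × resolution
  (10/25/50 cm) × response (flower richness, bee richness, bee
  abundance), regress the response on the per-transect HH value. Cells
  are flagged significant at α = 0.05 as is conventional for per-cell
  reporting; a Bonferroni-adjusted flag across the grid is carried as an
  extra column rather than replacing the per-cell decision.

## Synthetic scenes and surveys

The generator emulates the study design this pipeline targets: 30
separate grassland transects of 150 m × 1 m, point density 700 pts/m²,
~15 mm vertical noise, sward mean height 0.25 m, and a planted
vegetation-height SD gradient of 0.02–0.30 m across transects (the
"field-scale" preset; a "fast" preset shortens transects to 20 m at
50 pts/m² for quick runs).

* **Height field**: white noise on a grid at ℓ/4 spacing (ℓ = correlation
  length, default 0.5 m — the scale of sward patchiness), smoothed with a
  Gaussian kernel of scale ℓ, rescaled to the target marginal SD after
  smoothing, shifted to the target mean and truncated at 0. Rescaling
  post-smoothing gives direct control of the planted σ_h that the
  recovery experiments measure. Evaluation is bilinear off the grid.
* **Point cloud**: count ~ Poisson(density × area), (x, y) uniform; each
  point is a ground strike with probability p_g = 0.15 (independent of
  location — the simplest model of photogrammetry's partial ground
  visibility) or a canopy-top strike; Gaussian vertical noise on all z.
* **Surveys**: with `hh` the standardized planted σ_h of a transect,
  `flowers ~ Poisson(exp(α_f + β_f·hh))`,
  `bee_richness ~ Poisson(exp(α_b + γ·log1p(flowers)))`, and
  `bee_abundance ~ NegBin(mean = k·exp(α_b + γ·log1p(flowers)), size = θ)`,
  with richness finally capped at abundance. Defaults α_f = log 6,
  β_f = 0.8, α_b = log 3, γ = 0.7, k = 5, θ = 5: a median transect holds
  a handful of flowering species and a few tens of bees, counts are
  overdispersed (hence the negative binomial), and the planted effect is
  strong enough that a 30-transect study detects it — free choices, since
  field studies of this design publish ranges rather than distributions.
  Setting β_f = γ = 0 yields the null configuration used for calibration.

Everything is reproducible: a scene or survey seed fixes the output
byte-for-byte, and the pipeline manifest records config and SHA-256
checksums of every table written.

What the generator does *not* emulate: real sward geometry (leaves,
stems, flower heads), photogrammetric artifacts that correlate with
structure (occlusion, matching failure in textureless areas), spatial
autocorrelation between neighboring grasslands, and observation error in
the field counts beyond Poisson/negative-binomial noise. Passing tests
therefore demonstrate that the *procedure* is correct and statistically
calibrated, not that real grasslands obey the HVH.

## Simulation experiments and problem sizes

`grasshh.experiments` packages the standing experiments (also run by
`scripts/acceptance.py`):

* **CHM recovery** — noise-free 20 m × 2 m strip, constant 0.5 m canopy,
  700 pts/m², p_g = 0.15; mean CHM over in-hull cells with both strike
  types, at 10/25/50 cm.
* **Gradient recovery** — the full field-scale preset (30 transects at
  700 pts/m²), Spearman correlation between planted σ_h and Rao's Q on
  the 10 cm CHM.
* **Null calibration** — 200 replicate regression grids with no planted
  effect, reporting the significant-cell rate. Because the null decouples
  surveys from scenes, the experiment generates 5 independent fast-preset
  scene sets and redraws surveys 40 times per set: OLS inference is
  conditional on the regressors, so the marginal per-cell type-I rate is
  identical to full re-simulation at a fraction of the cost.
* **Planted effect** — one fast-preset study at the default effect sizes,
  reporting the Rao's Q cells' significance and the spread of their R²
  across the three resolutions (the resolution-robustness property).

## Known limitations

* Ground filtering is the lowest-point rule only; progressive TIN
  densification or cloth simulation would be needed for taller or woodier
  vegetation.
* No CRS handling beyond carrying a label through GeoTIFF round-trips;
  all inputs must share one planar CRS.
* The LAS writer emits version 1.2 point format 0 at 1 mm scale; readers
  of exotic LAS payloads (waveforms, extra bytes) are out of scope.
* Simpson's D and Berger–Parker depend on the binning width; 1 cm is a
  package default, not an empirical calibration.
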