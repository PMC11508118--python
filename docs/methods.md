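# Methods

## The score pipeline

The composite inundation score is a deterministic function of a
projected DEM with square, meter-unit cells. Stages, in order:

1. **Pre-smoothing.** 5×5 focal mean. Integer-valued source DEMs
   become fractional, and single-cell artifacts are damped. Edge
   policy is *shrink*: the window is intersected with the grid and the
   mean taken over the valid cells only (reflect padding is available
   as an option). Nodata propagates — a nodata cell stays nodata and
   is omitted from its neighbors' windows.
2. **Depression filling.** Priority-flood from the grid boundary (and
   from cells adjacent to nodata, which are also exits). Output ≥
   input everywhere; draining cells are untouched. An optional epsilon
   (default 0) enforces a strict gradient across filled flats.
3. **D8 routing.** Each cell drains to the neighbor with the largest
   positive drop per distance (diagonals √2 longer). Ties go to the
   first maximum in the fixed scan order N, NE, E, SE, S, SW, W, NW,
   making routing fully deterministic. Boundary cells with no lower
   neighbor are outlets. Cells inside flats are routed toward the
   flat's spill point by breadth-first distance from the draining
   edge. A genuine interior pit raises an error by default
   (`pit_policy="error"`); `pit_policy="sink"` instead accepts it as
   an interior sink, which is occasionally useful on deliberately
   unfilled toy grids.
4. **Flow accumulation.** Upstream cell count per cell, the cell
   itself excluded (a config flag includes it). Computed by
   topological propagation over the direction graph; a cycle aborts
   with the offending coordinates.
5. **Log transform.** `log10(x + 1)` per cell: zero accumulation maps
   to zero and ranking is preserved. Base e is available.
6. **Post-smoothing.** 25×25 focal mean applied twice, suppressing
   microtopography so the score reflects landscape-scale convergence.
7. **Normalization.** Min–max to [0, 1] over the analysis extent.
   Consequence worth noting: per-site water-accumulation scores depend
   on the extent supplied, so extracted values are comparable only
   within one run.
8. **Convexity.** Second derivatives of the 3×3 neighborhood by
   central differences (the Zevenbergen–Thorne quadratic, exact for
   quadratic surfaces). Longitudinal convexity is minus the second
   directional derivative along the gradient; cross-sectional is
   minus the derivative perpendicular to it. The sign flip puts
   concave, water-stagnating forms below zero. At zero-gradient cells
   the unrotated north–south and east–west derivatives are used
   (same sign convention) so symmetric valley floors and crests are
   still scored rather than dropped. Boundary cells are nodata unless
   reflect padding is requested. By default convexity is evaluated on
   the DEM after the 5×5 filter plus one 25×25 pass
   (`convexity_source="post_smoothed_once"`); the stage is
   configurable (`raw`, `pre_smoothed`, `post_smoothed_twice`) because
   the reference procedure is ambiguous about which smoothed surface
   the curvature came from, and smoothed-surface curvatures differ in
   magnitude from raw ones.
9. **Composition.** `score = WA × |LC| × 100` where `LC < 0`, else 0.
   The clip is decided by the longitudinal convexity alone; this
   reconstruction reproduces all seven published site rows, including
   the two zero rows (one of which has *negative cross-sectional*
   convexity, ruling out a both-convexities clip). A
   `product_of_both` mode that also multiplies by |cross-sectional
   convexity| is provided for sensitivity analysis. The ×100 scale
   factor puts scores in a convenient 0–1.1 range for these
   landscapes.

Printed-table comparisons round half-up to 2 decimals (`round_half_up`),
matching how agronomy tables are typeset; Python's banker's rounding
would differ on exact halves.

## Statistics

* **OLS** (`ols_fit`): statsmodels under the hood; adjusted
  R² = 1 − (1−R²)(n−1)/(n−2); two-sided slope *t*-test. The analysis
  excludes one site (Nandiala) from the water-condition regressions as
  an explicit, logged flag — its submergence is controlled by
  groundwater and a road embankment, not terrain — never as automatic
  outlier removal.
* **Correlations**: `correlation_matrix(method="pearson"|"spearman")`.
  The published texture–chemistry matrix reproduces under the
  product-moment coefficient (e.g. sand–clay −0.93; the rank
  correlation of the same 34 horizons is −0.87), so the Pearson route
  is the one validated against printed values while the Spearman route
  is validated against a rank-enumeration oracle.
* **Group comparisons**: Welch *t* with Satterthwaite df; one-way
  ANOVA with Tukey HSD (Tukey–Kramer for unbalanced groups) and an
  insert-absorb compact letter display. α = 0.05 throughout.
* **PCA** (`pca_standardized`): columns z-scored with ddof = 1, then
  PCA of the standardized matrix — equivalently an eigendecomposition
  of the sample correlation matrix. Loading columns are unit-norm
  eigenvectors; variance proportions are eigenvalues over their sum.
* **Saturation indices**: BS = 100·(Na+K+Ca+Mg)/CEC (may exceed 100
  when ammonium-acetate bases overshoot the measured CEC, as one
  published topsoil row does); EBS = 100·bases/(bases+Al) ≤ 100.

## Packaged tables and their limits

The three CSVs carry the published values at printed precision (2
decimals for yields and cations, 3 significant figures in exponent
notation for convexities; the verbatim printed strings are kept in
`*_printed` columns). Consequences:

* Statistics recomputed from them can differ from published ones in
  the last printed digit. The CT yield regression gives slope 1.7356
  and intercept 0.5517 against the published 1.73 and 0.56 — the
  original fit used unrounded source values. Tests therefore compare
  at one printed ulp (±0.01).
* EBS recomputed from 2-dp cations matches the printed column within
  ±0.1 on typical horizons but degrades to ~0.8 where the base sum is
  tiny (worst case: a horizon with bases summing to 0.35 cmolc/kg).
* Replicate-level yields, per-year precipitation, and the
  significance letters of the published trial table are not
  published; the corresponding machinery (ANOVA/Tukey/letters, PCA
  loadings) is validated by property tests and oracles instead of by
  printed values.

## Synthetic generators

`simulate_dem` composes a southward tilt, an optional concave
footslope profile (`profile_curvature`, 1/m: the slope decays
downslope, giving longitudinal convexity −profile_curvature
everywhere), a parabolic channel of configurable depth and width along
the center column, a few broad seeded Gaussian hills, and white
elevation noise. Defaults are 5 m cells and ≥30×30 grids (smaller
grids leave no room for the 25×25 filter). The channel's cross-axis
curvature is 8·depth/width² per cell², used as the analytic check.
A purely tilted plane with a translationally invariant channel has
near-zero curvature *along* the gradient on the channel axis, so
valley scenarios meant to exercise the longitudinal-only composite
must set `profile_curvature > 0`; the test configuration uses 2×10⁻⁵
1/m with a 30-cell channel on a 100×60 grid, where channel-axis cells
out-score the flanks by an order of magnitude across seeds.

`simulate_trial` draws plot-level yields linear in the site score with
independent Gaussian noise per treatment/site/year, floored at zero.
Default slopes/intercepts for CT and NK are the fitted field values
(1.73/0.56 and 1.71/1.26 Mg/ha per score unit); the P-fertilized
treatments default to flat responses at their all-site mean yields
(3.52 and 4.15 Mg/ha) with pooled SDs (0.5–1.9 Mg/ha). The generator
emulates the *linear-plus-noise* structure only: no year effects, no
spatial correlation, no heteroscedasticity, so passing recovery tests
demonstrate estimator correctness, not robustness to real field data.

## What synthetic tests do not show

The raster stages are validated on exact quadratics, toy grids and
brute-force oracles (priority-flood re-implementation, path-walking
accumulation). Real DEM tiles bring sensor noise, projection
resampling and landform scales interacting with the fixed 5×5/25×25
windows; curvature magnitudes from differently smoothed surfaces are
not comparable to the published per-site convexities, which came from
proprietary operators. The score-composition stage is therefore
validated on the published component values directly, and the raster
pipeline on structural properties (axis vs. flank ordering, sign
behavior, offset invariance, determinism).

## Numerical choices

Focal means use a separable uniform filter on value and validity
planes (sum/count), agreeing with the per-cell loop oracle to 1e−12.
D8 tie-break and the neighbor scan order are pinned by test. Filling
uses a stable heap (insertion-order tiebreak). Convexity at boundary
cells is nodata by default. The compact letter display inserts a
split per significant pair and absorbs subset columns, guaranteeing
significant pairs never share a letter and non-significant pairs do.
Degenerate inputs fail loudly: all-nodata grids, constant grids under
normalization, constant regressors/vectors, zero-variance PCA columns,
CEC ≤ 0, empty groups.
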