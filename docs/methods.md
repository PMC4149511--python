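# Methods

This note documents the models, defaults and numerical choices behind
`gridrep`, and what its simulations do and do not establish.

## The evaluation model

A *population* is a regular raster of elevation values; a *design* is an
ordered set of planar points inside its extent.  The pipeline treats
sampling-design adequacy as three separate questions, each with its own
statistic:

1. Does the sample's value distribution match the population's?
   Two-sample Kolmogorov–Smirnov D between the sampled values and all
   non-missing population cells.  The same test is applied to the full
   set of interpolated cell values.  D is computed exactly as the
   supremum of the ECDF difference over the pooled sorted values, which
   is correct under ties; the p-value uses the limiting Kolmogorov
   distribution at √(n_eff)·D.  With population sides of thousands of
   cells the limiting form is standard; it diverges from finite-n
   refinements only for very small joint sizes (the test suite checks
   convergence against an independent implementation at population
   scale).
2. Does an interpolated surface co-vary with the truth?  Pearson r over
   cell-wise (predicted, true) pairs.  If either side has zero variance
   the correlation is *undefined* and reported as NaN — never coerced to
   0, and excluded listwise from trend fits, because flat areas carry no
   similarity information and a fabricated 0 would bias trends.
3. How large are the cell-wise errors?  RMSE over the same pairs, in
   meters.

Samples extract the value of the cell whose center is nearest the
design point (ties toward the lower row/column).  No bilinear smoothing:
a sample must be an actual population value or the KS comparison stops
being a sample-versus-population test.

## Designs

* `regular_lattice(extent, n, rng)` places an r×c lattice (the factor
  pair of n minimizing c−r) at spacings (width/c, height/r), then adds a
  uniform offset in (−s/2, s/2] per axis and wraps points torus-fashion
  back into the extent.  The wrap preserves both the spacing and the
  exact count for every iteration, which is the property that makes
  "10 iterations per size" meaningful: iterations differ only in
  anchoring.  For prime n > 3 (never used by the default sizes) the
  lattice of the largest composite below n is used.
* `rapeld_design(raster)` is deterministic: six north–south trails at
  1 km spacing (clamped half a cell inside the extent), five plots per
  trail at y = 0.5…4.5 km — 30 plots, consecutive plots 1 km apart.

## Interpolation

IDW with exponent 2 and a global neighborhood is the default; both are
configurable (`IdwConfig`).  Distances are planar Euclidean meters —
all frames are local 5×5 km tiles, so no geodesy.  Predictions are
convex combinations of sample values (bounded by the sample min/max,
exact at sample locations, translation-equivariant).  The weighted mean
is computed as a shift from the sample mean, so a constant sample
yields an exactly constant surface instead of one polluted by ~1e-14
rounding residue, which matters because the KS statistic compares
values exactly.

## Synthetic terrain

`make_gaussian_field(TerrainSpec)` smooths seeded white noise with an
isotropic Gaussian kernel (periodic boundaries), standardizes, and
affinely rescales so the realized raster mean and SD equal the targets
exactly.  The kernel width is set so the field autocorrelation is
approximately Gaussian with scale `correlation_length`.

Defaults describe the study conditions the simulation experiment
emulates: 56×56 cells of 90 m (a 5×5 km tile at elevation-model
resolution), target mean 159.5 m (the Amazon-wide mean of the setting
that motivated the package), per-area SD drawn uniformly from 1–56 m
(the heterogeneity band covering ~95% of that region; observed SDs
range up to ~466 m but 90% of areas fall at or below 40), and
correlation length 1,000 m — a value chosen once as realistic for
terrain that varies smoothly at the kilometer scale while retaining
sub-kilometer texture.  `tail="long_tailed"` exponentiates the
standardized field before rescaling, forcing right skew (sample
skewness > 0.5 at SD 40) to emulate floodplain-dominated tiles with a
long high-elevation tail.

What the generator does *not* emulate: anisotropy and persistent
directional gradients (use `make_ramp` for controlled experiments),
drainage networks, terraces, or the marginal distributions of any
specific real site.  Consequently, passing simulations show the
pipeline's statistics behave correctly and that adequacy thresholds are
recoverable under stationary isotropic heterogeneity; they do not
certify particular thresholds for real landscapes — run the pipeline on
your own rasters for that.

## Trend smooths

`fit_smooth` fits `y ~ s(sample_size) + s(sd)`: one cubic B-spline
smooth per covariate with up to 10 interior knots at covariate
quantiles (duplicates collapsed, so a covariate with 6 distinct values
gets the basis its support can identify), each basis centered for
identifiability against the intercept, a second-difference penalty per
smooth, and one common smoothing parameter λ minimizing
`GCV(λ) = n·RSS/(n − edf)²` over a 40-point log grid spanning 1e−6 to
1e8 (a 1e−10 ridge keeps the penalized normal equations solvable, since
the penalty's null space contains all linear trends).  Deviance
explained is 1 − RSS/TSS clipped to [0, 1]; pointwise 95% bands are
fit ± 1.96·SE with SE from the penalized hat matrix and
σ² = RSS/(n − edf).  Whether the underlying trend analysis should use
univariate additive smooths or a bivariate surface is genuinely open;
additive univariate smooths are implemented because the responses'
dependence on size and SD is reported separately throughout.

Zero-variance covariates lose their smooth with a warning; rows with
NaN response (undefined correlations) are dropped before fitting; a
constant response reports deviance explained 0.

## Conditional-inference trees

`fit_ctree` follows the conditional-inference scheme with Monte-Carlo
permutation inference instead of asymptotic conditional-distribution
theory: exact-in-distribution at small node sizes, seedable, and free of
specialized distribution code.  Per node: the association statistic is
`|Σ(xᵢ−x̄)(yᵢ−ȳ)|`; its permutation p-value is plus-one corrected over
B permutations (default B = 9,999; the pipeline config uses 999, a
deliberate desk-scale choice that leaves p-value resolution of 1e−3,
ample against α = 0.05); covariate p-values are Bonferroni-adjusted
across the (non-constant) covariates; the node becomes a leaf when the
minimum adjusted p ≥ α (default 0.05), the node has fewer than
2·min_node rows (default min_node 20), or y is constant.  Otherwise the
most significant covariate is split at the cutpoint maximizing
`|ȳ_L−ȳ_R|·√(n_L·n_R/n)` over midpoints between distinct sorted values,
subject to min_node per child, ties to the lower cutpoint.  One shared
permutation-index matrix per node serves both covariates; the statistic
is compared raw because the permutation SD is constant across
covariate-wise comparisons and cannot change the p-value ranking.
Affine transforms of y rescale observed and permuted statistics alike,
so p-values are invariant (up to equality-tolerance ties).

## Pipeline and seeding

`run_experiment` spawns one `SeedSequence` child per area from
`master_seed`: child 0 drives area-level draws (SD, tail selection),
child i+1 drives area i's terrain seed and its lattice offsets, and a
final child seeds tree permutations.  Areas are therefore independent
and individually recomputable, and two runs with equal configuration
are byte-identical.  Raw tables hold
2 · areas · sizes · iterations rows; mean tables average iterations
within (area, size, source) and are what the smooths and trees consume,
so between-iteration noise does not masquerade as trend signal.  An
area that fails is logged, skipped, and counted in the run manifest;
partial tables are flushed per area.

The default experiment scale — 50 areas, six sizes, 10 iterations —
keeps a full run around ten seconds on one CPU while leaving the
trend shapes (mean interpolation RMSE falling, mean sample KS p rising
with sample size) stable across master seeds.

## Known limitations

* The IDW exponent and neighborhood of the original tooling this
  workflow echoes are unreported; results are tied to the power-2,
  global-neighborhood default, though both are exposed.
* The limiting-Kolmogorov p-value is anti-conservative for very small
  joint sample sizes; `ks_two_sample(..., method="exact")` provides the
  small-sample exact variant, but the pipeline's scoring uses the
  asymptotic form throughout.
* The interpolation-KS arm inherits the enormous power of a
  population-vs-population comparison: with thousands of cells per
  side, even mild over-smoothing drives p to zero.  Trends in that
  response are dominated by D, not p.
* GCV occasionally under-smooths in small tables with near-duplicate
  covariate values; the 1e−10 ridge bounds but does not eliminate the
  resulting variance.
* No stratified/random/clustered comparison designs, no riparian-plot
  derivation, no geodetic handling, no variogram-based interpolators.
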