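# Methods

`rsfpipe` implements a seasonal resource-selection analysis for
GPS-collared animals in an agricultural landscape, exercised end to end on
synthetic data with known ground truth.  This note documents the models,
the defaults and why they were chosen, the numerical machinery, and what
the synthetic study does and does not establish.

## The model

Selection is modeled with a used/available design.  Each recorded GPS fix
(cleaned and binned, below) is a *used* location (y = 1); for every used
location one *available* location (y = 0) is drawn uniformly from the
individual's seasonal 100% minimum convex polygon (the convex hull of its
cleaned fixes in that season).  Each location l gets:

- **proportional coverage** x_c for each land-cover category c: the
  fraction of raster cells whose centers lie within a 100 m buffer of the
  location that map to category c (30 m cells; 37 cells per full buffer);
- **distance to the nearest flowline** (stream/canal/ditch polylines),
  entered as a standardized linear term x_f and a *centered-then-squared*
  quadratic term, standardize((d − d̄)²), which keeps the linear and
  quadratic terms interpretable independently.

Per season, the binary response is fit with a random-intercept logistic
(binomial GLMM):

    logit P(y_ij = 1) = x_ij' β + b_i,    b_i ~ N(0, σ_b²)

with individual i as the grouping factor.  One coverage category is the
reference and is excluded from the design (proportions are compositional);
the remaining categories, plus the two flowline terms, are the fixed
effects.  Inference is Wald at α = 0.05: a coefficient whose 95% interval
covers zero is reported "neutral".

Fixed effects feed two products:

- **selection curves**: p(l) = logistic(β₀ + β_c P + β_w (1−P) + β_fl x_f +
  β_fq x_f²) for a location covered by a focal crop (proportion P) and
  wetlands (1 − P), evaluated over P ∈ [0, 1] at the 0/50/100% quantiles
  of the season's observed flowline distances.  The linear predictor is
  affine in P, so each curve is monotone with slope sign equal to
  sign(β_c − β_w) — an algebraic invariant the tests assert.
- **prediction maps**: the same expression evaluated per raster cell from
  moving-window coverage and the cell center's flowline distance.  The
  random intercept is excluded: maps describe population-level *relative*
  selection, not absolute probability of use.

### Aggregation competition

Raw land-cover codes are collapsed into modeled categories by one of four
a-priori aggregation hypotheses: H1 (individual crops; wetland distinct
from other natural cover), H2 (individual crops; wetland merged into other
non-crop), H3 (all crops equivalent; wetland distinct), H4 (all crops
equivalent; all natural cover equivalent).  All four designs are built
from the *same* used/available points, fit per season, and ranked by
AIC = −2ℓ + 2k with k counting the fixed effects plus one variance
component; a runner-up ΔAIC ≥ 2 is reported as decisive.  Open water is
kept as its own category under every hypothesis, with the config free to
collapse it.  The pipeline carries only the AIC winner into curves and
maps.  Competition is ranked within each season; the per-season tables can
be summed by the caller for a cross-season view.

### Collinearity screen

Proportional coverage is compositional and therefore collinear by
construction.  VIF_k = 1/(1 − R²_k) is computed for every predictor by
OLS on the design; VIF ≥ 3 triggers a warning.  On synthetic landscapes
where the reference category is scarce the VIFs genuinely exceed 3 — the
screen reports rather than blocks, since the fitted likelihood is still
well defined.

## Telemetry QC

1. **Speed filter** (default 20 km/h): a single sequential pass holding
   the last retained fix as anchor; a fix implying a straight-line speed
   above the limit from the anchor is dropped and the anchor stays, so a
   run of aberrant fixes is removed against the same good fix.  The
   output never contains a consecutive pair exceeding the limit, and the
   pass is idempotent.
2. **Deployment trimming**: fixes within 24 h of collar deployment or of
   the track end (mortality/retrieval) are dropped; a missing bound leaves
   that side untrimmed.
3. **Even-hour binning**: only fixes within 5 min of a whole hour are
   kept, relabeled to that hour; the closest fix wins a contested bin
   (earlier on ties).
4. **Independence screen**: for every pair of binned tracks, fixes are
   matched on identical bin times; with ≥ 30 matched bins (correlation on
   fewer points is not meaningful), Pearson r is computed per axis.  A
   pair with |r| > 0.5 on *both* axes is dependent; a random member of a
   random flagged edge is removed (seeded) until no flagged edge remains,
   which handles cliques larger than two.  Correlations are computed once
   on the full track set rather than recomputed after each removal.

All geometry is planar (projected meters); real inputs must be projected
upstream — the package does no geodesy.

## The mixed-model fitter

The marginal likelihood integrates each group's Bernoulli likelihood over
its Gaussian intercept.  The 1-D integral per group uses adaptive
Gauss–Hermite quadrature: 15 nodes (default) recentered at the conditional
mode of b_i (found by a safeguarded Newton iteration — the integrand is
log-concave) and rescaled by the conditional curvature.  σ_b is optimized
on the log scale (floor 1e-6; estimates at the floor are reported as
σ_b = 0 with a boundary flag).  The gradient uses Fisher's identity (the
posterior expectation of the complete-data score on the same nodes);
optimization is L-BFGS-B followed by Newton polishing until the score's
∞-norm is below 1e-6.  Standard errors come from the inverse numerical
Hessian (central differences of the analytic gradient).  `fix_sigma_b`
pins the variance for profile fits; at 0 the model reduces to plain
logistic regression through the same quadrature path, which is the lever
the test suite uses to compare against an independent IRLS fit.

Numerical checks in the suite: the quadrature log-likelihood agrees with
dense trapezoid integration (10,000 points over ±8σ) within 1e-6;
doubling the nodes (15 → 31) moves estimates by < 1e-5; a Wald-interval
calibration study (200 replicates, 13 groups × 1,500 rows, σ_b = 0.5)
keeps per-coefficient 95% coverage inside [90%, 99%] with mean bias below
0.05.

Degenerate inputs: a constant response or apparent separation yields a
flagged (non-converged) result with diagnostics rather than an exception;
a rank-deficient design raises.  AIC counts the variance component as one
parameter.

## Raster similarity

For probability rasters A and B of identical geometry,

    S = 1 − Σ d² / Σ Δ²,   d = A − B,   Δ_ij = max(B_ij, 1 − B_ij),

where Δ is the cellwise difference between B and the binary raster
arranged to maximize disagreement with B (0 where B ≥ 0.5, 1 elsewhere;
at exactly 0.5 both choices give 0.5).  S runs from 0 (as far from B as
any 0/1 raster can be) to 1 (identical), needs no distributional
assumptions, and is *asymmetric*: the denominator is defined by the target
(second) raster.  The pairwise matrix therefore fills all ordered pairs;
the conventional rendering is the lower triangle at 7 decimal places.
Values are accepted on the closed interval [0, 1]; cells missing in either
raster are dropped from both sums.  The suite verifies Σ Δ² against
exhaustive enumeration of all 2^(mn) binary rasters on grids up to 3×3 and
asserts S(A, A) = 1 bit-exactly.

## The synthetic study

No real telemetry or land-cover extract ships with the package, so the
generator recreates the study conditions with known truth:

- **Landscape**: a 300 × 300 grid of 30 m cells (9 × 9 km).  A Gaussian
  random field smoothed at 4 cells is split at its empirical quantiles to
  hit target class frequencies — soybeans 38%, wetland 23%, corn 12%,
  idle cropland 8%, shrubland 6%, cotton 5%, rice 4%, water 2%, developed
  2% — mirroring the study region's reported crop mix, with the
  unreported remainder split once and kept fixed.  Smoothing produces
  contiguous patches; `patch_scale=0` gives i.i.d. cells.
- **Flowlines**: 6 wavy edge-to-edge polylines.
- **Animals**: 13 individuals with fixed disc home ranges (radius 1.5 km)
  emitting 2-hour fixes across the four seasons (early growing 1 Mar–15
  May 2016, late growing 16 May–31 Jul, harvest 1 Aug–31 Oct, fallow
  1 Nov 2016–31 Jan 2017).  Three are deployed late and two drop out
  early, so seasonal full-span inclusion varies as in real deployments.
  Each fix is drawn within the disc with probability proportional to
  exp(β₀ + b_i + Σ β_k x_k) evaluated at cell centers with the same
  coverage/distance predictors the pipeline later computes (the true
  flowline terms act on distance in km so their magnitudes are comparable
  to the coverage terms).  Per-season truth coefficients follow the
  system's qualitative story — wetland attractive year-round, corn avoided
  early and selected once grown, rice peaking at harvest — with
  σ_b = 0.5.
- **Defects**: 2% speed spikes (extra fixes inserted midway between
  consecutive fixes, displaced to twice the removable speed limit), 2%
  off-hour timestamp shifts (6–25 min), and one companion animal whose
  coordinates are the first animal's plus 50 m Gaussian jitter.  Injected
  defects are recorded so QC recall is computable.

What the generator does **not** emulate: serially correlated movement
(fixes are independent draws, so home ranges are stable discs, not
random walks), group (sounder) dynamics, seasonal home-range drift, GPS
fix-rate failure, or habitat-driven detectability.  A consequence worth
noting: with exactly balanced 1:1 used/available sampling per individual,
the individual random intercept absorbs almost nothing and its estimate
sits at or near the boundary — the fitter's variance recovery is instead
validated on direct logistic simulations where b_i genuinely perturbs the
response.  Passing tests therefore demonstrate correctness of the
estimators and plumbing under the stated design, not robustness to
autocorrelated real telemetry.

## Numerical and design choices

- Buffer membership is cell-center-in-radius (not area-weighted); with
  30 m cells and a 100 m radius this is cheap, unambiguous, and matched
  exactly by the brute-force enumeration oracle and by the moving-window
  convolution used for maps (edge-clipped windows renormalize over the
  surviving cells in both paths).
- Standardization constants (mean/SD of raw distance, and of the centered
  square) are computed over the pooled used + available rows within a
  season — the model's estimation sample — and are stored in the design
  table and in every fitted model, so curves and landscape projection
  reuse the training-sample constants rather than restandardizing.
- Season boundaries are inclusive on both ends; span tolerance defaults to
  0 days.
- Availability sampling is bounding-box rejection, seeded; identical seeds
  reproduce tables bit-exactly.  One master seed spawns per-stage seeds so
  stages can be rerun in isolation.
- Rasters travel as ESRI ASCII grids (text, georeferenced) with `repr`
  float formatting so round-trips are bit-exact; tracks and design tables
  as delimited text (the table carries its standardization constants and
  scheme metadata in a JSON header line); fitted models as JSON.
- Test and acceptance runs use a scaled-down study (6 individuals on a
  120 × 120 grid) chosen as the smallest configuration where every season
  retains at least two individuals and the aggregation competition is
  informative; the full 13-animal configuration is the default for the
  numbered analysis scripts.

## Known limitations

- The speed filter's anchor semantics differ from pure
  consecutive-pair filtering when errors cluster; both remove the later
  fix, but the anchor rule is deterministic for runs of bad fixes.
- VIFs on compositional coverage predictors routinely exceed the warning
  threshold when the reference category is scarce; the warning is
  informational.
- S compares rasters cellwise; it carries no spatial structure, so two
  maps differing by a small shift can score low.
- Numerical results tied to a particular field deployment (specific
  seasonal coefficient values, specific map-similarity entries) depend on
  that deployment's GPS and land-cover data; the pipeline reproduces the
  *procedure* and its internally verifiable quantities on synthetic
  conditions.
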