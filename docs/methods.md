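# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices a maintainer would want recorded.

## Data model and conventions

All coordinates are planar meters on an abstract plane; the package does no
datum or projection handling because every computation it performs is
scale-invariant given the cell size.  Grids use a fixed convention chosen
once: row 0 is the southernmost row, cell (r, c) covers the half-open square
`[x0 + c·s, x0 + (c+1)·s) × [y0 + r·s, y0 + (r+1)·s)`, and a point is in a
cell iff the half-open intervals contain it — so a point on a shared edge
belongs to exactly one cell.  The reference resolution is 131 m, the cell
size of the motivating survey's habitat rasters.  Rasters are read and
written as ESRI ASCII grids (a plain-text format; note its rows run north
to south and are flipped on I/O).  Bathymetry is stored negative (depth
below datum); "shallower" means closer to zero.  Rugosity is a ratio >= 1.

Raw occurrence points are collapsed to at most one presence per grid cell
(pseudoreplication guard); among same-cell points the first in input order
is kept, and off-grid or nodata-cell points are dropped with a logged count.
The survey domain is a set of strip-transect polygons; its cell mask is the
set of cells whose centers fall inside any polygon.

## Kriging and rugosity

Habitat point samples are interpolated by ordinary kriging: an empirical
semivariogram (default 12 lag bins up to half the maximum pairwise
distance), a weighted least-squares fit (weights = pair counts, multi-start
bounded optimization) of a spherical (default), exponential, or Gaussian
model, and local kriging from the k = 12 nearest samples with the
weights-sum-to-one constraint enforced by a Lagrange multiplier.  Local
neighborhoods keep the cost at O(cells · k³) rather than a global solve.
Duplicated sample locations are averaged before solving; kriged percent
covers are clamped to [0, 100] because the interpolator can overshoot the
data range.  One convention worth stating: the fitted variogram curve jumps
to the nugget as h -> 0+, but the kriging system uses gamma(0) = 0 on its
diagonal and right-hand side (the semivariogram of a point with itself),
which is exactly what makes the interpolator honor the data when the nugget
is zero.  The default variogram settings are stated and configurable
because the original ArcGIS workflow's settings are not documented.

Rugosity is derived from bathymetry as true (3-D) surface area over
planimetric area in a 3x3 window: the depth surface over cell centers is
triangulated (two facets per lattice square, eight per window) and facet
areas are summed.  A flat surface gives exactly 1 and a plane of constant
slope s gives sqrt(1 + s²).  Cells whose window is incomplete or touches
nodata become nodata, so derived rugosity loses a one-cell border.

## Covariate screening

Multicollinearity is screened by stepwise variance inflation factors:
VIF_j = 1/(1 - R²_j) with R²_j from regressing covariate j (with intercept)
on all others; while any VIF exceeds the threshold the single largest is
dropped and the VIFs recomputed.  The threshold defaults to 10, the
conventional default of the stepwise VIF method, and is a config key.  Ties
drop the earlier column in input order.  The screen can run on any
cell-by-covariate table; the CLI runs it over survey-domain cells.

## The maximum-entropy model

Features are built from covariates min-max scaled over the training sample
(presences plus background): L = z, Q = z², and hinge features
max(0, (z-k)/(1-k)) and max(0, (k-z)/k) at 50 evenly spaced interior knots
per direction (both counts configurable).  Constant feature columns are
dropped; at projection time covariates are clamped to the training bounds,
so every feature stays in [0, 1].

Per-feature lasso penalties follow the standard sample-size-interpolated
schedule — anchors n = (0, 10, 30, 100) with betas (1.0, 1.0, 0.2, 0.05)
for linear and quadratic features, flat beyond the last anchor, and a
constant 0.5 for hinges — scaled at fit time by the feature's
presence-sample standard deviation over sqrt(m), floored by 0.001 of the
feature range and by the hinge identifiability bound, and multiplied by the
global regularization multiplier.

The penalized objective is convex and is minimized by cyclic coordinate
descent with per-coordinate proximal Newton steps (soft-thresholding); each
step is halved until the exact objective does not increase, so the
objective is non-increasing at every accepted update.  Convergence is
declared when no coordinate moves more than 1e-6 in a verifying full sweep
(cap 1000 sweeps, warning flag on non-convergence); an active-set schedule
skips zero coefficients between periodic full sweeps.  Stationarity (KKT)
violations on test fits are below 1e-4.  Presence cells are included in the
background sample for the partition function by default (the reference
behavior; a flag disables it).

Raw output is normalized so the background raws sum to one.  The default
report scale is the complementary log-log transform
`1 - exp(-e^H · raw)` with H the entropy of the fitted background
distribution — the convention of MaxEnt 3.4.3, whose defaults the analysis
design invokes; a uniform model maps to 1 - 1/e ~ 0.632 everywhere.  The
transform is monotone in raw, so every rank-based metric is identical under
either scale.

Habitat-association reports: percent contribution credits each coefficient
update's drop in unpenalized negative log-likelihood to the updated
feature's covariate (negative totals floored at zero, normalized to 100%);
permutation importance permutes one covariate jointly across the
presence+background sample, rebuilds features, and averages the training
AUC drop over 120 iterations (floored, normalized); response-curve
direction is the sign of the Spearman correlation between a covariate and
its marginal cloglog curve (all other covariates at background means), with
|rho| < 0.05 or an all-zero coefficient reported as NA.

## Evaluation, tuning, and selection

AUC is the Mann-Whitney estimator with half credit for ties, computed
presence-versus-background (the full background stands in for absences in
both training and validation; no background partitioning).  OR10 thresholds
at the linear-interpolation 10th percentile of calibration presence scores
and counts test presences strictly below it.  Presences are split by random
k-fold partitioning (k = 5 by default, sizes differing by at most one);
AUC_diff is differenced per fold and then averaged, which is why the
averaged difference need not equal the difference of averages.  AICc
refits on all presences, standardizes raw output to a probability mass over
all landscape cells, takes lnL as the summed log mass at the presences, and
uses K = nonzero coefficients; it is undefined (and excluded from
selection) when n <= K + 1.

Tuning enumerates feature sets {L, LQ, H, LQH} by multipliers 1-5 — twenty
candidates — scoring each with cross-validated metrics plus full-data AICc.
Sequential selection filters to the lowest mean OR10, then the highest mean
AUC_val, with remaining ties resolved toward the lower multiplier and the
simpler feature set; AICc selection minimizes AICc with ties toward fewer
parameters.

## Null-model significance testing

The selected specification is referenced against a null distribution built
from randomly placed occurrences.  Each of the (default) 1000 iterations
draws one uniform random occurrence set from the survey domain with the
same size as the empirical presence set, partitions it with the same fold
assignment, and runs the identical cross-validation against the same
background: AUC_train on the drawn calibration folds, AUC_val and OR10 on
the drawn withheld folds.  Because the null statistic is produced by
exactly the procedure that produced the empirical one — differing only in
where the occurrences sit — the two are exchangeable when the species is
habitat-indifferent, which is what calibrates the test.  The package's own
simulations bear this out: for a uniform virtual species the empirical
AUC_val falls inside the null 90% band at the nominal rate, while for an
informative species (coefficients +3/-3 on two covariates, 500 presences,
60x60 landscape) the standardized effect size on AUC_val is typically in
the 11-18 range.

A design alternative — validating null models on the *empirical* withheld
presences rather than their own withheld draws — was implemented and
measured during development and is worth recording as a limitation of that
alternative: with the empirical test set frozen across iterations, the null
AUC_val fluctuates only through the fitted model, so for low-dimensional
models its spread badly understates the empirical statistic's spread
(measured 90%-band coverage near 70% for a 3-covariate linear model) and on
informative landscapes its location drifts above chance.  The own-withheld
design in the package shows neither pathology and reproduces the
characteristic printed pattern of such analyses: null AUC_val slightly
below null AUC_train (a positive null overfitting gap) with small,
similar-magnitude standard deviations.

Comparison reports, per metric: z = (empirical - null mean)/null SD, the
one-sided normal-tail p in the metric's favorable direction (greater for
the AUCs, less for AUC_diff and OR10), an empirical-rank p alongside, and
the 0.01/0.05/0.95/0.99 null quantiles.  A degenerate null (zero SD, e.g.
on a constant landscape) falls back to the rank p and is flagged.  Null
iterations are seeded individually from (seed, iteration index), so runs
can be split and merged bit-identically.

## Synthetic data: what it emulates, and what it does not

Landscapes are Gaussian white noise convolved with a Gaussian kernel
(correlation length = `smoothness` cells, default 4) and rank-rescaled to
uniform margins on the attribute's range — the simplest generator with
controllable spatial autocorrelation, standing in for kriged (hence smooth)
percent-cover surfaces.  Percent covers span [0, 100]; bathymetry spans
(-170, -1) m, the depth range of the motivating drop-camera survey;
synthetic rugosity is derived from the synthetic bathymetry rather than
drawn independently, as in the real workflow.  Survey designs are parallel
north-south strips (width and spacing in cells, defaults emulating 400 m
strips every ~4 km at 131 m cells).  Virtual species sample presence cells
without replacement with probability proportional to
exp(sum_j beta_j z_j) over min-max scaled covariates — the same
exponential-of-linear-predictor family the model fits, which is what makes
coefficient-sign recovery a well-posed test.  The synthetic habitat-sample
table (a synthetic stand-in for the real drop-camera table, which the
package does not ship) reproduces the compositional closure of substrate
percent covers: mud, the ubiquitous dominant class, is the noisy complement
of the six minority substrate covers, and is therefore the unique stepwise
VIF offender, mirroring the real screen's outcome.

What passing tests on these data do *not* show about real data: the
generators produce stationary isotropic fields with uniform margins, no
observation error, no spatial bias in survey effort, no animal clustering
beyond habitat response, and a species drawn from the model's own family.
Real performance (absolute AUC, contribution rankings) will differ; the
tests validate the machinery and its statistical calibration, not field
predictive skill.

## Problem sizes used in the test suite

The suite exercises the pipeline at desk scale, as the package's own
choice of test conditions: landscapes of 40x40 to 60x60 cells, 200-500
presences, 1000-cell background samples, 100 null iterations, and 100
replicate pipelines for the power and type-I checks (500 and 200 presences
respectively, both on 60x60 grids with three covariates).  The defaults
users see (10,000 background points, 1000 null iterations, 120 permutation
iterations, 50 hinge knots) match the motivating analysis.

## Known limitations

* The ESRI ASCII grid is the only raster format; values round-trip at full
  float precision but files are verbose.
* Kriging provides no variance maps, anisotropy, or co-kriging; variogram
  fitting is WLS with random restarts, not REML.
* Feature classes are limited to linear/quadratic/hinge (the candidate set
  of the motivating analysis); product, threshold, and categorical features
  are out of scope, as are sample-bias grids and extrapolation (MESS) maps.
* AICc for presence-background models uses the landscape-normalized
  likelihood convention; its absolute values are not comparable across
  landscapes with different cell counts.
* The null test assumes the background sample represents available space;
  strongly biased survey effort would need a different null.
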