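# Methods

## The roughness model

An endplate outline is modelled as an ellipse plus surface irregularity. The
DS score of a contour `{x_i}` against an ellipse `E(xc, yc, a, b, phi)` is
the mean nearest-point Euclidean distance to the boundary of `E`. DS is
invariant to rigid motion of the contour and scales linearly with the
coordinates, so it carries the contour's units (mm after scaling); DS = 0
exactly when every point lies on the fitted ellipse.

### Contour extraction

Segmentation uses Otsu's threshold with the explicit `I >= theta` foreground
convention: `theta` is the integer in 1..255 maximizing between-class
variance of the 256-bin histogram, the smallest maximizer on ties. External
boundaries of 8-connected foreground components are traced with
Moore-neighbour tracing (Jacob's stopping criterion) through pixel centers,
yielding full chains without polygonal simplification; hole boundaries are
suppressed. The largest contour by shoelace polygon area is retained (ties
resolved to the first in raster-scan order, with a warning).

The straight posterior cut line left by endplate isolation shares one image
row. Its removal finds the modal integer-rounded y-coordinate `y*` and drops
every point with `|y - y*| <= tau` (default `tau` = 2 px). Modal ties are
broken toward the candidate with more points inside the `±tau` band, then
toward smaller y — the baseline is the densest flat run. Scaling multiplies
by `ref_len_mm / ref_len_px`, flips y to mathematical orientation and
re-centers on the centroid; the fixed convention is what makes the
rotation/translation invariance tests meaningful.

### Penalized ellipse fit

The fit minimizes a stacked residual with `scipy.optimize.least_squares`
(trust-region-reflective, bounded), starting from a PCA initialization:
center at the centroid, semi-axes `sqrt(2 * lambda_j)` of the (biased)
covariance eigenvalues — exact for a uniformly-parameter-sampled ellipse,
where `Var(a cos t) = a^2/2` — and rotation from the leading eigenvector.
Semi-axes are optimized as logarithms, keeping them positive without
constraints; the result is canonicalized to `a >= b`, `phi in [0, pi)`.

Residual components:

* **Algebraic**: `((dx cos phi + dy sin phi)/a)^2 + ((-dx sin phi + dy cos
  phi)/b)^2 - 1` per point. Zero on the boundary, -1 at the center.
* **Tangential** (open contours, weight `w_tan` = 0.1): the sine of the
  angle between each end segment and the ellipse tangent at the nearest
  boundary point. Anchors the two free ends of an arc.
* **Curvature** (open contours, weight `w_curv` = 0.1): relative difference
  between the discrete Menger curvature at the endpoints and midpoint and
  the ellipse's analytic curvature at the nearest boundary points.
* **Eccentricity hinge** (weight `w_ecc` = 10): `max(0, |log(b/a)| -
  r_max)` with `r_max = log 3` by default — endplates are only mildly
  eccentric, and the hinge keeps open arcs from collapsing onto degenerate
  elongated solutions. All weights and `r_max` are `FitConfig` fields.

Two numerical choices matter in practice. First, closure detection: a
contour is treated as closed when the first-last gap is below both 3x the
median point spacing and 5% of the bounding-box diagonal. Spacing alone is
unreliable — on densely sampled noisy outlines the spacing is
noise-dominated — and endpoint penalties applied to a spuriously "open"
loop can dominate the objective. Closed contours receive only the
eccentricity hinge (their endpoints are an artifact of the starting index).
Second, the end-direction and curvature stencils span about 2% of the chain
(`max(1, n // 50)` points) rather than immediate neighbours, so a single
noisy pixel cannot dominate a penalty term.

Convergence: `ftol = xtol = 1e-10`, iteration cap 200 (as a function-
evaluation budget); the `converged` flag reports the optimizer's own
termination status honestly. Bounds: center inside the bounding box dilated
by one diameter, log-axes bracketed by the spread of centroid distances,
rotation free then canonicalized.

### Nearest-point distances

Point-to-ellipse distance works in the ellipse frame by symmetry (first
quadrant). For interior/exterior points off the axes it solves the
stationarity condition `F(t) = (a y0/(t + a^2))^2 + (b y1/(t + b^2))^2 - 1
= 0` — monotone decreasing on `(-b^2 + b y1, inf)` — with safeguarded
Brent root-finding (`xtol` = 1e-10, bracket expanded geometrically). Points
on the axes and the center use the closed-form branches, including the
major-axis case where the nearest point leaves the axis. Circles reduce to
radial geometry. The solver agrees with a 10^6-sample parametric
brute-force scan to better than 1e-8 on random instances (tested at 1e-6).

## Synthetic data

### Phantom outlines

`PhantomSpec` samples `center + R(phi) ((a + delta) cos t, (b + delta) sin
t)` at equally spaced parameter angles, with `delta` the sum of zero-mean
Gaussian radial noise and raised-cosine bumps/pits (`amp * cos^2(pi d / w)`
inside an angular window `w`, emulating marginal osteophytes or erosions).
Radial perturbation approximates the orthogonal deviation the DS measures;
for a circle it is exact, and the calibration identity `E[DS] ->
sigma * sqrt(2/pi)` (mean of |N(0, sigma)|) holds within 10% at 2000
points for moderate eccentricity. `include_baseline` appends a straight
chord at the outline's minimum y — the flat cut line the modal-y filter
must remove. Rasterization joins consecutive points with Bresenham lines
into an 8-bit image (background 0, strokes 255) and records the true
mm-per-pixel factor for round-trip tests.

What the phantoms do **not** emulate: partial-volume gray levels, cortical
thickness, interior texture, or anisotropic CT point spread. A traced
boundary of a rendered 1-px stroke also differs from the generating points
(both stroke sides contribute), so raster round-trip DS values sit above
the point-wise noise average; calibration tests therefore fit the generated
points directly, while pipeline tests assert structural properties
(baseline removal, determinism, survival fractions).

### Cohorts

`CohortSimSpec` draws ages uniform on 21–94 y and per-vertebra DS values
`intercept + slope * age + N(0, sd)`, floored at 1e-6 mm (roughness is
strictly positive). Default trends are calibrated per sex and vertebra to
the observed cohort: each vertebra's mean DS level and its age correlation
are matched exactly, with the cranio-caudal gradient (near-zero cervical
trends, strongest lumbar trends) preserved. Because a Gaussian linear model
at the observed — right-skewed, outlier-inflated — SDs would truncate
15–40% of draws at zero and bias any linear recovery, the slope and
residual SD are jointly rescaled per vertebra (their ratio, hence the
correlation, is invariant) by the largest factor that keeps the trend at
least 3.3 residual SDs above zero across the age range. Simulated marginal
SDs are consequently smaller than observed ones; passing recovery tests
demonstrate estimator correctness under the generator's Gaussian linear
conditions, not robustness to the skewness and outliers of real DS
distributions.

## Statistics layer

* Descriptives per sex with `mean ± t_{0.975, n-1} * SD / sqrt(n)` CIs.
* Sex comparisons default to Mann–Whitney U (DS is right-skewed; medians
  sit well below means): exact null distribution when both groups have
  n < 20 without ties, tie-corrected normal approximation otherwise;
  Welch's t available by configuration.
* Age correlations default to Spearman (mid-ranked ties), Pearson optional.
* The ANCOVA screen regresses age on sex, the 19 metrics and all
  first-order sex-by-metric interactions, testing the 20 sex-related
  coefficients jointly by Wald F; a significant joint test motivates
  sex-stratified modelling. Singular designs fail loudly with the aliased
  columns named.
* MLR reports R², adjusted R², the SEE `sqrt(SSR / (n - k - 1))` with
  k = 19, the overall F-test, VIF/tolerance from auxiliary regressions and
  condition indices of the intercept-included, unit-column-length-scaled
  design (the SPSS convention). Outlier screening (±3 within-sex SD) flags
  by default and removes only on request.
* LASSO uses the `1/(2n)`-scaled least-squares objective with the penalty
  chosen from a 50-point log grid on [1e-3, 10] by cross-validated MAE;
  standardization lives inside the pipeline so fold test data never leaks
  into scaler estimates. Reported coefficients are mapped back to the
  original DS scale; the test-split SEE uses k = number of nonzero
  coefficients.

## Machine-learning layer

One shuffled 80/20 hold-out split per sex (`|test| = round(0.2 n)`; sex
stratification is implicit in fitting sexes separately), then 10-fold
shuffled CV grid search inside the training portion. Grids: SVR C in
{1, 10, 100}, gamma in {scale, 0.01, 0.1}, epsilon in {0.1, 1}; forest of
100–250 trees with depth in {3, 5, 10, none}, bootstrap and OOB scoring on;
k-NN with k in 3..7; GNB pseudo-regressor with 5 equal-frequency age bins
by default (bin edges at empirical quantiles, Gaussian NB on bin labels,
prediction = posterior-weighted bin midpoints, so predictions are bounded
by the extreme midpoints). Hold-out metrics: MAE, RMSE, R², and the Eq.-8
style SEE with k = number of input features (19) for the non-sparse
learners; when `n_test <= k + 1` the divisor is guarded at 1 with a
warning — at the study's test sizes that SEE degenerates to
`RMSE * sqrt(n)`, so RMSE is the more interpretable hold-out error there.
Percentile-bootstrap CIs use 1000 resamples of the test set; degenerate
resamples (zero age variance) are skipped. Diagnostics: permutation
importance (mean drop in hold-out R² per shuffled feature), Bland–Altman
bias and `bias ± 1.96 SD` limits of agreement, and learning curves that
re-tune on seeded subsamples.

All randomness flows from explicit seeds; batch runs record a configuration
hash in every manifest, and identical configurations produce byte-identical
outputs.

## Power analysis

`f2 = R2 / (1 - R2)`; `lambda = f2 * df2` with `df2 = n - k - 1`; achieved
power is `P(F' > F_crit)` for non-central `F'(df1, df2, lambda)` with
`F_crit` the central upper-alpha quantile (scipy's `ncf`/`f`). The
implementation is cross-checked in tests against direct Monte-Carlo
simulation of the noncentral-chi-square ratio at 10^6 draws. Power equals
alpha exactly at `lambda = 0` and is strictly increasing in `lambda`.
Critical values are reported per sex (they differ with `df2`).

## Problem sizes

The test suite and the acceptance script size their simulations to run on a
single CPU in minutes: 100–1000 distance-solver instances against 10^6-
sample brute force, 100 random images for the Otsu oracle, 20 seeds x 3
noise levels x 2000-point phantoms for DS calibration, 500–1000 null
replicates for F-test calibration, and 50–100 replicates of 500-per-sex
cohorts for slope recovery.

## Known limitations

* The tangency/curvature penalty forms are this package's own smooth,
  zero-at-truth constructions; alternative anchorings of open arcs exist.
* DS is computed on the baseline-filtered point set only; endpoints are
  never re-included and closure is never forced.
* The cohort generator is linear-Gaussian by design; it does not reproduce
  the skewness, outliers, or inter-vertebra correlation of real DS panels.
* No DICOM/CT handling: the pipeline starts from an isolated 8-bit
  endplate image or a contour CSV, and no 3-D surface machinery is
  included.
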