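# vertds

Vertebral endplate surface-roughness scoring and adult age estimation.

## The problem

Adult skeletal age estimation leans on degenerative "wear-and-tear" changes,
most of which are still scored subjectively. `vertds` implements an objective
alternative: the **distance-to-fitted-ellipse roughness score (DS)**. The
antero-superior rim of a vertebral endplate is close to elliptical in young
adults; cumulative cortical remodeling — scalloping, porosity, marginal
osteophytes — makes the outline increasingly irregular with age. Fitting an
ideal ellipse to the extracted endplate boundary and averaging each boundary
point's nearest-point Euclidean distance to it collapses that irregularity
into a single millimetre-scale number per vertebra:

```
DS = (1/n) * sum_i  min_{p in ellipse} || x_i - p ||
```

Scored for all 19 vertebrae C7–S1 and regressed on chronological age
(separately per sex), DS supports both a classical multiple-linear-regression
benchmark and non-parametric learners (random forest, k-NN, SVR, and a
discretized Gaussian naive-Bayes pseudo-regressor).

The package covers the full chain, testable end to end on synthetic phantoms:

* **`vertds.phantoms`** — synthetic endplate outlines with controlled radial
  noise/bumps and synthetic cohorts with known sex-specific age–DS trends;
* **`vertds.contour`** — Otsu thresholding, external boundary tracing
  (pixel-center chains, 8-connectivity), modal-y baseline removal (the
  straight posterior cut line), mm scaling;
* **`vertds.ellipse`** — penalized least-squares ellipse fit (PCA
  initialization, log-axis parameterization, trust-region-reflective solver,
  tangency/curvature/eccentricity penalties for open arcs) and the DS score;
* **`vertds.cohort`** — descriptives, Mann–Whitney sex comparisons, Spearman
  age correlations, ANCOVA sex-interaction screen, MLR with SEE
  (`sqrt(SSR/(n-k-1))`) and collinearity diagnostics, cross-validated LASSO;
* **`vertds.ml`** — 80/20 hold-out protocol with 10-fold in-training tuning,
  fold-wise standardization, bootstrap CIs, permutation importance,
  Bland–Altman limits, learning curves;
* **`vertds.power`** — post hoc power of the overall regression F-test via
  Cohen's `f2 = R2/(1-R2)`, non-centrality `lambda = f2 * df2` and the
  non-central F distribution;
* **`vertds.workflow` / `vertds` CLI** — batch orchestration with manifests
  and config hashes.

## Worked example

Fit an ellipse to a noisy synthetic endplate outline (semi-axes 15 x 10 mm,
zero-mean radial Gaussian noise of SD 0.3 mm):

```python
import vertds as v

spec = v.PhantomSpec(a_mm=15, b_mm=10, sigma_radial_mm=0.3, n_points=2000, seed=7)
result = v.fit_ellipse(v.make_phantom_contour(spec).points)
print(result.summary())
```

```
Penalized ellipse fit
============================================
points            2000
center            (-0.0132, -0.0164)
semi-axes (a, b)  (15.0036, 10.0082)
rotation phi      3.1411 rad
DS (mean dist)    0.232873
residual norm     2.502e+00
converged         True
```

The fit recovers the generating geometry (15.00 x 10.01 mm; phi = 3.1411 is
0 mod pi), and the DS of 0.233 mm sits where theory puts it: the mean
absolute value of N(0, 0.3) noise is `0.3 * sqrt(2/pi) = 0.239` mm.

The power side is equally direct. For a male regression benchmark explaining
R² = 0.399 of age variance with 19 predictors in 94 subjects:

```bash
vertds power --r2 0.399 --n 94 --k 19
```

```
R2 = 0.399  ->  Cohen's f2 = 0.664
df = (19, 74), alpha = 0.05
non-centrality lambda = 49.1
critical F = 1.73
achieved power = 0.992
```

i.e. a >99% probability of detecting an age effect of that size with the
overall F-test.

Other entry points: `vertds simulate` (phantom images / cohort CSVs),
`vertds extract` (image to contour CSV), `vertds fit` (contour to DS
record), `vertds stats`, `vertds ml`, and `vertds report` for the full
bundle.

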