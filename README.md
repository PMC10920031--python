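# ottersdm

Presence-background species distribution modeling for benthic habitat
association studies, built around the analysis design used for northern sea
otters (*Enhydra lutris kenyoni*) in Kachemak Bay, Alaska: point drop-camera
habitat surveys interpolated to raster covariates, presence-only aerial
survey locations, a lasso-regularized maximum-entropy model, cross-validated
model tuning, and randomized-presence null-model significance testing.

The package is aimed at ecologists working in data-limited systems: one
season of presence locations, a handful of interpolated habitat surfaces,
and no absence data.

## The model

Given presence cells $x_1,\dots,x_m$ and background (available) cells
$b_1,\dots,b_N$ sampled from the surveyed area, the model estimates a Gibbs
density over cells,

$$P_\lambda(x) = \frac{e^{\lambda \cdot f(x)}}{N\,Z(\lambda)}, \qquad
  Z(\lambda) = \frac{1}{N}\sum_{i=1}^{N} e^{\lambda \cdot f(b_i)},$$

where $f(x)$ are features derived from the habitat covariates — linear (L),
quadratic (Q), and hinge (H) transforms of the min-max scaled values — by
minimizing the lasso-penalized negative log-likelihood

$$J(\lambda) = -\frac{1}{m}\sum_{i=1}^m \lambda \cdot f(x_i)
  + \log Z(\lambda) + \sum_j r\,\beta_j\,|\lambda_j|,$$

with per-feature penalties $\beta_j$ from the standard sample-size schedule
and a global regularization multiplier $r$.  This is the maximum-entropy
("MaxEnt") formulation of presence-background modeling; predictions are
reported either as the raw density or through the complementary log-log
transform $1 - \exp(-e^{H}\,P_\lambda(x))$ (with $H$ the entropy of the
fitted background distribution), read as a probability of occurrence.

Around the core model the package provides:

* **`ottersdm.grids`** — planar raster grids (ESRI ASCII text format),
  point CSVs, WKT survey polygons, presence rasterization (one observation
  per 131 m grid cell).
* **`ottersdm.kriging`** — empirical variograms, weighted least-squares
  variogram fits, local ordinary kriging of point percent covers, and
  rugosity (surface-area ratio) from bathymetry.
* **`ottersdm.vif`** — stepwise variance-inflation-factor screening of the
  covariate table.
* **`ottersdm.maxent`** — the `MaxEnt` model class; `fit()` returns a
  `MaxEntResults` with coefficients, `summary()`, prediction grids, percent
  contribution, permutation importance (120 iterations), and response-curve
  directions.
* **`ottersdm.evaluate`** — k-fold cross-validated AUC/omission metrics,
  AICc, the 20-model tuning grid (feature sets L/LQ/H/LQH x multipliers
  1-5), and sequential vs AICc model selection.
* **`ottersdm.nullmodel`** — null distributions from randomly placed
  occurrences run through the identical cross-validation, with standardized
  effect sizes (z), one-sided p-values, and quantile bands.
* **`ottersdm.synth`** — synthetic landscapes, strip-transect survey
  designs, and virtual species with known truth, so the full pipeline runs
  and is validated without any external data.

## Worked example

Simulate a bay-like landscape, a virtual species that prefers shallow water
and filamentous algae and avoids shell litter, fit the selected model
specification, and test it against the null distribution:

```python
import numpy as np
from ottersdm import (MaxEnt, FoldPartition, compare, cross_validate,
                      run_nulls, synth)

stack = synth.gen_default_stack(seed=1, n_rows=60, n_cols=60)     # 13 covariates
domain = synth.gen_survey_design(stack, transect_spacing_cells=8,
                                 transect_width_cells=3)
presences, truth = synth.gen_species(
    stack, domain,
    {"bathymetry": 3.0, "shell_litter": -3.0, "filamentous_algae": 2.0},
    n_presences=400, seed=2)
background = synth.sample_background(domain, stack, n=1000, seed=3)

res = MaxEnt.from_cells(stack, presences, background,
                        feature_set="L", rm=1.0).fit()
print(res.summary())
```

```
Maximum-entropy presence-background model
=========================================================
Feature set:            L   (rm = 1)
Presences / background: 400 / 1000
Features (nonzero):     13 (10)
Converged:              True in 19 sweeps
...
shell_litter              1.2872         1       56.00
...
bathymetry                1.7122         1       21.75
...
```

The three covariates the species was built from dominate the contribution
table, with the correct signs in `res.relationship_directions()`.  The
cross-validated metrics and the null-model comparison:

```python
P = stack.values_at_cells(presences.rows, presences.cols)
B = stack.values_at_cells(background.rows, background.cols)
rows, cols = domain.cells(stack.grid, valid_mask=~stack.nodata_mask)
D = stack.values_at_cells(rows, cols)

part = FoldPartition.make(len(presences), k=5, seed=4)
metrics = cross_validate(P, B, part, covariates=stack.names)
null = run_nulls(D, B, P, part, n_iter=100, seed=5, covariates=stack.names)
print(compare(metrics.means, null).table[
    ["empirical", "null_mean", "null_sd", "z", "p"]].round(4))
```

```
           empirical  null_mean  null_sd        z       p
metric
auc_train     0.7758     0.5504   0.0080  28.0657  0.0000
auc_val       0.7698     0.4891   0.0202  13.9097  0.0000
auc_diff      0.0060     0.0614   0.0150  -3.6889  0.0001
or10          0.1050     0.1479   0.0203  -2.1158  0.0172
```

Read the table as: the empirical model discriminates presences from
available habitat far better than models built from randomly placed
occurrences (AUC z-scores of 28 and 14, one-sided p ~ 0), and it is *less*
overfit than the nulls (negative z for AUC_diff and the 10%-omission rate).
`res.predict_grid(stack)` then maps the probability of occurrence over the
full raster extent.

## Command line

The same stages are exposed as a `sdm` console tool:

```bash
sdm simulate --config sdm.cfg --out demo/
sdm screen   --stack demo/stack --domain demo/domain.wkt --out vif.json
sdm tune     --stack demo/stack --presences demo/presences.csv \
             --domain demo/domain.wkt --config sdm.cfg --out tuning.csv
sdm fit      --stack demo/stack --presences demo/presences.csv \
             --features L --rm 1 --out model.json
sdm nulls    --stack demo/stack --presences demo/presences.csv \
             --domain demo/domain.wkt --out nulls.csv
sdm predict  --stack demo/stack --model model.json --out pred.asc
sdm report   --stack demo/stack --presences demo/presences.csv --out report.csv
```

The config file holds `key = value` lines (`seed`, `k_folds`, `rm_list`,
`feature_sets`, `n_background`, `n_null`, `vif_threshold`,
`output_transform`, `hinge_knots`).

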