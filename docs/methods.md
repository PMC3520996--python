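# Methods

This note documents the models, the synthetic study system, the
numerical choices, and the limitations of `abaclim`. Empirical claims
here are limited to what the test suite and `scripts/acceptance.py`
themselves compute.

## Raster model

All spatial data are regular geographic (lat/lon, decimal degree)
grids with cell-center registration; latitude increases northward in
memory regardless of on-disk row order. Masked (land/invalid) cells
carry NaN in memory — chosen because NaN propagates loudly — and the
format-native nodata on disk. Supported formats are NetCDF (xarray,
scipy backend) and ESRI ASCII grid; every statistic in the package is
computed over valid cells only and is therefore independent of any
on-disk sentinel value. Map projections other than geographic lat/lon
and vector coastlines are out of scope.

## The synthetic study system

The generators are pure functions of their parameters and a seed, and
their defaults define the study conditions used throughout the tests
and the acceptance script.

**Domain.** A 120 × 60 cell, 0.01° grid (≈1 km cells) with a
procedural coastline: sea is the southern band below a smoothly
wiggling coastline at ~70 % of the domain height (~76 % sea). This
stands in for a coastal shelf without a shapefile dependency.

**Climatologies.** August (winter) SST is a smooth closed-form surface
— warmest offshore, coldest along the coast, with low-order harmonics
— spanning ≈12.5–18 °C, plus iid Gaussian observation noise of
0.3 °C (a realistic residual for a multi-year satellite monthly
climatology). March (late-summer) SST is August plus a smooth positive
offset that grows strongly toward the coast, emulating the large
seasonal amplitude of shallow gulf water; it spans ≈15–22 °C, with
roughly an eighth of the sea at or below 17 °C and a fifth at or above
20 °C. This anti-correlation of winter and summer suitability is the
load-bearing feature: winter warming expands habitat into exactly the
coastal band where March temperatures approach the 20 °C tolerance
category.

**Scenarios.** Anomalies are linear in decade by default:
0.11 °C/decade for the Reference scenario (≈1.1 °C by 2100) and
0.05 °C/decade for Policy (≈0.5 °C by 2100); an optional
"peak-and-decline" Policy shape peaks around 2080 and eases ~5 % by
2100. Per-model structure adds an iid Gaussian offset (spread 0.15 °C)
and a smooth spatial perturbation; one model can be planted as an
outlier with a configurable bias (default +3 °C) for testing the
screening machinery. Climate-sensitivity standardisation across models
is treated as already done upstream; the generator emits standardised
anomalies. For skill ranking, per-model *historical* fields are
generated as observed + bias + noise with per-model error scales, so
the true skill ordering is known.

**Surveys.** Sites are drawn without replacement from sea cells;
covariates are depth ~ U(5, 30) m (the survey depth band), harvest
intensity ~ U(0, 1) (dimensionless index) and distance-to-launch
~ U(0, 50) km — the latter two ranges are artifacts of the emulation,
documented constants, since no empirical ranges exist for them. The
log mean count is

    species A (blacklip):  η = −3.5 + 0.45·SST + covariate terms
    species B (greenlip):  η = −39.5 + 5.1·SST − 0.15·SST² + covariates
                               (thermal optimum −b₁/2b₂ = 17 °C)

with covariate effects (−0.03/m depth, −0.4 harvest, +0.015/km
distance) and negative-binomial counts (size k = 2, var = μ + μ²/k;
Poisson available by configuration). These defaults give realistic
densities of a few to ~100 individuals per 100 m², with the 20/100 m²
fishing-ground threshold crossed inside the domain.

**Mortality.** Tank-level percentages are Gaussian around the group
means, truncated to [0, 100]; default conditions are the two-group,
four-tank design with means 3.1 % and 58.12 % and SDs 6.2 % and 17.2 %
(SE·√n of the reported summaries).

What the generator does *not* emulate: satellite cloud gaps and
orbital artifacts, spatially correlated survey noise, preferential
survey placement, harvest dynamics, larval dispersal. Passing tests
therefore demonstrate correctness of the *procedure* under known
ground truth, not predictive skill on real monitoring data.

## Climate-model ensemble

Bias is the difference of spatial means over shared valid cells;
centred RMSE and pattern correlation are computed after removing each
field's spatial mean, so RMSE² = bias² + centred-RMSE² holds as an
algebraic identity (asserted to 1e-9). Ranking uses |bias| — a cold
bias is as bad as a warm one — with average ranks for ties (the
standard rank-statistics convention, keeping cumulative ranks
comparable), and the four statistics equally weighted. The outlier
score is the spatial-mean absolute departure of a model from the mean
of all others, averaged over decadal slices; models above 3× the
median score are flagged, which cleanly separates a +3 °C outlier
(score 3.0 vs 0.6 for the others in a six-model set). The ensemble
anomaly is the unweighted cell-wise mean of the top-five models after
outlier removal; five members because fewer makes the average
sensitive to model choice and more adds little.

## Downscaling

The thin-plate spline uses the classical r² log r kernel with an
affine polynomial part, solved as a bordered penalized system in
coordinates rescaled to the unit box for conditioning. For each
candidate λ (default 25 values log-spaced over eight decades,
1e−6–1e2) the influence matrix trace is computed exactly below 2000
knots (hat-matrix columns from identity right-hand sides) and by a
32-probe Hutchinson estimator above; candidates with n − tr H ≤ 0 are
rejected. Affine data are reproduced exactly for any λ (null space of
the penalty) and λ → 0 recovers interpolation; both are tested, the
latter against scipy's independent thin-plate interpolator.

The change-factor chain bilinearly refines the 2.5° anomaly to 0.5°
(to soften grid-box discontinuities; fine values are bounded by the
surrounding coarse values, and coarse cell centers are preserved
exactly at odd refinement ratios) and then assigns each 0.01° cell the
anomaly of its *nearest* 0.5° parent. Nearest-parent transfer is the
default because the method adds the mid-resolution change directly;
projected − baseline is then piecewise constant on 0.5° blocks and all
within-block baseline detail survives exactly. A second bilinear
interpolation is available by configuration. Coastal cells whose
parent is invalid or just outside the anomaly's coverage borrow the
nearest valid parent within one cell; larger gaps are an error listing
the uncovered cells. The change factor perturbs means only — no
variance correction, no dynamical downscaling.

## Abundance ensemble

The GLM is a negative-binomial (NB2, dispersion estimated by maximum
likelihood) count model with log link; Poisson is available by
configuration. SST is centered at its training mean in both response
shapes; the quadratic shape adds the centered square, and the fitted
thermal optimum is center − b₁/(2b₂). The BRT is gradient boosting on
log1p counts (depth 3, learning rate 0.01, bag fraction 0.5, up to
2000 trees with early stopping on a 20 % internal holdout, fixed
seed); predictions are back-transformed and clipped at zero. Model
comparison and ensemble weighting use total Poisson deviance on
held-out data as a family-agnostic currency; weights are
w_i ∝ exp(−Δ_i/2) of the excess validation deviance — a deviance
analogue of information-criterion weights that reduces to (0.5, 0.5)
for equally skilled components and to ~1 for a component better by
Δ > 20. Equal weights are available by configuration. At projection
time every non-SST covariate (including an optional SST-variability
column, if supplied) is held at its training mean; harvest intensity
is treated as exogenous and constant across decades. Only GLM and BRT
are implemented as ensemble members.

## Range products and overlay

Fishing grounds are cells with abundance ≥ 20 individuals/100 m²
(inclusive); the four change classes partition the sea mask exactly.
Percent change in harvestable abundance compares the summed abundance
over threshold cells, each epoch using its own cells. March categories
are <17, [17, 20), ≥20 °C — 17 °C is placed in the middle bin, fixing
a convention where prose could be read either way; the edges are
configurable. The "current distribution" region is cells with
present-day predicted abundance above 0.5/100 m² (configurable
occupancy cut-off); "expansion" cells are the gained class at the
overlay's decade and scenario. Overlay fractions are cell fractions by
default, with cosine-latitude area weighting available since cells on
a lat/lon grid differ slightly in area. Box-plot summaries use type-7
(linear-interpolation) quantiles.

## Mortality statistics

The tank is the unit of replication: four tanks per temperature give
F's (1, 6) degrees of freedom, and individuals within tanks are
pseudo-replicates that never enter the test. The
reconstruction-from-summaries path recovers SD = SE·√n, pools
within-group variance and rebuilds the between-group sum of squares —
algebraically identical to the raw-data decomposition (tested to
1e-10), so any discrepancy against a reported F is bounded by the
rounding of the printed summaries. Percentages are analysed untransformed
(an arcsine/logit transform is a configuration option, not the default).
Zero within-group variance with distinct means is reported as an
infinite-F flag rather than an exception. p-values are reported at full
precision. A binomial GLMM on individual outcomes would be the modern
alternative and is out of scope.

## Pipeline and reproducibility

Stages communicate through files in the output directory and a
cumulative manifest (content hashes, per-stage seeds, wall time).
Per-stage seeds are derived deterministically from one base seed; the
whole pipeline is bit-reproducible under a fixed configuration. The
default configuration (120 × 60 domain, 6 models, 3 decades, 800
surveys per species, 300 spline knots) runs the full chain in a few
seconds on one CPU; problem sizes in the acceptance script (2000
records × 20–50 fits, 10,000 ANOVA null simulations, 400-knot spline
with 500 holdout points) were chosen as the smallest sizes at which
the sampling error of each check is comfortably below its tolerance.

## Known limitations

- The 0.01° grid and "1 km" cells are treated as synonymous.
- Cumulative rank uses exactly the four listed statistics with equal
  weight; upstream tooling may weight variants differently.
- The assignment of 0.5° anomalies to 0.01° cells (nearest parent vs a
  second interpolation) is genuinely underdetermined; nearest is the
  default and both are implemented.
- Ensemble SST anomalies perturb the baseline mean only; variance and
  extremes are unchanged.
- No demographic, dispersal or occupancy coupling: projections are
  correlative abundance surfaces, and the March overlay is a
  qualitative screen, not a mortality model.
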