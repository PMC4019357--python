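# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Allometric estimation

Three families are implemented behind one registry interface
(`EquationRegistry`, loaded from YAML):

* **ln–ln by species group** — `m_kg = exp(β₀ + β₁ ln D_cm)`. The packaged
  coefficients for the 10 national species groups are transcribed from the
  published generalized compilation; their `r_squared`/`n_obs` metadata are
  nominal values of the right order, used only by the error-simulation
  engine (which calibrates to whatever R² the registry carries).
* **volume-based (component-ratio) chain** — combined-variable bole volume
  `v_m3 = a + b·D²·h`, bole biomass `v·ρ`, whole tree `bole / r`. The
  packaged volume/density/ratio coefficients are *generic demonstrative
  defaults* (so the chain is exercisable and unit-correct), not a regional
  coefficient set; they are flagged as such in `data/equations.yaml` and
  should be replaced for real analyses. A missing bole height is an error,
  never imputed.
* **species-specific** — local ln–ln equations per species, with the
  general group equation substituted on a miss (the lookup reports which
  path was taken). The packaged species entries are likewise generic
  defaults.

Units are fixed: DBH cm, heights m, tree biomass kg, plot density Mg/ha
(`Σkg / 1000 / (A_m²/10⁴)`). DBH outside an equation's fitted range raises
an `OutOfRangeWarning` but still returns a value, since field data always
contain trees beyond the source regressions' support.

## Allometric-error engine

`simulate_population` draws ln D uniformly over the equation's validity
range (uniform-in-log keeps leverage balanced for the ln–ln refit) and adds
log-scale Gaussian noise; the noise SD is found by bisection until the
refitted R² matches the registry R² within 0.005 (log-scale noise keeps
simulated biomass positive and produces the increasing-SE-with-size
pattern expected of multiplicative allometric error). `derive_mean_se_function`
draws ≥100 subsets of `n_obs` diameters from a Weibull (default shape 2,
scale set so the mean sits mid-range), matches each draw to the nearest
population point, and fits `SE(D) = a·Dᵇ` by least squares on the log of
binned absolute residuals (20 equal-count bins, half-normal correction
√(π/2)·mean|r| per bin); the parameter-wise mean over subsets is returned.
"Standard error" here means the residual SD of a single tree's prediction —
that is what per-tree perturbation requires.

`propagate_plot_ci` perturbs each tree independently by
N(prediction, SE(D)), truncates at zero, sums to Mg/ha, and takes 2.5/97.5
percentiles over ≥1,000 (default 10,000) reps. The reported `mean` is the
deterministic allometric density; the Monte-Carlo mean (`mc_mean`) equals
it up to truncation bias. A `shared_plot_error` flag replaces the
independent draws with one common multiplier per rep for sensitivity runs;
default is independence, since between-tree error correlation is unknown.

## Spatial model

`fit_spatial_regression` implements `y = Xβ + w + ε`, `w ~ GP(0, σ²R)`
with exponential correlation `R_ij = exp(−φ d_ij)` and nugget
`ε ~ N(0, τ²I)`. Sampling: conjugate Gibbs updates for `w` (Gaussian, via
Cholesky of the conditional precision), `β` (flat prior), `σ²`, `τ²`
(inverse-gamma(2, v̂/2) priors, with v̂ the OLS residual variance — half the
data variance to each component a priori); log-scale random-walk Metropolis
for `φ` with a uniform prior whose support sets the effective range `3/φ`
between the smallest plot separation and the domain diagonal. The proposal
SD adapts during burn-in to a 25–45% acceptance rate. Defaults: 5,000
iterations, half burn-in, thin 5 (the orchestrated pipeline uses 4,000 at
its desk-scale sizes; the replicate-fit simulations use 2,500). Duplicate
coordinates are rejected (singular correlation matrix); chains report the
acceptance rate and a convergence flag rather than failing silently.

`predict_posterior` uses composition sampling: per retained posterior draw,
each new location's spatial effect is drawn from its exact univariate
Gaussian conditional given the training effects (`r'R⁻¹w`,
`σ²(1 − r'R⁻¹r)`), plus `N(0, τ²)` measurement noise; pixels are processed
in blocks conditioned only on training locations, which bounds memory and
matches prediction at unobserved sites. Conditioning is exact at a training
coordinate, so no singularity arises there. Predicted biomass is *not*
clipped at zero — the bands remain internally consistent summaries of the
Gaussian model; pixel-level negative means only occur where the design
pushes predictions below zero and are visible rather than hidden.

The random-forest baseline delegates to scikit-learn
(`RandomForestRegressor`, 500 trees default, out-of-bag R²/RMSE). The
empirical semivariogram utility reports empty lag bins as missing, never
as zero.

## Synthetic landscape generator

The generator produces data with exactly the structure the analysis
assumes — which is its purpose and its limit:

* **Biomass surface** — Gaussian random field with covariance
  `sill·exp(−decay·d)` around a mean, clipped at zero; defaults
  sill 2,500 (Mg/ha)², decay 0.01 m⁻¹ (effective range 300 m), mean
  60 Mg/ha — a fragmented mid-Atlantic mosaic of open land and dense
  stands at 30-m resolution. Nonforest land is carved as random rectangles
  (plus retained "scattered trees" on those pixels — yards and
  rights-of-way); an optional target fixes the share of landscape biomass
  on nonforest pixels exactly (defaults: 30% of area, 25% of biomass,
  matching the mid-twenties shares seen in the region).
* **Plot network** — systematic lattice with a random start; clusters of
  four 168 m² subplots, satellites 7 m from the center at azimuths
  0°/120°/240°. The 7-m spacing follows the stated cluster geometry this
  package mirrors even though operational inventory spacing differs; it is
  configurable. Plot capacity is bounded by non-overlapping cluster
  footprints. The nonforest-inventory (NFI) design is a single 400 m²
  center plot; the "FIA-like" mode restricts placement to forest pixels.
* **Tree lists** — expected stems per subplot = local Mg/ha × area ÷ the
  mean single-tree biomass implied by the Weibull DBH distribution
  (shape 2, scale 22 cm) under a nominal ln–ln equation (closed form
  `E[D^β₁] = scale^β₁·Γ(1+β₁/shape)`), Poisson-distributed; this makes
  expected plot biomass proportional to the surface, so censoring-share
  recovery is unbiased. Species drawn from a fixed mid-Atlantic mix
  (red maple, white oak, yellow-poplar, sweetgum, loblolly pine); condition
  labels inherited from the subplot's pixel; bole height `1.3·D^0.72` with
  10% log-normal noise. The `stems_per_ha` field acts only as an optional
  density cap.
* **LIDAR metrics** — noisy monotone power links of biomass
  (`scale_k·B^0.7 + N(0, sd)`), mutually correlated through the shared
  signal; a bisection calibrator sets the noise SD so a linear metric→
  biomass fit attains a target R² (default 0.67, a realistic skill level
  for 30-m LIDAR biomass models in mixed forest).
* **Inventory censoring** — the protocol filter drops nonforest-condition
  trees in FIA mode, keeps the 400 m² center plot in NFI mode, keeps all
  in FIA-like mode.

What the generator does **not** emulate: real canopy-height-model errors,
geolocation error, temporal mismatch between LIDAR and field campaigns,
condition mapping within mixed plots, variable-radius training designs, or
non-Gaussian biomass distributions. Passing tests therefore demonstrate
the correctness of the estimators and the censoring/propagation mechanisms
under the assumed structure — not map accuracy on real landscapes.

## Comparison and county estimation

Pixel membership is half-open (`[x, x+s) × (y−s, y]`, north-up), so a
subplot on a boundary is assigned deterministically. The agreement
regression is fixed as mapped-on-field; RMSE uses raw pair differences
(map error directly) with a residual-RMSE variant available. No-data
pixels exclude the pair and are logged, never zero-filled. The KS statistic
is the plain two-sample sup-distance (no p-values). County design
estimates use a t-interval with n−1 degrees of freedom (bootstrap
percentile optional); pixel sums use the exact pixel-area factor
(0.09 ha at 30 m). Report display rounds percentages to integers and Tg to
2–3 decimals; internal values keep full precision.

## Orchestration and problem sizes

`run_pipeline` derives every stage's seed as
`sha256(master_seed:stage) mod 2³¹`, so stages are individually
reproducible and the whole run is bit-identical under a fixed master seed.
Default experiment sizes are desk-scale by design: a 40×40-pixel landscape
(129.6 ha), 60 plots, 10,000 CI reps, 4,000 MCMC iterations, 250
predictive draws; the packaged demo uses 30×30/40 plots. The
replicate-heavy simulations (plot-CI coverage: 500 plots × 10,000 reps;
spatial credible-interval coverage: 20 datasets at n = 200 with 2,500
iterations) use the sizes at which their Monte-Carlo error is small
relative to the quantities checked. The dense-Cholesky field simulator is
O(N³) in pixels and is intended for grids up to roughly 60×60.

## Known limitations

* The packaged volume-based and species-specific coefficient tables are
  placeholders for regional sets; only the ln–ln group table is a
  transcription of published values.
* The spatial model assumes isotropy and an exponential kernel; no Matérn
  or anisotropic options, and no model averaging over candidate metric
  sets — a single configured design matrix is used.
* Sapling-specific adjustments to the volume-based chain are not applied;
  all trees go through the same chain.
* The error engine treats DBH as measured without error and ignores
  covariance between allometric and sampling error.
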