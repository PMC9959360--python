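# Methods

`stuntmap` implements model-based geostatistics for mapping childhood
stunting prevalence from DHS-style cluster surveys: survey descriptives,
SPDE/Matérn spatial logistic regression fitted by MCMC, information-criterion
model comparison, gridded prediction with administrative aggregation, and
cluster hold-out validation. Because the microdata such analyses use are
restricted-access, the package carries a first-class synthetic survey
generator that reproduces the statistical structure of the design, and all
statistical guarantees are demonstrated against that generator's known truth.

## Outcome and descriptive statistics

A child is stunted when the height-for-age z-score (HAZ, WHO Child Growth
Standards) is strictly below −2.0. Scores with |HAZ| > 6 are treated as
biologically implausible and excluded (the WHO flagging convention; the
threshold is configurable). Descriptive prevalence tables are produced
crude (unweighted cross-tabulation) and design-based: the Horvitz–Thompson
ratio estimator p = Σwy/Σw per covariate category, with Taylor-linearized
standard errors under the stratified, with-replacement-PSU approximation
(the same estimator R's `survey::svydesign` defaults to). A stratum with a
single PSU contributes zero variance, with a warning. Report percentages are
rounded half-up to one decimal; computations carry full precision. Missing
covariate values are excluded per covariate, so each variable has its own
denominator.

## Spatial model

For child *i* in cluster *c(i)* at location *s*:

    y_i | p_i ~ Bernoulli(p_i),   logit(p_i) = x_i'β + S(s_c(i))

with dummy-coded categorical covariates (reference levels per the covariate
schema) and S a zero-mean stationary isotropic Matérn Gaussian field with
smoothness ν = 1. The field is represented by the SPDE approach: a linear
finite-element basis on a Delaunay triangulation turns S into a Gaussian
vector at the mesh vertices with sparse precision

    Q = τ²(κ⁴C + 2κ²G + G C⁻¹ G),

where C is the mass-lumped (diagonal) mass matrix and G the stiffness
matrix. Derived quantities: spatial range √8/κ (distance at which
correlation drops to ≈0.13) and marginal variance σ² = 1/(4πκ²τ²).
ν = 1 (α = 2) is fixed — the customary choice for 2-D prevalence mapping —
and is a documented constant, not a knob. Observation and prediction
locations enter through the projector matrix A of barycentric weights;
rows for locations outside the mesh are zero and flagged.

Mesh coordinates are raw lon/lat degrees, so κ is "per degree" and the
range is in degrees; `geoutils.degrees_to_km` converts at the domain's
mean latitude for reporting. Default mesh controls (cutoff 0.05°, max edge
0.5° interior with a coarse extension ring) give O(10³) vertices on a
country-scale domain. The extension ring absorbs the variance inflation the
Neumann boundary condition induces; it should be at least 1.5 correlation
ranges wide (the simulation mesh builder enforces this).

## Inference

Fitting is by exact MCMC rather than a Laplace-type approximation; the
inferential targets (posterior odds ratios with 95% credible intervals,
hyperparameter posteriors) are the same.

* **Pólya-Gamma augmentation.** Given ω_i ~ PG(1, η_i), the Bernoulli-logit
  likelihood is conditionally Gaussian in η, so (β, S) updates as one exact
  Gaussian block with precision blockdiag(B⁻¹, Q) + [X A]'Ω[X A]. The PG
  sampler is Devroye's exact alternating-series rejection method
  (numba-compiled; validated against closed-form moments and a quadrature
  oracle).
* **Hyperparameters.** (log κ, log τ) move by joint random-walk Metropolis,
  step size adapted during burn-in toward 20–40% acceptance. A one-off
  eigendecomposition of C^{-1/2}GC^{-1/2} makes each target evaluation
  (log-determinant and quadratic form of Q) O(n_vertices).
* **Priors.** β ~ N(0, 10²) componentwise. Penalized-complexity-style priors
  on the derived scales: prior median of the range at one fifth of the
  domain diameter, and P(σ > 1) = 0.1 (exponential on σ). Both are
  configurable; the defaults are weakly informative at country scale.
* **Summaries.** OR = exp(posterior median) by default (mean available),
  CrI from the 2.5/97.5 percentiles, significance = CrI excludes 1.
  Split-R̂ and bulk ESS (via ArviZ) are reported when ≥ 2 chains are run.
* **Defaults.** The CLI default is 2 chains × 2000 iterations (800 burn-in,
  thin 2). The replicate studies in `experiments` use single chains of 1500
  iterations (500 burn-in), which pilot runs showed give stable 95% interval
  endpoints at the study's data size.

## Model comparison

DIC uses the classic plug-in form pD = D̄ − D(θ̄) with θ̄ the posterior
mean; WAIC uses the variance penalty (pWAIC2) with a max-shifted
log-mean-exp. For the spatial model the pointwise likelihood conditions on
the sampled latent field (the conditional likelihood, comparable with what
INLA reports for these models). Candidates are ranked ascending; ties break
toward fewer parameters; comparison refuses mismatched observation sets.

## Prediction and aggregation

For each retained draw d and grid pixel g, p_dg = invlogit(x_g'β_d +
(A_grid S_d)_g), where x_g uses the raster-derived covariates at the pixel;
survey-only covariates (child/household variables without raster surfaces)
are held at their reference levels, so the surface is a reference-profile
prevalence map. Pixels outside the country polygon or missing a covariate
are masked. Admin-level and national estimates are computed per draw as
(equal or population-weighted) pixel means, then summarized over draws, so
credible intervals are coherent under aggregation. Default grid: 0.05°
(~5 km), matching the coarser source rasters.

## Hold-out validation

Whole clusters are split 75/25 (floor convention on the test share),
stratified by admin-1 to preserve geographic spread; children follow their
cluster. Predicted prevalence per test cluster is the posterior mean of the
cluster-average child probability; predictive intervals add binomial noise
at the cluster size. Reported: Pearson and Spearman correlation, mean error,
mean absolute error, 95% predictive-interval coverage.

## Synthetic data generator

The generator emulates the 2018 Nigeria DHS design the pipeline is built
for:

* **Administrative map.** Voronoi partition of the domain box: 37 level-1
  units × 21 level-2 units by default (≈774 second-level units). Cells are
  valid, non-overlapping, and cover the box exactly.
* **Sampling.** Two-stage stratified cluster sampling: strata are
  admin-1 × urban/rural, clusters allocated proportionally to simulated
  stratum size (largest remainders, ≥1 per stratum); 1377 clusters and a
  Poisson(≈9.2) analysed-children count per cluster by default, for
  N ≈ 12,627. Urban clusters are placed near shared "city" centers so the
  urbanization raster classes and the urban strata cohere. Weights are the
  stratum population share over the sample share (a PPS proxy; exact DHS
  weight computation and non-response are out of scope — the emulated survey
  had a 99.3% response rate).
* **Geo-masking.** Displacement with uniform bearing and distance uniform
  on [0, 2 km] (urban) / [0, 10 km] (rural), redrawn until inside the
  country polygon. True coordinates are retained for validation only. DHS
  additionally displaces 1% of rural points up to 10 km; the simple uniform
  cap is used here and is configurable.
* **Latent field.** One SPDE draw on a simulation mesh with edge length
  range/4. Default truth: κ = 7.33 per degree, σ² = 0.24 — the full-scale
  fitted values for this outcome. With mass lumping the discrete marginal
  variance at this resolution is biased high by ≈9% relative to the
  continuum value (it decays slowly with refinement); tests budget for this.
* **Covariates and outcome.** Child/household covariates are drawn from
  marginals calibrated to the emulated survey's descriptive table; climatic
  covariates are read back off smooth synthetic rasters (planar gradient +
  Gaussian bumps, affinely mapped so the category band edges sit at the
  calibrated cumulative shares) through the same buffer-extraction code the
  real pipeline uses. True effects are the fitted adjusted odds ratios
  (e.g. diarrhoea 1.35, clean fuel 0.79); the intercept (−0.47) is
  calibrated so crude national prevalence lands near the design-based 37%.
  HAZ is back-filled from truncated normals consistent with the outcome.
* **What it does not emulate.** Region (geopolitical zone) effects — admin
  units are abstract Voronoi cells, and broad regional confounding is played
  by the latent field; household clustering of siblings; covariate
  correlation structure (covariates are drawn independently given the
  cluster); measurement error in anthropometry. Passing tests therefore
  demonstrate correctness of the estimator under the assumed model, not
  robustness to these real-data features.

Same seed ⇒ byte-identical output tables.

## Numerical choices

* Band edges: rainfall [142, 1200) mm (half-open); DLST bands <30 /
  [30, 35) / ≥35 °C (the printed "30–34.9" / "+35" labels leave [34.9, 35)
  formally unassigned; it is folded into the middle band); aridity <17.5 /
  [17.5, 32.5] / >32.5 with the upper edge closed ("17.5 up to 32.5"
  inclusive).
* Buffer extraction uses cell-center-in-buffer membership (the common zonal
  statistics default) on the sphere (haversine), radius exact, no
  reprojection.
* Gaussian sampling from a precision matrix: dense Cholesky up to 1500
  vertices, banded Cholesky after reverse-Cuthill-McKee reordering above.
* Degenerate inputs: zero-area bbox, cutoff larger than the domain,
  collinear mesh points, empty categories, single-PSU strata, units without
  valid pixels, and clusters outside the mesh all raise or warn explicitly
  (see the operation docstrings).

## Scaled study conditions

The replicate studies (`stuntmap.experiments`) run at 300 clusters × 20
children on a 2°×2° domain with the truth hyperparameters above — a
desk-scale version of the full design that keeps the range-to-domain ratio
informative and the mesh (≈250 vertices) small. The null study uses 400
clusters × 10 children with every effect zeroed — the held-out set must
contain ~100 clusters for the no-correlation check to be meaningful, since
the null sampling sd of Pearson r is ≈ 1/√(n_test − 3). All reported coverage
rates, win rates and correlations are computed by these studies at run
time; nothing is looked up.

## Known limitations

* The FEM variance bias above means hyperparameter "truth" is defined up to
  discretization; coverage checks use the continuum value and still pass.
* The conditional (not marginal) likelihood in DIC/WAIC makes the absolute
  criterion values non-comparable with marginal-likelihood-based software;
  rankings are what the pipeline relies on.
* Marginal-likelihood estimation is deliberately not implemented.
* Single split validation (no k-fold), matching the emulated workflow.
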