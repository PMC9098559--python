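# Methods

## Scope and data model

`pfnets` analyzes multi-scale personalized functional networks from
per-subject time × vertex matrices on a shared surface mesh, a per-vertex
functional-hierarchy map (a unimodal→transmodal scalar gradient, supplied
as an input), and cohort covariates (age in years, binary sex, mean
framewise displacement in mm, EF factor score in z-units). Acquisition and
preprocessing of real fMRI (distortion correction, confound regression,
filtering, surface projection) are out of scope; the pipeline starts from
surface timeseries.

## Synthetic cohort generator

The generator is not a test fixture but the package's stand-in for the
protected cohort; its defaults are the study conditions.

* **Surface**: an icosphere (12·4ⁿ vertices; subdivision 2 → 162 vertices by
  default). A sphere is used so spin-test rotations are exact isometries.
  162 vertices is the coarsest surface that still carries contiguous
  parcels at K up to ~10; it was chosen for single-CPU tractability and is
  far below the real 17,734-vertex surface, so absolute spatial statistics
  (e.g. vertex counts per network) do not transfer.
* **Hierarchy map**: z-coordinate plus mesh-smoothed Gaussian noise
  (sd 0.3 of the field), rescaled to [0, 1]. Smooth and nonconstant, like a
  principal functional gradient.
* **Group networks**: recursive 2-means bisection of the sphere (the first
  split is the K = 2 partition, so finer networks nest inside its halves),
  with soft loadings from a Gaussian kernel of great-circle angle to each
  region centroid (width 0.8 × region angular radius), max-normalized per
  network. This yields contiguous, partially overlapping parcels.
* **Personalized topography**: per vertex-and-network multiplicative
  perturbation with sd `topo_sd · hierarchy(v)` (default `topo_sd` 0.3),
  clipped nonnegative and re-max-normalized — topographic variability
  grows toward association cortex, as observed in real cohorts.
* **Coupling targets**: for each scale, an edge's correlation target is
  `intercept − a·D + b(edge)·(age − 15.5) + dev`, with `D` the hierarchical
  distance, `intercept` 0.35 and `a` 0.3 (so hierarchically close networks
  couple more), and per-subject stable deviations `dev ~ N(0, 0.08²)` per
  edge (individual differences beyond age; these are what cognition models
  and prediction latch onto once age is controlled). The per-edge age slope

      b = g1·(0.25 − D) + g2·(0.5 − h_mean),   g1 = 0.02, g2 = 0.03 /year

  plants both findings the analyses are meant to recover: distant edges
  weaken with age while short edges strengthen (g1), and edges among
  low-hierarchy networks strengthen while edges among high-hierarchy
  networks weaken (g2), so network-level age effects align negatively with
  hierarchy position. Magnitudes give coupling changes of ~0.1–0.2 over
  ages 8–23, a realistic developmental effect size. Targets are repaired to
  valid correlation matrices by eigenvalue clipping and re-normalization to
  unit diagonal; repair failure raises.
* **EF scores**: each network receives a weight quadratic in its
  within-scale normalized hierarchy position — negative at both extremes
  (segregation of sensorimotor and default-mode analogs helps EF), positive
  mid-hierarchy — and each edge the mean of its two networks' weights. EF =
  the standardized weighted edge-coupling sum pooled over configured scales
  + 0.08·(age − 15.5) + N(0, 1) noise, i.e. about half the EF variance is
  coupling-driven. The within-scale normalization matters: raw network
  hierarchy means compress toward mid-range (they are averages over member
  vertices), so a parabola anchored at the raw extremes would never go
  negative at the observed ones.
* **Timeseries**: K network courses drawn with the target correlation
  (Cholesky), mixed through the subject's loadings, plus i.i.d. Gaussian
  vertex noise (sd 0.25 against unit-variance courses — a generous but
  plausible vertex-level SNR). T = 555 timepoints, matching the
  concatenated scan length of the cohort design. No hemodynamics, no
  realistic noise spectra, no motion artifacts: passing tests show the
  pipeline recovers planted structure under idealized noise, not that it
  is robust to fMRI artifacts.
* **Determinism**: every operation funnels through one seeded
  `numpy.random.Generator`; identical config + seed is bit-reproducible.

An optional `scale_dependent_topo` flag makes topographic variability grow
at finer scales; it is off by default because the base variability gradient
already reproduces the qualitative alignment being tested.

## NMF solver

Alternating multiplicative updates: the standard Lee–Seung step for `U`,
and for `V` the graph-regularized step (numerator gains `λ_M·W·V`,
denominator `λ_M·D·V`), with the consensus term entering through its
positive/negative subgradient parts split between numerator and
denominator. Nonnegativity is preserved by construction. Monotone descent
of the full objective is not proven for the combined update, so each
iteration is checked against the tracked objective; on an increase the `V`
step is geometrically damped toward the previous iterate (up to six
halvings, falling back to no step). In practice the safeguard almost never
fires, and traces are asserted non-increasing to 1e-10 relative slack.

Stopping: relative objective change < 1e-6 (default) or 300 iterations.
Multiplicative updates approach exact factorizations slowly; tests that
demand reconstruction error < 1e-3 on exactly low-rank data allow up to
20,000 iterations at desk problem sizes.

The `‖V·,k‖∞ = 1` constraint is applied at convergence by rescaling each
column and folding the inverse scale into `U`, leaving `U Vᵀ` unchanged.
In the λ-scaling rules, `T` is always the per-subject scan length (555 by
default), including for the pooled group-stage matrix, and `n_m` is the
mesh's mean neighbor count. The group stage omits the consensus term (for
a single pooled `V` it is constant up to scale). Zero-variance vertices
get affinity 0.5 (the uninformative limit of `(1+corr)/2`).

Personalization runs the joint model for one subject with the fused group
atlas both as initialization and as a fixed pseudo-member of the consensus
stack, so the single-subject fit stays anchored to the atlas topography
while adapting to the subject's data. Loadings live in the preprocessed
space, where each vertex row is effectively rescaled by its peak amplitude;
recovery of planted loadings is therefore assessed either against the
rescaled truth or through hard partitions (argmax labels), which are
invariant to positive row scaling. Ties in argmax break to the lowest
network index; all-zero rows are labeled unassigned (−1).

## Atlas fusion

Bootstrap group decompositions (random subject subsets, random
initializations) are stacked and clustered with normalized-cut spectral
clustering (sklearn, precomputed affinity `exp(−d²/σ²)`, σ = median
off-diagonal distance, k-means assignment with a config seed). Each
cluster's representative maximizes summed within-cluster similarity with
self-similarity excluded; representatives are ordered by stacked index for
determinism. An empty cluster triggers up to five re-runs with shifted
spectral seeds, then an error. Desk-scale defaults are 10 replicates of
20-subject subsets; the published design (50 × 100) is available via the
`paper` profile.

## Statistics

* **Additive models**: cubic P-splines (uniform unclamped knots, basis
  dimension 8) with second-difference penalties, sum-to-zero constrained
  next to an intercept; parametric covariates unpenalized. Smoothing
  parameters minimize the profiled Gaussian restricted marginal likelihood
  (grid scan then bounded refinement; Nelder–Mead for multiple smooths).
  Uniform knots make the infinite-penalty limit exactly a straight line.
  Effective df is `tr((XᵀX+S)⁻¹XᵀX)`; adjusted R² uses it. Effect size is
  the change in adjusted R² between full and reduced fits, signed by the
  age (or EF) coefficient of the equivalent linear model; significance is
  an F-comparison on effective df. Like other penalized-ANOVA
  approximations, this p is mildly liberal under the null (rejection
  ≈ 0.07–0.09 at nominal 0.05 in calibration runs); ΔR²adj itself is
  unbiased near zero under the null (mean |ΔR²adj| < 0.01 at n = 500).
* **Derivative windows**: finite-difference derivative of the fitted
  smooth on a grid, pointwise 95% intervals from coefficient-posterior
  simulation (default 1000 draws), contiguous runs where the interval
  excludes zero. Pointwise, not simultaneous.
* **Second-order regressions**: OLS of unit effects on hierarchy position
  (optionally + squared term) or hierarchical distance, with CIs from
  resampling analysis units with replacement (default 1000), Spearman and
  Pearson correlations reported, and partial correlation via double
  residualization for the Euclidean-distance sensitivity check. The
  expensive alternative — resampling subjects and refitting every GAM — is
  what the full pipeline's bootstrap stage would do at paper scale; unit
  resampling is the desk-scale default.
* **Tensor surface**: a GCV-tuned tensor-product P-spline surface of edge
  effects over the two networks' hierarchy positions (visualization), with
  inference from a bootstrap of the product term in a linear interaction
  model.
* **GEE**: across-scale inference per unit with exchangeable working
  correlation and sandwich covariance (statsmodels), smooth terms expanded
  into fixed, rank-reduced spline bases and interactions as products of the
  two leading basis directions; joint Wald chi-square on the tested block.
  Coefficients are initialized at the independence-model estimates. With
  desk-sized bases (≈4 df) the GAM-stage penalty is negligible, so GEE
  re-estimates unpenalized coefficients on the frozen basis rather than
  carrying the penalty itself. Null calibration at 100 clusters × 7 scales
  lands inside [0.02, 0.09] at nominal 0.05. One observation per cluster
  degrades to robust OLS with a warning.
* **Spin test**: uniformly random 3D rotations (scipy `Rotation`) of one
  map's vertex positions with nearest-vertex resampling (cKDTree),
  two-sided add-one p on |Pearson r|. Only one map is rotated. Because
  the null preserves spatial autocorrelation it is wider than an i.i.d.
  shuffle null, which is the point of the method.
* **FDR**: Benjamini–Hochberg (statsmodels), applied per analysis family —
  network-level effects pooled across networks × scales, vertex-level maps
  per map.
* **Scale trend**: Pearson correlation of a per-scale statistic with scale,
  zero (flagged) for degenerate constant input, with a subject-resampled
  bootstrap CI when a recomputation callback is supplied.

## Prediction

Nested split-thirds ridge: per repeat, a random three-way split; covariates
(age, motion) are projected out of the response using a fit on the two
training thirds; features are standardized on the fitting third alone;
coefficients for a 20-point log-spaced λ grid (1e-3–1e4 × mean feature
variance) come from one SVD of the fitting third; λ minimizes MSE on the
tuning third; performance is measured on the untouched third. Per-subject
predictions are averaged over evaluating repeats (per-repeat r is also
kept). Permutation inference re-runs the whole procedure on permuted
responses, one-sided add-one p. Effectively constant predictions (the
infinite-shrinkage limit) are flagged and reported as r = 0.

A known desk-scale behavior: the generator fixes the per-edge deviation
variance, so spreading the planted EF signal over many scales dilutes the
per-edge weights; with 286 features and ~230 training subjects the
estimator approaches its shrinkage limit (r ≈ 0.1), while the concentrated
five-scale configuration recovers r ≈ 0.5. Real cohort data, with far more
per-edge signal, do not show this collapse at 4,495 features; the
acceptance script therefore demonstrates prediction on the concentrated
configuration and this note records why.

## Pipeline

`run_pipeline` executes simulate → atlas → personalize → coupling → stats →
predict with a JSON manifest recording config digests, outputs and wall
time per stage; stages whose digest and outputs are unchanged are skipped
and their products reloaded. Vertex-level GEE tests run on a deterministic
subsample of vertices (default 20) for tractability. Two runs with the
same config and seed produce identical result tables (the spectral
clustering seed is part of the config).

## Problem sizes used by tests and the acceptance script

Module tests run on 42- or 162-vertex meshes with small cohorts. The
end-to-end recovery block uses the desk defaults (40 subjects, T = 555,
162 vertices, K = 4, 10 bootstrap replicates of 20 subjects). The
developmental/cognitive recovery analyses run at the study's cohort size
(n = 693) on truth-level couplings (network courses sampled at the planted
correlations, bypassing NMF) over scales 2–12, with the per-edge GAM table
restricted to scales ≤ 8; the EF-quadratic power check follows the
~77-unit network table. These sizes are the package's chosen desk-scale
conditions; the `paper` profile exposes the published counts.

## Known limitations

* The sphere has no medial wall, no SNR mask, and two orders of magnitude
  fewer vertices than the real surface.
* Coupling noise is purely sampling noise of Gaussian courses; no
  autocorrelated BOLD spectra, so T = 555 is "worth more" here than in
  real data.
* The GAM F-test is approximate (mildly liberal); inference that matters
  downstream rests on bootstrap CIs, FDR flags and permutation tests.
* Monotonicity of the NMF objective is enforced by safeguard, not proven.
* The EF analysis recovers the planted quadratic reliably only at
  study-sized cohorts (n ≈ 693); at n = 150 the point estimate is negative
  but CIs often cross zero.
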