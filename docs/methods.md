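# Methods

## Model

A population of d covariates is modelled as marginals + copula. Writing
F₁…F_d for the marginal CDFs, the joint density factorizes as

    f(x₁…x_d) = c(F₁(x₁), …, F_d(x_d)) · ∏ f_j(x_j),

and the d-dimensional copula density c is factorized further into bivariate
(conditional) copulas along a regular vine: a sequence of trees in which
tree 1 links the variables and tree t+1 links edges of tree t that share a
node. Each edge (a,b | S) carries a parametric pair copula acting on the
conditional CDFs F(a|S), F(b|S); those conditionals are produced recursively
by h-functions, h(u|v) = ∂C(u,v)/∂v, of the lower trees.

### Marginals

Continuous covariates use a Gaussian KDE with a Silverman rule-of-thumb
bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5). Biochemical covariates (serum
creatinine, ALT, AST, ALP, bilirubin) and fat mass are modelled on the log
scale, which guarantees strictly positive back-transformed simulations. The
CDF is tabulated on a 512-point grid spanning the data range ±4 bandwidths;
PIT and quantile interpolate this shared table, so they are exact inverses
of each other by construction and a serialized marginal (grid + CDF +
density + bandwidth) reproduces the fitted transform without subject-level
data. Pseudo-observations are clamped to [1e−10, 1−1e−10].

Categorical covariates are described by level probabilities and mapped to
the uniform scale with a randomized PIT: u ~ Uniform(F(level−), F(level)],
using one seeded jitter per row. The randomization makes the discrete
variable usable in a continuous copula; the jitter seed is stored in the
model, so fits are reproducible.

The choice of kernel and bandwidth rule is deliberately standard; any
smooth kernel with a consistent bandwidth gives equivalent behaviour at the
sample sizes targeted here (10³–10⁴ subjects).

### Pair copulas

Families: independence, Gaussian, Student-t, Clayton, Gumbel, Frank, Joe,
BB1 (Clayton–Gumbel), BB8 (Joe–Frank); rotations 90°/180°/270° for the
one-sided families. This set covers symmetric, lower-tail, upper-tail and
two-parameter tail-mixture dependence. Densities and h-functions are
evaluated in log space throughout; for Clayton, BB1 and BB8 the Archimedean
generator identities (e.g. k(C) = k(u)k(v)/η for BB8) avoid forming the
copula value C explicitly, which would otherwise lose all precision near
the corners. Log-densities are floored at −700.

Fitting maximizes the (optionally weighted) log-likelihood with L-BFGS-B
inside each family's admissible box (t degrees of freedom restricted to
[2, 50]; Frank |θ| ≤ 35 with the |θ| < 1e−5 limit treated as independence),
started from the Kendall-τ inversion of the empirical tau. One-sided
families are only tried in the rotations matching the sign of the empirical
tau. The family with minimal AIC = 2k − 2ℓ wins; ties break toward fewer
parameters, then a fixed canonical family order, then rotation — selection
is fully deterministic. Below 20 observations the independence copula is
returned with a warning.

h-inverses use closed forms where they exist (independence, Gaussian, t,
Clayton, Frank) and a 52-step vectorized bisection otherwise; both satisfy
h(h⁻¹(p|v)|v) = p to better than 1e−8.

### Vine estimation

Tree t is selected as the maximum spanning tree (deterministic Kruskal:
weight descending, then lexicographic node keys) on |empirical Kendall τ|
of the pairwise-complete (conditional) pseudo-observations, restricted to
pairs allowed by the proximity condition. Kendall's τ is used as the edge
weight because it is invariant under the monotone PIT, so "maximizing the
sum of correlations" is assessed on the scale the copula actually sees.
Each later tree re-runs the constrained MST rather than inheriting a fixed
structure. Each selected edge is fitted by the AIC search above; its two
h-functions produce the next tree's inputs. The model log-likelihood is the
sum of edge log-likelihoods; AIC adds 2 per copula parameter.

Missing data: every edge is estimated on the rows complete for its
conditioned pair and conditioning set; incomplete rows propagate missing
conditional pseudo-observations upward. No imputation is performed — the
fitted model is complete even though no subject is.

Weights are frequency weights: the KDE bandwidth uses an effective n equal
to the weight total and the IQR term uses weighted type-1 quantiles, so
duplicating a row is *exactly* equivalent to doubling its weight. Survey
sampling weights should therefore be normalized to sum to the number of
subjects before fitting if Silverman-scale bandwidths are desired; the
copula parameter estimates themselves are invariant to the weight scale.

Categorical level ordering: the ordinal encoding of a nominal covariate is
not identified, so `fit_vine_with_categorical` fits one vine per level
permutation (k! candidates, refused for k > 7) and keeps the lowest AIC.
All candidates share the same PIT jitter realization; otherwise their
likelihoods would differ by randomization noise rather than by ordering.

An optional truncation level stops copula estimation after the first so
many trees (higher trees contribute least to the fit); the remaining
structure is still selected so that simulation stays exact, with
independence copulas on the truncated edges.

### Simulation

The inverse Rosenblatt transform needs an elimination order. The structure
is peeled: the single edge of the top tree names a variable that is a
conditioned member of exactly one edge per tree; removing it leaves a vine
on d−1 variables. Each peeled column converts one independent uniform
through a chain of h-inverses (conditioning values retrieved from a cache
filled by already-sampled columns), exactly the column decomposition that
underlies the usual R-vine matrix. Uniform-scale samples are then mapped
through the marginal quantiles (exp applied for log-scale covariates) and
categorical uniforms decoded by cumulative level probabilities under the
model's stored ordering. Simulated tables are always complete.

Subgroup simulation is rejection sampling from the full model: batches of
4n rows (growing geometrically) are filtered by category membership and
inclusive numeric ranges until n rows are kept; the empirical acceptance
rate is reported, and an acceptance rate below 1e−4 at the attempt cap
raises an infeasible-filter error. BMI = weight/(height/100)² is the one
derived covariate (its formula is universal).

## Evaluation metrics

- Marginals: RE = (M_sim − M_obs)/M_obs for M ∈ {mean, SD, P5, P50, P95}
  (percentiles by linear interpolation between order statistics — stated
  because conventions differ); level-frequency differences for categorical
  covariates, which are excluded from the correlation/overlap metrics.
- Correlation: Pearson on the modelling scale (log for log-scale
  covariates), error |r_sim − r_obs| per pair.
- Contour overlap: the "95% contour" is read as the highest-density region
  containing 95% of the estimated mass. The 2-D KDE is a binned estimate on
  a 256×256 grid padded 3 bandwidths past the data range (normal-reference
  bandwidth σ·n^(−1/6) per axis, Gaussian smoothing of the histogram),
  thresholded at the smallest density whose superlevel set holds the target
  mass; rings from marching squares are assembled into polygons with
  even-odd nesting, and the metric is 100·area(A∩B)/area(A∪B) (shapely).
  Contours are computed on the modelling scale. The operand order inside the
  geometric ops is canonicalized so overlap(A,B) = overlap(B,A) exactly.
- `evaluate_model` simulates replicates of the observed size, computes all
  metrics per replicate, and summarizes by median and coefficient of
  variation. An `exclusions` hook drops simulated values that have no
  observed counterpart (e.g. a measurement never taken above an age
  cut-off) so extrapolation is not scored as error.
- `compare_subgroup_strategies` contrasts filtered-full-model simulation
  with dedicated per-subgroup models; `holdout_missing_validation` masks a
  covariate inside anchor bands, refits and scores the in-band predictions.

## Synthetic population generator

`vinepop.fixtures` draws from a latent Gaussian copula whose margins target
the published adult-survey summary table: truncated normals (loc/scale
solved so the *truncated* mean and SD hit the targets) for age, weight,
height and albumin; moment-matched lognormals for fat mass and the
laboratory panel; sex 48.5/51.5 and the five race-ethnicity groups at their
published frequencies. Sex is a thresholded latent coordinate, so it shifts
height, creatinine, bilirubin and fat through the correlation structure
(moderate weight–height–fat block, mild age–creatinine, strong ALT–AST).
Default missingness: fat mass structurally missing at age ≥ 60 plus a 45%
random block among the age-eligible (total ≈ 56%), ~6.3% MCAR on each lab
value, 1% on weight/height.

What the generator does *not* emulate: survey design effects, heaped or
detection-limited laboratory values, heavy right tails of body weight
beyond a truncated normal, and any dependence pattern more exotic than a
Gaussian copula plus thresholding. Passing tests therefore demonstrate
correct recovery of a known joint distribution and calibrated metrics —
not fidelity to any real survey beyond first/second moments and category
frequencies.

## Numerical choices and problem sizes

Default test and acceptance runs use 10³–10⁴ subjects, 10 evaluation
replicates and the full nine-family search; a 12-covariate fit at n = 10⁴
takes on the order of two minutes on one core, and simulation runs at
thousands of rows per second. Degenerate inputs fail loudly: all-missing or
<10-value columns, zero-variance contour inputs, non-positive-definite
fixture correlation specifications (repaired by eigenvalue clipping when
possible), non-positive values under a log-scale flag (reported with the
offending row), infeasible subgroup filters.

## Known limitations

- Sequential (tree-by-tree) estimation is the standard greedy approximation;
  no joint or Bayesian structure estimation, and no model averaging.
- Parametric pair copulas only: sharply non-monotone dependence shapes
  (e.g. a heart-shaped pair density) are captured at best approximately.
- The exhaustive categorical ordering search is factorial in the number of
  levels and refused above 7; nominal variables with many levels need a
  pre-specified order.
- Subgroup generation is by rejection, so very rare subgroups are expensive;
  no analytic conditional-vine sampler is provided.
- Randomized PIT treats a categorical variable as continuous during
  estimation; frequencies are reproduced, but copulas attached to a
  categorical node mix within-level jitter with between-level dependence.
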