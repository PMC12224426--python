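# Methods

This note documents the statistical model, the estimation and inference
procedures, the defaults and the numerical choices made where the design
was genuinely open, and what the synthetic-data generator does and does not
emulate.

## Model

Images are rows of an N×V matrix Y, vertices live on a triangulated
surface. At vertex v,

    y(v) = X β(v) + r(v) + ε(v)

with three independent Gaussian components:

- **Between-image dependence** r(v) ~ N(0, θ²(v) K), drawn independently
  across vertices. K encodes the study design: a block of ones within each
  subject's scans (test-retest), 1 / 0.5 for MZ / DZ co-twins, or a
  user-supplied genetic relationship matrix. θ²(v) is the parameter under
  test; θ²(v)/(θ²(v)+τ²(v)) is the vertex-level ICC (test-retest) or
  narrow-sense heritability (twins).
- **Spatially autocorrelated within-image noise** b_i ~ N(0, σ² Φ(φ, D))
  with exponential SACF Φ = exp(−φD), D the geodesic distance matrix.
- **White noise** δ_i ~ N(0, τ² I).

The null hypothesis is θ²(v) = 0 for every v.

## Geometry

Geodesic distances are edge-weighted shortest paths on the mesh graph
(Dijkstra over Euclidean edge lengths), not exact polyhedral geodesics.
The method only thresholds distances at millimetre radii, so the
within-one-edge-length error of graph geodesics is immaterial; an exact
precomputed distance matrix can be supplied to override. Masked vertices
(e.g. the medial wall) are removed before the shortest-path computation
and never enter any neighborhood. Neighborhood membership is precomputed
once per (D, radii) pair as sparse indicator matrices, so a neighborhood
sum over all vertices is a single sparse product reused across all
permutations.

## Null-model estimation

- Per-vertex OLS through one shared projector (identical to per-vertex
  least squares, bit for bit).
- (σ², τ², φ) minimize Σ_i ‖ε̂_i ε̂_i' − σ²Φ(φ,D) − τ²I‖²_F. The objective
  is quadratic, so it is fit through the mean outer product
  M̂ = (1/N)Σ ε̂_i ε̂_i' (same minimizer, O(V²) memory instead of O(NV²)).
  For each φ on a grid the optimal nonnegative (σ², τ²) solve a 2×2 Gram
  system in closed form (active-set enumeration over the three feasible
  candidates); the grid point with the lowest objective wins.
- **φ grid default**: 20 log-spaced values such that the SACF at the
  median pairwise distance spans 0.95 to 0.01 — negligible to strong
  autocorrelation on any mesh scale.
- **Nonnegativity and flooring**: the unconstrained Frobenius fit can
  return negative variances on noisy data, which would break the positive
  definiteness of Σ̂; σ² is truncated at 0 and τ² floored at 1e−8·var(E).
- **Identifiability caveat**: a decay rate whose correlation length
  exceeds the mesh diameter is barely expressed in the data, so φ is only
  reliably recovered when the surface spans a few correlation lengths
  (the parameter-recovery test uses a ~50 mm patch for φ = 0.05/mm).
- The BLUP b̂_i = σ̂²Φ Σ̂⁻¹ ε̂_i is computed per image (the model makes
  residual images i.i.d., so nothing is pooled across images). Whitened
  residuals are δ̂_i = ε̂_i − b̂_i.
- For V ≤ 2000 (default) Σ̂⁻¹ is applied by dense Cholesky. Above that, a
  Vecchia / nearest-neighbor Gaussian-process factorization is used:
  vertices ordered by their first spatial coordinate, each conditioning on
  its m = 50 nearest previously-ordered neighbors (by geodesic distance),
  giving a sparse triangular precision factor. With m = V−1 this is exact;
  at m = 50 the relative reconstruction error on kilovertex problems is a
  few percent, far below the Monte-Carlo noise of the permutation null.

## Score statistics and enhancement

U(v) = d(v)' K d(v), with d the whitened residuals (full model) or raw OLS
residuals (non-spatial variants). The proportionality constant of the
classical scaled score statistic is dropped: every downstream quantity is
standardized by permutation moments and is scale-invariant. The analytic
null (mixture of χ²₁ with weights the eigenvalues of the kernel conjugated
by the residual projection) is implemented — including an Imhof-inversion
tail probability accurate to ~1e−4 — purely as a validation oracle; the
inference path is permutation-only.

Neighborhood sums S_r(v) = Σ_{v*∈N_r(v)} U(v*) are standardized per
(r, v) by the sample mean and sample standard deviation (B−1 denominator)
of the same sums across the B permutations; the same moments standardize
the permuted sums themselves, so the permuted standardized values have
mean 0 and sd 1 exactly. The adaptive statistic is T(v) = max over radii
(radius 0 keeps the raw statistic in play; ties take the smallest radius),
and T = max over unmasked vertices. Default radii are 0,1,…,20 mm with
r_max configurable; unit spacing is a convention, and the spacing is a
config knob.

## Permutation scheme and exactness

Under H0 the images are exchangeable, so shuffling image labels against
the fixed K — equivalently, permuting the rows of the whitened residual
matrix — generates the null. Nothing is refitted inside the loop: β̂, b̂
and (σ̂², τ̂², φ̂) are permutation-invariant functionals of the data.

One deliberate convention matters at small B: **the identity shuffle is
always the first member of the permutation set**, so the observed
statistic is one of its own B references. Every stage (standardization
moments, threshold, p-value) then treats observed and permuted data
completely symmetrically, and the test is exact: under H0 the global
rejection probability is ⌊αB⌋/B for continuous statistics. If instead the
observed statistic is excluded, its standardized coordinates carry ~(1 +
c/B) more variance than the self-standardized permuted ones; the global
maximum over thousands of vertices amplifies that small asymmetry into a
noticeable FWER inflation at B in the low hundreds (an idealized
Monte-Carlo of the excluded-observed construction at B = 200, V = 289
gives ≈ 0.081 at nominal 0.05). With the identity anchored, measured null
FWER at B = 200 is statistically indistinguishable from 0.05. The
reported p-value count/B is algebraically the usual (1 + #{T⁽ᵇ⁾ ≥ T}) /
(B_random + 1) form and can never be zero.

t_α is the ceiling-rank (1−α) empirical quantile of the permuted maxima
(the ⌈(1−α)B⌉-th order statistic) — the conservative reading of "the
(1−α)th quantile". The global decision (T > t_α) and the localization rule
(T(v) > t_α) share this one threshold. B defaults to 5000 and α to 0.05.

Degenerate designs are flagged rather than silently standardized: an
exchangeable kernel (e.g. K = I) makes every permuted statistic identical,
and the zero permutation variance raises an error naming the offending
vertex. The kernels keep a unit diagonal; replacing K by K − I shifts every
U(v) by the permutation-invariant constant d'd and leaves all standardized
statistics unchanged (unit-tested), so the diagonal convention is
inconsequential.

## Variants

- `full`: spatial whitening + enhancement.
- `no_spatial`: OLS residual statistics, same neighborhoods.
- `no_enhance`: spatial whitening, radius 0 only.
- `massive`: OLS residuals, radius 0 only — the classical
  massive-univariate permutation score test. `no_spatial` at radius 0 is
  definitionally identical to `massive` (tested exactly); `full` fitted on
  data without spatial noise approaches `massive` as σ̂² → 0.

All variants share the identical permutation machinery.

## Effect-size estimator

The descriptive per-vertex ratio θ̂²/(θ̂²+τ̂²) uses method-of-moments under
the non-spatial vertex-level model: θ̂²(v) = Σ_{i≠j} K_ij e_i e_j / Σ_{i≠j}
K_ij², τ̂²(v) the remainder of the residual variance, ratio clipped to
[0, 1]. The clipping makes the null expectation slightly positive (order
of the estimator's standard deviation); the estimates are descriptive and
play no role in the test.

## Synthetic-data generator

The simulator draws directly from the generative model above on built-in
meshes (planar triangulated lattices with 1 mm spacing; icospheres of
radius 50 mm). Scenario builders mirror the standard study structures:
20 subject pairs (N = 40) for test-retest, 60 twin pairs (N = 120, half
MZ) for heritability. A "null" scenario claims pseudo pairs in the
analysis kernel while generating fully independent images; partial-signal
scenarios make only a fraction of the claimed pairs real by giving the
generating kernel blocks only for true pairs. Defaults: σ² = 1, τ² = 1, φ
set so the SACF at the median pairwise distance is 0.3 (a mid-strength,
mesh-scale-free choice), θ² = τ² inside the signal region (vertex-level
ICC 0.5, a strong but realistic reliability), signal confined to a
geodesic disc covering ~10% of vertices so enhancement is exercised by
contiguous signal.

What this does **not** emulate: real task-fMRI contrast maps are
nonstationary and anisotropic, their SACF is only approximately
exponential, true signal regions follow functional anatomy rather than
discs, and data-driven resampling of real images preserves all of that.
Calibration and power results on these synthetic surfaces therefore
demonstrate correctness of the machinery under its own model — FWER
exactness in particular holds under any exchangeable null — but power
magnitudes are not quantitative predictions for cortical data.

## Problem sizes used in the shipped studies

The calibration study uses a 17×17 lattice (289 vertices), N = 40 images,
B = 200, 500 replicates; the power-monotonicity study a 10×10 lattice with
200 replicates per signal level at B = 100. These sizes put Monte-Carlo
error around one percentage point on a rejection rate while keeping the
full suite in the minutes range on a single core; all scale knobs are
plain function arguments.

## Known limitations

- Graph geodesics overestimate true surface distance by up to one edge
  length; supply an exact D if that matters at r ≤ 2 mm on coarse meshes.
- The covariance regression assumes a stationary isotropic exponential
  SACF; misspecification degrades power but not FWER (the permutation null
  never relies on the fitted covariance being correct).
- Only the additive component of twin designs is modeled (no shared-
  environment decomposition); pedigree file parsing is out of scope —
  supply a GRM as a custom kernel.
- Vertex-wise adjusted p-value maps are not produced; localization is the
  single-threshold rule T(v) > t_α.
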