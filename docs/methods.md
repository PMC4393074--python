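# Methods

This note records the statistical model implemented by `fdmoments`, the
conventions and numerical choices that were genuinely open, and what the
test suite does and does not establish.

## Model

### Counts and observability

All genes are treated as null (the all-null presumption, appropriate when
the null proportion π₀ is large, say ≥ 0.9; the resulting estimate of the
false-discovery count F is conservative). Each gene's pooled-variance
two-sample t statistic (df = M − 2) is mapped through its null CDF and the
normal quantile to a z value, unit normal under the null. Two regions of
the z axis drive everything:

* tail area: z ≤ δ (left-sided by default, δ = −2.5) with null count F;
* center area: |z| ≤ c (c = 1) with count C, treated as observable since
  essentially no non-null score falls near zero. The choice c = 1 follows
  the eigenvector analysis in the literature indicating that [−1, 1] has
  count behavior opposite to the rest of the axis.

The z axis is binned with width Δ = 0.1, edges anchored at 0 so that ±c
and δ fall exactly on edges; scores use half-open bins [lo, hi), so a
score exactly at −c belongs to the center side. The binned range defaults
to [−6, 6] (unit-normal mass beyond is ~10⁻⁹ per gene); region-level
computations use exact interval probabilities and need no truncation.

### Moments under dependence

With z scores jointly normal to third order, the bin counts Y_b have

* mean  μ̂(Y_b) = G Δ φ(z_b);
* covariance  φ̂(Y_b, Y_b′) = G(G−1) Δ² Q_ρ(z_b, z_b′) + δ_bb′ μ̂_b − μ̂_b μ̂_b′;
* a third-central-moment formula built from the trivariate analogue Q_R,
  the three pair-coincidence Q_ρ terms, the triple-coincidence mean, and
  the central-moment conversion.

Here Q_ρ(z₁, z₂) = ∫ q_ρ(ξ) N₂(z₁, z₂; ρ = ξ) dξ and
Q_R(z) = ∫ q_R(Ξ) N₃(z; 0, Ξ) dΞ mix the normal densities over empirical
correlation densities (below). The Kronecker term in the covariance is
implemented with a **plus** sign: the same-gene term of the exact
expansion adds δ_bb′ μ̂_b, and only this sign reproduces multinomial
moments (nonnegative variances) in the independence limit. The suite
verifies the full second/third-moment algebra against exhaustive
multinomial enumeration at small G.

Moments of (F, C) are obtained by region aggregation. The implementation's
default path replaces bin sums by exact bivariate/trivariate normal *box
probabilities* over the tail and center intervals (no midpoint error, no
truncation; the semi-infinite tail is integrated as such). The literal
bin-sum path is retained for testing and agrees with the region path to
O(Δ²) (~0.3% at Δ = 0.1).

### The correlation densities

Column standardization of the residual matrix (each gene's within-group
means removed) forces each column to sum to zero, hence the *full* double
sum of pairwise row covariances is exactly zero — the justification for
fitting a zero-symmetric density to the observed correlations. (The
off-diagonal sum alone equals −trace, i.e. O(1/G) relative to the G²
pairs; the test asserts the exact identity.)

Sample correlations ρ̄ of residual row pairs are Fisher-transformed
(τ = atanh ρ); a zero-mean normal is fitted to the τ̄ values by the method
of moments (second moment about zero; the τ̄ mean is reported as a
diagnostic only). The known sampling variance is subtracted
(deconvolution), the remainder is mapped back to the ρ scale through
σ²_ρ = E[tanh²(ξ)], ξ ~ N(0, σ²_τ) (Gauss-Hermite), and matched to the
Beta-family density

    q_ρ(ξ) ∝ (1 − ξ²)^a,  ξ ∈ [−1, 1],   via   α = (1 − σ²_ρ) / (2 σ²_ρ).

**Fisher sampling variance.** Residual rows with df = M − K (K = 2 groups)
behave like uncentered spherical (M−K)-vectors, for which the null
variance of atanh ρ̄ is 1/(M − K − 2); a Monte-Carlo calibration at
M ∈ {8, 15, 16} confirms this to under 1%. This is the default
(`fisher_var="auto"`). The textbook alternatives 1/(M−K−1), 1/(M−3),
1/(G−3) and any explicit float are selectable; the G-based form is
documented only as a historical variant (with G in the thousands it
subtracts essentially nothing and the deconvolution becomes vacuous).

**Convention flag.** The Beta-family bookkeeping admits two internally
coherent readings that differ by one in the exponent:

* `eq22` (default, literal): density exponent a = α with
  α = (1 − σ²)/(2σ²). This mixed pairing is what reproduces the published
  downstream values (implied corr(F, C) of −0.88/−0.73 at α = 17.77/3.51
  against the printed −0.89/−0.75).
* `eq24` (variance-consistent): a = α − 1, so the fitted density's
  variance 1/(2a + 3) equals σ² = 1/(2α + 1) exactly. Generative recovery
  tests use this self-consistent convention.

The discrepancy is O(1/α) and immaterial at heavy-tailed α ≈ 18, modest at
α ≈ 3.5.

**The matrix density q_R.** Third moments need a density over 3 × 3
correlation submatrices whose pairwise marginals equal q_ρ. Assuming the
(unnormalized) covariance matrix follows an inverse-Wishart W⁻¹(I, ν) and
separating scales from correlations, every κ × κ correlation submatrix has
a closed-form density; for κ = 2 it is (1 − ξ²)^{(ν−G−1)/2}, so setting
ν − G = 2a + 1 pins the construction to q_ρ. The κ = 3 density is

    q_R(Ξ) ∝ det(Ξ)^{2a+2} / Π_i det(Ξ_ii)^{a+2},

with Ξ_ii the 2 × 2 principal minors; its sampler draws
Σ ~ W⁻¹(I, 2a + 4) in three dimensions and rescales to a correlation
matrix. The inverse-Wishart assumption is instrumental — it is used only
to extend q_ρ consistently to triplets, not as a model of the full G × G
matrix.

### Quadrature and sampling

* E_ξ[·] over q_ρ: Gauss-Jacobi quadrature with weight (1−ξ²)^a
  (96 nodes; exact for polynomial integrands, machine-precision for the
  smooth normal mixtures). For a > 200 the density is within O(1/a) of
  N(0, 1/(2a+3)) and Gauss-Hermite nodes are substituted.
* E_Ξ[·] over q_R: a shared sample of matrices (default n_mc = 50 000,
  seeded) reused across every box-probability evaluation in a run. The
  sampler drives the Bartlett decomposition with a scrambled-Sobol
  quasi-Monte-Carlo stream: each draw is exactly q_R-distributed, but
  sample averages converge much faster than 1/√n. This matters because
  third central moments are near-cancelling differences of O(G³) terms —
  with plain pseudo-random draws at moderate n_mc the estimated moment
  vector can fall outside the feasible set and the maxent fit fails.
* Bivariate/trivariate normal box probabilities: Gauss-Legendre
  conditioning integrals (48/32 nodes per axis, semi-infinite limits
  clipped at |z| = 8.5 where the neglected mass is ~10⁻¹⁷), vectorized
  over the ξ nodes / Ξ sample with chunking.

### Maximum-entropy fit and inference

The maxent distribution matching the 5 (order 2) or 9 (order 3) moments on
the feasible mesh {f ≥ 0, c ≥ 0, f + c ≤ G} has exponential-family form
with monomial sufficient statistics in mean/sd-normalized coordinates
(normalization keeps the cubic terms conditioned). The Lagrange
multipliers minimize the convex dual log Z(λ) − λ·m; the gradient is the
moment mismatch and the Hessian the statistic covariance, so a damped
Newton iteration (backtracking line search, Gaussian initialization of
the quadratic terms) converges in ~10–30 iterations to |grad|∞ < 10⁻⁸.
The fit is verified against a generic solution of the primal optimality
system (Powell-hybrid root finder) to better than 10⁻⁶ per cell, and the
order-2 solution against the analytic discretized Gaussian.

Mesh: axes cover mean ± 6 sd clipped to [0, G]; 100 × 500 cells by
default, refined (e.g. 400 × 2000) under heavy covariance; a refinement
test checks <1% movement of the conditional mean when doubling.

Conditioning slices the mesh row nearest C_obs (ties to the lower row;
linear interpolation available behind a flag). The point estimate is the
conditional (posterior) mean; 50% and 75% central intervals are reported.
Discovery control scans candidate thresholds δ from most to least extreme
and returns the least extreme δ whose exceedance bound
P(F ≥ γ·G* | C) ≤ λ holds, with the full scan table.

Infeasible moment vectors (e.g. skewness unreachable on the bounded
support) raise with guidance rather than silently degrading; isolated
replicate failures in the benchmark are recorded and skipped.

## The simulator's stated world

`simulate` generates correlated all-null raw mRNA levels: a common Gamma
shape κ, per-gene scales θ_g ~ Gamma(κ₀, θ₀) (so gene means κθ_g and
variances κθ_g² rise together), and a Gaussian copula Z^c = L Z with L the
Cholesky factor of the target correlation matrix plus a diagonal load
(default 10⁻³) for rank-deficiency; x = Γ⁻¹(Φ(z^c)). Note the copula is
implemented as L·Z (giving row covariance LLᵀ = R); the transposed form
sometimes written does not reproduce R. The three preset parameter sets
(1, 0.6, 500), (2, 0.39, 384), (3, 0.33, 300) share total marginal
variance ≈ 3.9 × 10⁵ (within 2%) and range from exponential to
near-Gaussian marginals.

The reference protocol imposes a real data set's correlation matrix on the
copula; as a self-contained substitute the generator provides dense
factor-model correlation matrices, calibrated by default (3 factors, noise
sd 2) to Var(ρ) ≈ 0.06, i.e. α ≈ 8 — inside the range α ≈ 3.5–18 observed
on real panels. Any user-supplied correlation matrix is accepted, which
restores the original protocol exactly. Analysis of simulated raw levels
log-transforms them first, the standard pre-processing for positive
expression scales (and the regime where Fisher correlation theory is
calibrated).

What the generator does *not* emulate: array-level artifacts (batch,
normalization residue), non-null genes (the world is all-null by design),
and the specific eigenstructure of any real data set's correlation matrix.
A green benchmark therefore establishes internal consistency of the
estimator under dense exchangeable-ish dependence at desk scale
(default G = 500, 40 replicates; the reference scale is G ≈ 3200 with 800
replicates per setting), not field performance on any particular platform.

## External-data checks (documented, not asserted)

With the BRCA (G = 3226, M = 15, groups 7/8) and HIV (G = 7680, M = 8,
groups 4/4) matrices on disk, the pipeline can be pointed at them via
`fdmoments estimate <matrix> --design <file> --log-transform`. The
published analyses report α = 17.77 / 3.51, observed tail counts 116 / 46,
conditional point estimates 104 (order 3) vs 79 (order 2) for BRCA and
8 vs 19 for HIV, and 174 / 108 controlled discoveries for HIV at
(γ, λ) = (0.15, 0.5). These depend on the external data (and, for the
point estimates, on unpublished details of the original maxent appendix),
so they are not part of the test suite; the in-package checks cover every
data-free consequence of those configurations (naive means 20 / 73 / 48,
implied correlations −0.88 / −0.73, permutation count 70).

## Known limitations

* Moments stop at order 3; higher-order dependence is unmodeled.
* The one-parameter q_ρ cannot represent asymmetric or multi-modal
  correlation structure; column standardization deliberately symmetrizes.
* α estimation at very small M (e.g. 8) is noisy: the Fisher sampling
  variance (≈ 1/4 on the τ scale) then dominates the signal, and the
  deconvolution can fail (nonpositive variance) on weakly correlated
  panels — reported as an error suggesting the independence fallback.
* The estimand after column standardization is the *residual* correlation
  structure; a strong common factor is partly absorbed by the
  normalization, by design.
* Maxent feasibility bounds the representable skewness on a finite mesh;
  extremely skewed moment sets (very small α at small G) raise rather
  than fit.
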