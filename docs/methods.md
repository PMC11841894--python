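# Methods

## Model

Two data matrices `A (n_a × p)` and `B (n_b × p)` share a feature axis.
Covariances are estimated as `C = DᵀD/(n−1)` from *centered* data (the
estimators center each condition by default; `compute_covariance` itself does
not center, so callers working with raw matrices are responsible for it).
Each variant extracts unit feature-space directions extremizing a contrast:

* `v1` (cPCA): eigendecomposition of `C_A − αC_B` in feature space. α ≥ 0
  trades off how strongly B's variance suppresses directions; it has no
  data-independent correct value.
* `v2`: generalized eigenproblem `C_A x = λ C_B x` — λ is the ratio of the
  variance the component explains in A to that in B, in `[0, ∞)`.
* `v3`: `(C_A − C_B) x = λ C_B x` — λ is the relative variance change versus
  the background, in `[−1, ∞)`.
* `v4`: `(C_A − C_B) x = λ (C_A + C_B) x` — λ is the symmetric contrast index
  `(varA − varB)/(varA + varB)` in `[−1, 1]`. Swapping A and B yields the
  same components with λ negated, so A-enriched components sit at the top of
  the spectrum and B-enriched ones at the bottom.

### Solution on the joint principal subspace

The ratio denominators can be singular (fewer samples than features,
collinear features), so the problem is restricted to the subspace where the
data actually live: `J (p × k)` holds the right singular vectors of the
row-wise concatenation `[A; B]` with singular values above
`rank_tol × s_max` (`rank_tol = 1e-10`). The reduced denominator `Jᵀ S J` is
eigendecomposed; directions below the same relative tolerance are removed
(this matters for v2/v3, whose denominator `C_B` alone can be singular inside
the joint subspace even though `C_A + C_B` is not) and `J` is rotated into
the denominator's eigenbasis, which makes the square root `M` diagonal —
numerically cheaper and exactly equivalent to any other symmetric square
root choice. The symmetric matrix `M⁻¹Jᵀ N J M⁻¹` is then eigendecomposed
(`N` the variant's numerator), giving orthonormal whitened components `Y`
and eigenvalues equal to the generalized Rayleigh quotients. Feature-space
loadings are `X = JM⁻¹Y`.

Conventions: loading columns are rescaled to unit Euclidean norm (the
Rayleigh quotient is scale-invariant; unit norm makes loadings comparable
across variants), the entry of largest magnitude in each column is made
positive (deterministic output across eigensolver implementations), and
components are ordered by descending eigenvalue with ties left in eigensolver
order.

### Preprocessing matters, and why

v2–v4 eigenvalues are invariant under any invertible linear map of feature
space (the objectives are congruence-invariant), but the *coordinates* of the
loadings are not: `X = JM⁻¹Y` divides each denominator eigendirection by its
standard deviation, so features with near-zero variance acquire enormous
loading coordinates from arbitrarily small noise. On data whose feature
variances span many orders of magnitude, raw loadings are therefore dominated
by the lowest-variance features even when the fit itself is correct. The
practical recipe — used by this package's benchmark and recommended for real
data — is to z-score and l2-normalize each feature *jointly across both
conditions* (`standardize_pair`), which equalizes every feature's combined
variance, makes the whitening benign, and leaves between-condition variance
ratios untouched. Per-condition z-scoring would instead erase the very
contrast being sought.

## Orthogonal variants (v2.1 / v3.1 / v4.1)

Ratio-variant components are orthogonal in the whitened space, not in feature
space. The `.1` variants restore feature-space orthogonality by deflation:
solve the reduced problem on the current basis, accept the extreme
eigenvector mapped to feature space, then replace the basis by an orthonormal
basis of `(I − xxᵀ)J` (one fewer column, from the SVD of the regressed-out
basis) and re-solve, recomputing `M` each iteration since the reduced
denominator changes with the basis. For the symmetric `v4.1` the accepted
extreme alternates largest / smallest eigenvalue so both A- and B-enriched
directions are collected; for the asymmetric variants only the largest is
meaningful and alternation is not used. Output columns are re-sorted by
descending eigenvalue to match the unconstrained convention. The first
component always equals the unconstrained leading component, and when both
covariances are diagonal the constraint is inactive and the `.1` fit equals
the plain fit exactly.

## Sparse variants

Sparsification reinterprets the whitened eigenproblem as a regression. The
target matrix is `Θ = M⁻¹Jᵀ N J M⁻¹` (for v1, `Θ = C_A − αC_B` in feature
space). Since Θ may be indefinite (eigenvalues ≥ −1 for v3/v4), it is first
shifted by `(|λ_min| + ε)I` when `λ_min ≤ 0` — eigenvectors and eigenvalue
order are unchanged — and its symmetric square root `Θ^{1/2}` taken. From the
dense components `Y`, two steps alternate until the coefficient matrix `B`
changes by less than `1e-6` (relative Frobenius norm) or 200 iterations:

1. **Coefficients given rotation** — each column solves
   `min_β ‖Θ^{1/2}y_j − Θ^{1/2}β‖² + κ‖JM⁻¹β‖² + λ‖JM⁻¹β‖₁`. The penalties
   act on the feature-space image of β so the *loadings* become sparse.
   Substituting `w = JM⁻¹β` turns this into a standard elastic net in `w`
   with design matrix `Θ^{1/2}MJᵀ`, solved by coordinate descent
   (scikit-learn's `ElasticNet`; tolerance 1e-8, up to 1000 inner
   iterations); λ = 0 paths use least squares / the ridge normal equations
   directly. `w` ranges over all of `ℝ^p` — a relaxation of the exact
   constraint `w ∈ span(J)` that is an identity whenever `k = p` (the common
   full-rank case); for `k < p` the final loadings are the projection
   `JJᵀw`, which can be denser than `w`.
2. **Rotation given coefficients** — the reduced-rank Procrustes solution
   `Y = UVᵀ` from the SVD of `ΘB`.

The joint objective `‖Θ^{1/2} − Θ^{1/2}BYᵀ‖² + penalties` is non-increasing
across both steps (tracked in `objective_history_` and asserted in tests).
Final loadings are `JM⁻¹B`, nonzero columns rescaled to unit norm; fully
sparsified (all-zero) columns are reported, not errors.

**Symmetric variants are sparsified two-sided.** After the Tikhonov shift the
most-B-enriched direction (eigenvalue `λ_min`) has target weight `≈ ε`, so a
single repaired target hands the lasso exactly the components the symmetric
variant exists to find and they are zeroed at any useful λ. Because swapping
A and B negates Θ, components with negative dense eigenvalues are instead
sparsified against `−Θ` (with its own repair). Asymmetric variants use the
single-target algorithm unchanged.

Parameters: `lasso_lambda` (dimension of the data scale; no universal
default — sweep `sparsity_path` and pick by desired support size),
`ridge_kappa = 1e-4` (pure rank repair), `ε = 1e-6 × mean|eig(Θ)|` with a
1e-12 floor (a trace-based scale would be sign-degenerate for the symmetric
variant, whose eigenvalues can sum to ≈ 0).

Feature ranking multiplies each loading column by its eigenvalue and takes
the per-feature ℓ2-norm across the selected components, giving one
importance score per feature (e.g. per gene).

## cPCA α selection

For reference fits with `v1`, candidate α values are chosen automatically:
cPCA is solved on a log-spaced grid (default 40 values, 0.01–1000), each
solution is summarized by its top-k eigenvector subspace (default k = 2),
pairwise affinities are the product of cosines of principal angles between
subspaces, the affinity matrix is spectrally clustered, and each cluster's
medoid α is returned. The affinity and clustering algorithm are this
package's choices — the selection idea is standard but no canonical formula
exists; note the result depends on k, which is a second effective
hyperparameter.

## Synthetic benchmark

`generate_fig1_dataset(n_samples, seed)` builds two conditions with 100
dimensions whose magnitudes fall linearly from 10 to 0.001. Per condition,
each dimension's sample vector is built, centered, scaled to unit l2-norm,
then multiplied by its magnitude — so the sample variance of dimension *i*
is *exactly* `mag_i²/(n−1)` and all sampling error lives in cross-dimension
correlations (~n^{-1/2}), the mechanism that defeats the naive contrast.
Condition A doubles the magnitude of dimensions 71–72 (a square-with-a-hole
manifold: uniform samples with re-sampled central bands, offset by 0.5 and
sorted by their polar angle via the two-argument arctangent); condition B
doubles dimensions 81–82 (a diamond: a uniform square sorted by the first
coordinate and rotated 45°, counter-clockwise — recovery is
direction-invariant). All other dimensions are unit-norm Gaussian vectors.
Doubling the magnitude quadruples the variance, giving the planted
dimensions a v4 index of exactly ±0.6 before sampling noise.

Two construction choices deserve note. (1) Columns are centered *before*
l2 normalization: without it, the rotated-square dimensions carry a large
mean that inflates their norm and deflates their centered variance
sevenfold, which would silently flip one planted dimension from B-enriched
to A-enriched and make the stated ground truth unrealizable. (2) By default
the features *are* the generative dimensions (identity basis). An
orthonormalized-Gaussian rotation into feature space is available
(`rotate=True`, basis stored in the truth object); every fit here is
equivariant under it, so it exercises bookkeeping rather than statistics,
and per-dimension readouts (loading peaks, sparsity support) are only
meaningful in the identity basis.

What the generator emulates: a realistic decaying variance spectrum,
condition-specific low-variance structure, and finite-sample covariance
noise. What it does not: count noise, batch effects, non-Gaussian heavy
tails, correlated features within a condition, or mean shifts between
conditions — passing the benchmark shows robustness to variance-bias under
sampling noise, not to those artifacts.

`recovery_score` takes the argmax-|loading| dimension of each of the top
(and, for symmetric variants, bottom) components and reports the fraction
inside the planted sets. `adjusted_variance` scores possibly-correlated
component scores via QR: with `Z = QR`, component *i* receives the *i*-th
row sum of `R²` (a diagonal-of-`R²` convention is available behind a flag);
orthogonal columns reduce to ordinary sums of squares and a duplicated
column receives ~0.

## Problem sizes

The test suite and the acceptance script run the benchmark at n = 1000
(10 seeds for the recovery rate; the naive-contrast asymptotic check uses a
single n = 100000 run), eigenvalue-bound and target-bound sweeps over 100
random 20 × 5 Gaussian instance pairs, and oracle comparisons against dense
generalized eigendecompositions at p ≤ 6. These sizes make every check run
in seconds while leaving the qualitative phenomena (finite-sample failure of
the naive contrast, exact recovery by the ratio objectives) fully expressed.

## Limitations

* Two conditions only; no multi-condition or nonlinear/kernel extension.
* Sparse and orthogonal constraints are mutually exclusive (deflation has no
  meaning for non-orthogonal sparse solutions).
* `v1`'s α and the α-selector's k remain genuinely data-dependent choices;
  the selector narrows, but does not remove, that freedom.
* The sparse solver's λ is shared across components and not cross-validated;
  `sparsity_path` reports support sizes across a grid instead.
* Eigenvalue ties (exactly degenerate spectra) make individual loadings
  non-unique; only the spanned subspace is then identified.
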