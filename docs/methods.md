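# Methods

This note documents the statistical model, the estimation procedure, the
numerical conventions, and the simulation protocol implemented in
`relief_harmonize`, including the design choices made where more than one
reasonable convention exists.

## Model and assumptions

The data are a complete V × n features-by-subjects matrix observed on M
scanners (batches), each contributing nᵢ ≥ 2 subjects, with an n × q
covariate table. The additive decomposition is

    Y = A + βX′ + [Γ₁; …; Γ_M] + R + [I₁; …; I_M] + [δ₁E₁; …; δ_M E_M],

where R and each Iᵢ are low-rank, E has unit-variance entries, and δᵢ is a
per-scanner noise scale. Identification rests on three assumptions: latent
structure is low-rank against full-rank noise; variation shared by all
scanners belongs to R (kept) while variation expressible within a single
scanner's block belongs to Iᵢ (removed); and noise is homogeneous within a
scanner after scaling. Harmonization removes Γᵢ and Iᵢ and replaces the
per-scanner noise scales by their pooled value; it preserves A, βX′ and R.

## Estimation

**Step (i), two-step regression.** Per feature, OLS on [1, X] (the
intercept is always included, also when q = 0), then within-scanner means
of the first-stage residuals are subtracted. The two-step order (rather
than a joint one-hot regression) is deliberate; one consequence, verified
in the tests, is that a scanner-constant shift is absorbed exactly only in
the intercept-only model — with covariates a small part can leak into β̂
through in-sample covariate/scanner correlation. Missing values are
rejected, not imputed. An optional per-feature rescaling divides each
residual row by its population (divisor n) standard deviation before the
factorization and multiplies it back afterwards; the convention is
irrelevant to the output because the scales are inverted exactly. The
option is off by default; enable it when feature variances span orders of
magnitude.

**Step (ii), noise scales.** For each residual block,
δ̂ᵢ = median(singular values) / sqrt(max(V, nᵢ) · μ_β), with μ_β the median
of the Marčenko–Pastur distribution of ratio β = min(V,nᵢ)/max(V,nᵢ)
(unit-variance convention). Under this normalization a unit-variance noise
block yields δ̂ᵢ ≈ 1, which is what the standardized matrix Δ requires; the
estimator is exactly scale-equivariant and rotation-invariant, and the
median makes it robust to a few large signal singular values (all singular
values are included — no attempt is made to exclude "signal" ones first).
μ_β is computed by adaptive quadrature of the MP density after the
substitution x = a + u², which removes both the square-root edge and the
β = 1 endpoint singularity, plus bisection on the CDF (absolute/relative
quadrature tolerance 1e-12, root tolerance ~1e-12, cached per ratio). The
pooled scale is δ̄² = Σ nᵢ δ̂ᵢ² / n.

**Step (iii), linked factorization.** The objective is
½‖Δ − R* − I*‖²_F + λ‖R*‖⋆ + Σᵢ λᵢ‖Iᵢ*‖⋆ with defaults λ = √V + √n and
λᵢ = √V + √nᵢ. With the ½ on the misfit term, the exact block update is
singular-value soft-thresholding at the penalty level, and the default
penalties sit at the spectral edge of unit-variance noise, so pure noise is
(essentially) left to Ê. Block coordinate descent from R* = Iᵢ* = 0
alternates R* ← svt(Δ − I*, λ) and Iᵢ* ← svt(Δᵢ − Rᵢ*, λᵢ), one full sweep
per iteration, stopping when the relative objective change drops below
tol = 1e-6 (max_iter = 500); each step is an exact block minimization, so
the objective trace is non-increasing and this is asserted in the tests.
Non-convergence raises a warning and is flagged, never silent. The solver
is deterministic (LAPACK SVDs; the seed argument exists only for interface
stability). Singular values exactly at the threshold are treated as
removed (a measure-zero event). Because the penalties sit *at* the noise
edge, a largest noise singular value fluctuates above them with
non-negligible (Tracy–Widom) probability; the escaped component is a trace
amount (tested: < 2% of the input norm) and is harmless to the output.

**Step (iv), reassembly.** Ŷ = Â + β̂X′ + [δ̂ᵢ R̂ᵢ*] + δ̄ Ê with
Ê = Δ − R̂* − Î*. The shared component is returned blockwise on its
original scale (δ̂ᵢ R̂ᵢ*), not the standardized one, so latent covariate
effects inside R keep their magnitudes. No extra per-scanner centering is
applied to Ê; it inherits near-zero block means from preprocessing. The
stored components sum to the output to machine precision, and the re-added
fitted effects are bit-identical to the first-stage fit (a *refit* of the
design on the output can drift by a small amount because the retained
components are not exactly orthogonal to the design after block rescaling
and thresholding).

## Reference methods

**AdjRes** removes per-feature scanner means only. **ComBat** additionally
standardizes per-feature variance, with parametric empirical-Bayes
shrinkage of the per-scanner location/scale parameters across features
(normal prior on locations, inverse-gamma on variances, method-of-moments
hyperparameters, iterated conditional updates to relative change < 1e-8).
Standardization follows the canonical ComBat algorithm (batch indicators in
the standardization regression, sample-size-weighted grand mean, pooled
residual variance with divisor n). One deliberate deviation from the R/sva
implementation: the within-scanner variance of the standardized data uses
the population divisor nᵢ rather than nᵢ − 1, which makes single-batch
ComBat an exact no-op; `var_ddof=1` restores the sva convention, and a test
cross-checks the EB output against Bioconductor `sva::ComBat` in that mode
(agreement ≲ 1e-4). **CovBat** runs ComBat, eigendecomposes the residual
covariance, and re-harmonizes (location/scale, no covariates) the smallest
set of leading PC scores reaching `variance_retained` (default 0.95,
recorded in provenance because results depend on it); the score-level pass
uses no empirical Bayes by default (with a single retained score EB is
impossible and the closed form is used). All methods preserve fitted
covariate effects by the same re-addition structure and return the same
`HarmonizedDataset` container, so the evaluation metrics compare them under
identical settings.

## Simulation designs

**Linked-factor design** (the planted-truth test bed; defaults are the
study conditions): two scanners of 50 subjects, V = 100 features, q = 4
nuisance covariates drawn MVN with AR(1) correlation 0.2 and coefficients
N(0,1); location effects γᵥ ~ N(0, 1.5²) drawn once per feature and shared
by both scanners; shared latent structure R = rank-3 truncated-SVD
reconstruction of a standard Gaussian V × n matrix, and likewise rank-3
per-scanner components multiplied by a strength c ≥ 0; noise scales
δᵢ ~ Uniform(1, 1.5); noise N(0,1). All planted components are stored for
recovery checks.

**PC-shift design**: two scanners (defaults 172 and 179 subjects, V = 72),
y = α + γᵢ + δᵢᵥ ε with γᵢᵥ ~ N(0, 0.1²), δ₁ᵥ ~ IG(46, 50),
δ₂ᵥ ~ IG(51, 50) (drawn directly as the multiplicative factor), and
ε ~ MVN(0, S + cᵢ Σ_{l≤L} λ̂_l ψ̂_l ψ̂_l′) with c₁ = −3/4, c₂ = +3/4 — a
rank-L eigenvalue shift of a base correlation matrix, validated to stay
positive semidefinite. Because no real tract-level correlation matrix is
shipped, the default S is a *synthetic* random correlation matrix
(`scipy.stats.random_correlation`) with a geometric eigenvalue spectrum
(ratio 0.8, chosen to emulate the strong leading structure of tract-level
diffusion features); a user-supplied S is accepted. Results under the
synthetic S are design-matched, not value-matched, to analyses that used a
specific empirical S.

What these generators do *not* emulate: non-Gaussian noise, spatial
autocorrelation beyond low-rank structure, site-nested scanner hierarchies,
longitudinal repeats, and covariate–scanner confounding. Passing tests
therefore demonstrate correctness of the estimator under its own model
class, not robustness to every feature of real data.

## Permutation FWER/power protocol

Per dataset: draw a fresh binary covariate of interest z (Bernoulli(½),
redrawn if degenerate); optionally spike τ·z into a random 20% (default) of
features; harmonize with z excluded from the design (the recommended
configuration) or included (the configuration the protocol exists to warn
about); then test every feature against z with a pooled-variance two-sample
t statistic and Westfall–Young single-step max-|T| permutation p-values
p_v = (1 + #{b : max_b ≥ |t_v|})/(B + 1), rejecting at α = 0.05. By default
the nuisance covariates are regressed out of the harmonized data before the
t statistics (`adjust_covariates=True`) — the standard confounder
adjustment; without it, the nuisance-effect variance dominates the t
denominator and masks the covariate-inclusion inflation the protocol is
designed to expose. FWER is the fraction of null datasets with any
rejection (Clopper–Pearson 95% interval); power is the mean detected
fraction of spiked features. One master seed spawns independent per-dataset
substreams.

Problem sizes: the calibration checks use 250 datasets × 500 permutations
and the power-ordering checks 200 datasets × 300 permutations with τ = 0.8
(a mid-power effect size under the adjusted statistic), totalling a few
minutes on one CPU.

## Known limitations

- With the penalties at the noise spectral edge, planted scanner-specific
  components whose singular values are near the threshold are captured only
  in heavily shrunken form. In the covariate-included misuse experiment
  this caps the measurable false-positive inflation at moderate component
  strengths (c ≈ 1) well below what unshrunken removal would produce; the
  inflation grows clearly with c (≈ 0.15 at c = 2 in our runs). A debiased
  variant (unpenalized refit at the selected ranks) was evaluated and
  roughly doubles the inflation at c = 1, but it is not the minimizer of
  the stated objective and is not enabled.
- δ̂ᵢ assumes min(V, nᵢ) large enough for the MP approximation; at very
  small blocks the estimate is noisy (relative error shrinks with block
  size, tested at 50/100/200).
- QDA scanner prediction requires nᵢ − 1 > V or an explicit covariance
  shrinkage (`shrinkage` > 0, recorded in the report).
- `transform` is only defined for the fitted data: harmonization is a
  joint model of all subjects, and there is no out-of-sample mapping.
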