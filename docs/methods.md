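# Methods

## Model

A quantitative trait over a pedigree is modelled as multivariate normal
with covariance Ω = 2Φ·σg² + I·σe² (AE), optionally plus C·σc² where C is
the within-family sharing indicator (ACE).  Narrow-sense heritability is
h² = σg²/σP² with σP² the component sum.  The package stores the doubled
kinship matrix 2Φ — the covariance multiplier — rather than Φ itself;
entries are produced by the standard generation recursion
(φ(i,i) = ½(1+φ(fa,mo)), φ(i,j) = ½(φ(fa_i,j)+φ(mo_i,j)) on the
later-generation member, founders mutually unrelated), with monozygotic
co-twins collapsed onto one genetic representative so that they are
genetically identical to each other and equivalent to third parties.
Supported designs are non-inbred pedigrees without half-sibs from the
builders; the recursion itself is general.

## Eigen-rotation

2Φ is block diagonal by family, so its eigendecomposition is computed per
family block (with a content cache — all MZ blocks are identical) and
assembled; eigenvalues are clamped at zero within 1e-8 and sorted
descending.  Rotating a residualised trait by the eigenvectors gives
independent observations with variance σP²·wᵢ, wᵢ = (1−h²) + λᵢh².  All
likelihood work happens in this rotated basis.

## Maximum-likelihood fitting

σP² profiles out in closed form, σ̂P²(h²) = (1/n)·Σzᵢ²/wᵢ, leaving a 1-D
bounded problem.  Two deliberately independent optimizers are provided:
`mle_a` runs safeguarded Newton on the analytic gradient/Hessian of the
profile log-likelihood inside a gradient bracket (bisection fallback, and
immediate boundary return when the gradient at 0 or 1 already points
outward); `mle_b` scans a 0.01 grid and refines the bracketing interval
by golden section.  Convergence tolerance is 1e-8 on h², at most 100
iterations; non-convergence is reported on the estimate, never silently
accepted.

At h² = 1 the multipliers wᵢ vanish on zero eigenvalues (MZ-difference
components) and the likelihood is singular: degenerate noise-free data
drives it to +∞ there, noisy data to −∞.  Internally w is floored at
1e-12, which keeps every evaluation finite while preserving the ordering,
so boundary maxima are located correctly; the public `loglik_ae` instead
rejects arguments that would make w ≤ 0.

Significance uses the boundary likelihood-ratio test: the statistic is
max(0, 2·(ℓ_full − ℓ_null)) referred to a ½:½ mixture of a point mass at
zero and χ²₁.  At a zero statistic the reported p is 0.5 — the supremum
of the continuous branch, matching common variance-component software —
while the strict mixture CDF would give p = 1 there.

ACE fits are restricted to designs where 2Φ and C commute: independent
twin/sib pair (or singleton) families, where the per-pair joint
eigenvectors are (1,1)/√2 and (1,−1)/√2 with kinship eigenvalues 1±r and
sharing eigenvalues 2 and 0.  Anything larger raises rather than
approximating.  The (h², c²) simplex is maximised by a 0.02 coarse grid
followed by an SLSQP polish of the profile likelihood; the LRT null for
ACE retains the C component (a CE model).

## Fast approximations

FPHI: the squared rotated values sᵢ = zᵢ² satisfy E[sᵢ] = σe² + λᵢσg².
Stage 1 is OLS of s on (1, λ); stage 2 is one WLS step with weights
1/(2·(σ̃e²+λᵢσ̃g²)²) (the reciprocal variance of a squared normal), with
fitted variances floored at 1e-6 of the mean of s to guard near-zero
stage-1 fits.  Components are truncated at zero after the step.  The WLS
normal equations are exactly the ML score equations evaluated at the
stage-1 point, so on data whose rotated squares lie exactly on the line
the single step already sits at the ML stationary point; iterating the
step to a fixed point reproduces the (unconstrained) MLE and is exposed
only as a debug flag.

APACE: for a pair (i,j), d = ½(yᵢ−yⱼ)² has E[d] = σP² − cov(i,j), giving
the AE regression E[d] = (1−r)σg² + σe² and the ACE extension
(1−fam)·σc².  All pairs — MZ, DZ and cross-family unrelated — enter an
ordinary least-squares fit; negative components are truncated to zero and
σP² is then the truncated sum (this renormalisation affects h² only at
boundaries).  Because unrelated pairs grow quadratically, an option caps
them at a configurable multiple (benchmark default 10×) of the related
count via a fixed-seed subsample.  Whether published pair-difference
implementations weight pair classes differently is not derivable from
the model itself; unweighted OLS over all (or capped) pairs is this
package's documented reading.

## Homogenization

Residualisation is plain OLS against an intercept plus the declared
covariates (age, sex, optionally age², age×sex, age²×sex), applied in
original space before rotation on every path — raw and homogenized — so
method comparisons differ only in the transform.  The inverse normal
transform maps average ranks through Φ⁻¹((r − 3/8)/(n + ¼)) (Blom's
approximation to expected normal order statistics; exact order-statistic
means would cost far more for no practical gain). The r/(n+1) (van der
Waerden) convention is switchable.  Ties keep average ranks so tied
inputs stay tied; the transform is invariant to any strictly monotone
marginal distortion.  Homogenized matrices are flagged so downstream
fits use an intercept-only nuisance model.

## Simulator

`simulate_traits` draws y = g + c + e per trait: g from the family-block
matrix square root of 2Φ scaled by h²σP², c a per-family shared normal
scaled by c²σP², e independent with the remainder.  Defaults emulate the
reference twin study: 125 MZ + 125 DZ pair families (1,000 persons,
founder parents unphenotyped, 500 phenotyped twins), unit total variance,
no covariate effects, and true h² on an even deterministic grid over
[0, 1] — the grid removes one layer of Monte-Carlo noise relative to
random uniform draws and makes truth reproducible without storing it.
Per-trait random streams are keyed by (seed, trait index), so column
subsets are bit-reproducible.  Covariates, when requested, are age ~
U(20, 60) years and balanced sex, drawn once per dataset on a reserved
stream.

The generator produces exactly normal traits with exactly the specified
variance structure; real phenotypes add measurement noise, skewness,
kurtosis and covariate structure the generator does not emulate (a test
injects gross outliers to exercise the homogenization path).  Passing
simulation benchmarks therefore demonstrates estimator agreement under
the model's own assumptions, not robustness on arbitrary real data —
which is precisely the contrast the homogenization step addresses.

## Concordance benchmark

For each method and condition the report gives bias (mean estimate −
reference), average spread (mean |estimate − reference|/reference), the
least-squares slope/intercept of estimate on reference, and Pearson r.
Traits whose reference falls below a floor (default 0.05) are excluded
from the relative spread and counted, since |err|/true diverges as the
reference approaches zero; the floor is configurable and reported.  The
reference is either simulated truth or the mean of the two MLE vectors
(the standard choice when truth is unknown).  The Shapiro–Wilk screen
reports raw p-values at α = 0.05 with no multiplicity correction, plus
sample excess kurtosis.

## Problem sizes and determinism

Shipped benchmarks and the acceptance script run the 500-phenotype twin
design with 2,000 traits — enough that dual-MLE agreement and the
approximation correlations are measured well inside their Monte-Carlo
bands — and complete in well under a minute on one CPU; the full
10,000-trait design runs in a few minutes if wanted.  Dense relatedness
matrices bound the practical design size at a few thousand families;
simulator moment checks therefore pool co-twin correlations across many
independent traits rather than growing one enormous pedigree.  All
randomness flows from explicit integer seeds through numpy Generators;
reruns are bit-identical.

## Known limitations

No standard errors of h² (information matrix not assembled), no
bivariate/genetic-correlation models, no dominance or household
components beyond C, no inbreeding or X-linkage, and no permutation-based
familywise-error machinery for the fast estimators.  The ACE path covers
pair designs only.  Founders are used solely to define relationships
unless explicitly phenotyped.
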