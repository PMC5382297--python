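# Methods

## Model

For N unrelated subjects the mean model relates phenotype Y to covariates
X (N×m, intercept included), a single environmental exposure E (length N)
and a variant set G (N×p minor-allele counts 0/1/2) through a link g
(identity for continuous Y, logit for binary 0/1 Y):

    g{E(Y)} = X b_x + E b_e + [G main effects] + diag(E) G W pi2 + diag(E) G d

`W` (p×q, default the p×1 equal-weight vector 1/p) collapses the set for
the *fixed* interaction effect `pi2`; `d` is a per-variant random
interaction effect with `E[d] = 0`, `Var[d_j] = omega_j tau^2`
(`omega = identity` by default; beta-density MAF weights are available but
off). The G×E null hypothesis is `pi2 = 0` and `tau^2 = 0`.

### Genetic main effects in the null

The package's null mean models adjust **each SNP's main effect
separately** by default:

    M = [X, E, G, diag(E) G W]      (tau-score null)
    V = [X, E, G]                   (interaction-free null)

rather than collapsing the main effects through W. This choice is forced
by calibration: when variants carry real, heterogeneous main effects, a
burden-collapsed main-effect model leaves per-SNP structure in the
residuals, and the interaction scores are no longer centred. The failure
is mild for a randomly sampled continuous phenotype but catastrophic under
case-control sampling, where exposure and genotype become dependent given
selection — measured rejection of a nominal-0.05 test reached 0.98 at
n = 2,000 with burden-collapsed main effects, versus 0.05 with per-SNP
main effects. `main_effects="collapsed"` restores the W-collapsed design
for settings where p approaches N (hundreds of SNPs against hundreds of
subjects), where per-SNP adjustment is not estimable; users should prefer
smaller sets or stronger weighting there and read results cautiously.

### Null fits

Identity link: ordinary least squares (`numpy.linalg.lstsq`). Logit link:
logistic maximum likelihood by IRLS from a zero start, converged when the
relative deviance change drops below 1e-10 (at most 100 iterations);
|coefficient| > 30 on any column raises a quasi-separation error naming
the columns. Rank-deficient designs are pruned by an incremental
Gram–Schmidt rank test with relative tolerance 1e-10 that always prefers
earlier columns, so covariates are never dropped in favour of genetic
columns; dropped indices are reported in the fit and test diagnostics.
Missing genotype calls are imputed to the per-SNP mean of observed calls
(integer rounding available, off by default). Monomorphic SNPs are
retained (they contribute nothing) and flagged; an all-monomorphic set is
an error.

### Variance diagonals and the small-sample correction

The plug-in variance diagonals are RSS/N (identity) and `mu(1-mu)`
(logit); `variance_diag` returns exactly these. The *fits* store a
degrees-of-freedom-inflated version, `n/(n-k)` with k the number of
retained mean-model columns, used by the score tests. The plug-in
estimates ignore the k fitted parameters and make the score tests
anti-conservative in small samples (measured Fisher-combined rejection
0.061 at nominal 0.05 with n = 200); the inflation restores calibration
(0.0498) and vanishes as n grows. `dof_correction=False` disables it.

## Score statistics

* Variance-component score: `S = r' diag(E) G omega G' diag(E) r` with
  `r = Y - mu_hat` from the M-fit. Null law: `sum_i lambda_i chi2_{1,i}`
  where `lambda_i` are the non-zero eigenvalues of P·K, with
  `P = D - D M (M' D M)^{-1} M' D` the variance-projected hat complement
  and `K = diag(E) G omega G' diag(E)`; computed economically as the p×p
  eigenproblem of `A' P A`, `A = diag(E) G sqrt(omega)`. Eigenvalues below
  1e-10 of the largest are truncated. A numerically perfect null fit, a
  zero exposure vector or an empty eigenvalue set short-circuits to a
  degenerate result with p = 1 and a flag (never an exception).
* Fixed-effect score: `U = (diag(E) G W)'(Y - mu_tilde)` from the V-fit,
  `Sigma = B'{D - D V (V' D V)^{-1} V' D}B`, and `U' Sigma^+ U` referred
  to chi-square with df equal to Sigma's numerical rank (symmetric
  pseudo-inverse, relative cutoff 1e-10).
* The interaction-SKAT variant (`p_random`) repeats the variance score
  with residuals and projection from the V-fit.

Tail probabilities use the Liu et al. four-cumulant moment match: when
`s1^2 > s2` a non-central chi-square surrogate, otherwise the
skewness-matched central surrogate with `df = c2^3 / c3^2`. The
approximation is accurate in the decision-relevant tail (survival
probabilities below ~0.2 agree with Monte-Carlo truth to well under 0.01)
and can err by ~0.01 near the distribution centre for unfavourable weight
sets; a seeded Monte-Carlo oracle (`mixture_sf_mc`, default seed 20170406)
validates it in the tests. Combined p-values are
`chi2_4.sf(-2 log p_pi - 2 log p_tau)` (Fisher) and `1-(1-min p)^2`
(Tippett) — the unique continuous p-values consistent with the usual
rejection rules — with inputs clamped to [1e-300, 1] for log stability.

## Simulation engine

Binary phenotypes: `logit P(Y=1) = log(0.01/0.99) + 0.64 E + sum_j a_j G_j
+ sum_j b_j E G_j`, E ~ N(0,1), eight SNPs under Hardy–Weinberg
equilibrium with MAF redrawn per replicate from U(0, 0.5) (floor 0.005 to
avoid empty variants). Subjects accrue one at a time — implemented as
order-preserving vectorised batches — until the case and control quotas
are both met; overflow is discarded and total draws are capped at 1e7.
Continuous phenotypes drop the prevalence intercept and add N(0, sigma^2)
noise on n subjects with no quota. The type-I configuration fixes
`a = [1,1,-1,-1,0,0,0,0]`, `b = 0`; power presets redraw
`a_j ~ Bern(0.5)(1 - 2 Bern(0.5))` per replicate and set b to
`C × [1,...,1]` (burden), `C × [1,1,-1,-1,0,0,0,0]` (variance, zero-mean)
or `C × [1,1,0,0,.5,.5,.5,.5]` (mixed), with the published C grids per
sample size; continuous power fixes C = 1 and varies sigma^2 over
{2,...,10} (small) or {8,...,40} (large).

Seeding: a scenario seed spawns one independent child stream per replicate
(`numpy.random.SeedSequence`), so runs are bit-reproducible and
replicates parallelisable. A replicate whose logistic fit separates (a
rare variant private to one outcome class; about 1 in 2,000 replicates at
n = 200) is redrawn from a further child stream, capped at 20 attempts —
the induced conditioning is negligible at that rate.

What the generator does *not* emulate: linkage disequilibrium between
SNPs, population stratification, covariates beyond an intercept, missing
genotypes, related subjects, or multiple correlated exposures. Passing
tests therefore demonstrate correctness of the statistics under
independent HWE genotypes and a single exogenous exposure, not robustness
to those real-data features.

## Voxelwise driver and FDR

For an identity-link phenotype matrix (subjects × voxels) sharing one
design, everything voxel-independent is computed once: pruned designs,
orthonormal projection bases, the unit-variance eigenvalue set of the
projected kernel and the unit-variance score covariance. Because the
identity-link variance estimate is a per-voxel scalar, eigenvalues and
Sigma scale linearly in it, and per-voxel work reduces to two projected
residual vectors and a few inner products — this is what makes
whole-image scans practical. Logit-link phenotypes fall back to a
per-voxel loop. Constant-phenotype voxels are flagged, given p = 1 and
(by default) excluded from FDR.

Storey q-values: `pi0 = #{p > lambda}/(m(1-lambda))` at fixed
`lambda = 0.5` (a smoother-based automatic estimate is available by
flag), clamped to [1/m, 1]; `q_(i) = min_{j>=i} pi0 m p_(j)/j`. With
`pi0 = 1` this is exactly Benjamini–Hochberg, which serves as the test
oracle.

## I/O conventions

VCF sites are restricted to biallelic diploid records (others skipped with
a logged count); coding is the minor-allele count relative to the analysis
sample, ties broken to ALT, recomputed after any subject subsetting.
Variant-set intervals are 1-based and inclusive with a ±20 kb default
flank, both endpoints included. When several risk variables proxy one
exposure, the environment is the first principal component of the
standardized variables (sample sd), sign-fixed so the largest-magnitude
loading is positive, reported with loadings and explained-variance
fraction. All file readers cross-check row counts and refuse silently
truncated input. Result tables print p-values in 3-significant-digit
scientific notation with a full-precision CSV sidecar.

## Problem sizes in the shipped checks

The packaged tests use 10,000 null replicates for the small
case-control condition, 5,000 for the other three null conditions
(uniformity assessed on the first 5,000 everywhere), 300–400 replicates
per point for power ordering, 1e5–1e6 draws for Monte-Carlo oracles, and
100-voxel images for the voxelwise checks; the acceptance script runs both
type-I conditions at the full 10,000 replicates.

## Known limitations

* One exposure per model; multi-environment kernels are out of scope.
* Per-SNP main-effect adjustment is not estimable for p approaching N;
  the collapsed fallback changes the null being tested (see above).
* The tau p-value retains a small finite-sample bulk deviation
  (~0.02 on the CDF at n = 200, binary link) inherent to plugging
  estimated means into the quadratic-form reference distribution; exact
  numerical inversion of the mixture CDF does not remove it.
* No relatedness/mixed-model covariance; subjects are assumed
  exchangeable given the design.
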