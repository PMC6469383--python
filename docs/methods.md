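# Methods

## Model

`sgllmm` fits a multi-locus association model for a quantitative trait
measured on m samples genotyped at p biallelic SNPs (dosages 0/1/2):

    y = X beta + y_pop + phi,
    y_pop ~ N(0, sigma_g^2 K),    phi ~ N(0, sigma_e^2 I)

`X` holds standardized dosages, `beta` is a sparse vector of SNP effects, and
`K` is the realized relationship matrix (RRM) `K = Z Z^T / p` of
column-standardized genotypes `Z`, so the random effect absorbs population
structure, family structure and cryptic relatedness without modeling them
individually.

Estimation is two-step:

1. **Null model.** With `beta = 0`, `y ~ N(0, sigma_g^2 (K + delta I))` where
   `delta = sigma_e^2 / sigma_g^2`.  After the eigendecomposition
   `K = U diag(S) U^T`, `sigma_g^2` profiles out in closed form,
   `sigma_g^2 = (1/m) sum_i (U^T y)_i^2 / (S_i + delta)`, leaving a
   one-dimensional objective

       f(delta) = sum_i log(S_i + delta)
                + m log( (1/m) sum_i (U^T y)_i^2 / (S_i + delta) )

   minimized over `delta`.  This is a maximum-likelihood (not REML) profile;
   the delta-free additive constant is dropped, so reported log-likelihoods
   are comparable only within one dataset.  The phenotype is mean-centered
   before this step (the model has zero mean); the mean is restored at
   prediction.

2. **SNP effects.** Given `delta`, premultiplying by
   `S_delta U^T` with `(S_delta)_ii = (S_i + delta)^{-1/2}` whitens the
   covariance, so generalized least squares becomes ordinary least squares on
   rotated data `(y~, X~)`.  `beta` is then the sparse group lasso estimate

       argmin (1/(2n)) ||y~ - X~ b||^2
              + lambda (1-alpha) sum_G w_G ||b_G||_2
              + lambda alpha ||b||_1

   with SNPs grouped by gene, so the penalty encodes the prior that causal
   SNPs are few and concentrated in few genes.  `alpha = 1` is the lasso,
   `alpha = 0` the group lasso; with the rotation disabled (`rotate=False`,
   identity rotation) the same code path produces the unadjusted lasso/SGL
   baselines, so all four methods differ only in configuration.

## Solver

The objective is minimized blockwise.  A group is set to zero whenever
`||soft(g_G, alpha lambda)||_2 <= (1-alpha) w_G lambda` for the current
negated loss gradient `g`; otherwise the group subproblem is solved by FISTA
with the proximal map "soft-threshold, then group-norm shrinkage".  Because
the subproblem loss is quadratic, the exact Lipschitz constant
(largest eigenvalue of the scaled Gram block) gives the step size directly,
so no backtracking line search is needed.  Convergence requires both a
maximum coefficient change below `tol * max(1, ||b||_inf)` over a full pass
*and* an explicit KKT (subgradient) residual below `kkt_tol`; the double
criterion prevents false convergence along flat directions, and
non-convergence is always flagged on the returned fit.

Two execution modes share the same arithmetic.  When p is moderate
(<= 6000) the Gram matrix `X^T X` is precomputed once per problem and the
gradient is maintained by covariance updates, making the per-sweep cost
independent of the sample count; otherwise (and for the many small,
very sparse fits inside stability resampling) residual updates are used.
Both modes are verified against each other and against an independent
full-vector proximal-gradient implementation in the test suite.

`lambda_max`, the smallest penalty at which `b = 0` is optimal, follows from
the same zero condition: closed forms at `alpha` in {0, 1}, bisection
(1e-10 relative) in between.  The path is geometric over `nlam = 100` values
down to `0.01 * lambda_max`, each fit warm-started from the previous one.

Conventions: the `1/(2n)` loss scaling and `w_G = sqrt(p_G)` group weights
match the standard SGL software; both are configurable
(`scale_loss=False`, unit weights) so the unscaled textbook objective is
also runnable.  Exact ties in the group-zero test keep the group at zero
(conservative sparsity).

## Model selection and SNP ranking

`lambda` is chosen by 5-fold cross-validation on the rotated rows (seeded
shuffle; fold sizes differ by at most one), maximizing mean held-out
explained variance `1 - ||y~_te - X~_te b||^2 / ||y~_te - mean||^2`.

SNPs are then ranked by stability selection: the chosen lambda plus 9 larger
path values at evenly spaced path indices (index spacing = log-lambda
spacing on a geometric path) are refit on 100 random half-samples
(floor(n/2) rows drawn without replacement).  A SNP counts as selected in a
resample iff its coefficient is nonzero at *any* of the 10 lambdas — the
simplest monotone reading of ranking by order of inclusion along the path;
per-resample selection is binary and the score is the selection frequency.
SNPs with frequency >= 0.5 (boundary inclusive) form the selected set.
Frequencies, not the |beta| tie-break used for display ordering, are the
scores used in evaluation.

Cross-validation and resampling reuse the full-data rotation (delta and
eigenvectors estimated once).  Re-estimating the null per subset is
statistically cleaner but would change the estimand mid-procedure; the
single-rotation variant matches the whole-dataset path construction and is
the default.

## Prediction

For new samples with genotypes `X'` on the same SNP panel:

    y'_hat = X' b + K_{X'X} (K_{XX} + delta I)^{-1} (y - X b) + y_mean

Both kinship blocks are built from genotypes standardized with the
*training* per-SNP means and scales and divided by the training marker
count, so no test information leaks into the transform.  The linear system
is solved by a Cholesky-backed solver, never an explicit inverse;
`delta > 0` guarantees invertibility.

## Synthetic data generator

The generator emulates a structured plant association panel:

* **Genotypes.** Balding–Nichols model: per-SNP ancestral frequency
  ~ Uniform(0.1, 0.9); population frequencies Beta-distributed around it
  with differentiation `fst = 0.1`; two populations of equal size.
  Within each gene (contiguous block of 10 SNPs) linkage disequilibrium is
  induced by thresholding two independent latent AR(1) Gaussian haplotypes
  per sample (`ld_rho = 0.5`), which preserves Binomial(2, p) margins while
  correlating neighboring SNPs at realistic within-gene levels.
* **Confounder.** `y_pop = U diag(sqrt(S)) z`, `z ~ N(0, I)` — one draw from
  N(0, K) using the kinship of the simulated panel itself.
* **Phenotype.** `m_active = 3` of the `N_g = 200` groups are chosen
  uniformly; 5 causal SNPs per active group (k = 15) receive effects
  `beta ~ N(0, I)`; with `y_sig = X_causal beta` and `phi ~ N(0, I)`,

      y = s_sig * y_sig + (1 - s_sig) * [ s_pop * y_pop + (1 - s_pop) * phi ]

  Each component is standardized to mean 0 / unit variance before mixing so
  the weights are interpretable as signal fractions (variance bookkeeping
  `Var(y) ~ s_sig^2 + (1-s_sig)^2 [s_pop^2 + (1-s_pop)^2]` is a tested
  invariant); `raw_components=True` mixes the unstandardized draws instead.

Default study conditions: `n = 1130` samples, `p = 2000` SNPs in 200 groups,
`sigma_sig` in {0.1, ..., 0.5}, `sigma_pop` in {0.5, 0.7, 0.9}; the
benchmark grid generates 10 replicate datasets per cell with seeds derived
deterministically from a master seed and the cell coordinates.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data:

* Real within-gene LD of a selfing species can be far stronger than the
  AR(1) latent model; strong LD changes both the reachable recovery ceiling
  and the interpretation of "causal SNP found" (proxy selection).
* The confounder is an exact N(0, K) draw, not an empirical random-effect
  fit to a real phenotype; real confounding is not exactly Gaussian in the
  kinship eigenbasis.
* No genotyping error, no missingness (I/O and QC handle these, but the
  generator emits complete data), one chromosome, equal-size genes.

A practical consequence of `beta ~ N(0, I)`: a sizeable fraction of causal
SNPs receive effects near zero (P(|beta| < 0.2) ~ 0.16) and are statistically
undetectable at n = 1130 regardless of method, and a fixed noise realization
shared by all resamples lets a few null SNPs acquire stable spurious
correlations.  Both effects cap the precision-recall AUC of
frequency-based recovery below 1 even in the strongest-signal setting; the
evaluation module reports whatever the pipeline actually achieves.

## Numerical choices

* Delta grid: 100 points, `ln delta` in [-10, 10], then bounded scalar
  refinement inside the bracketing cell (`xatol = 1e-10`); the refined value
  is never allowed to be worse than the grid incumbent.
* Flat profile (range < 1e-6 over the grid, e.g. K = I): `delta = 1` by
  convention with `flat_likelihood=True` — the ratio is unidentifiable, not
  estimated.
* Eigenvalues in `(-1e-8 * trace/m, 0)` are clamped to 0; anything more
  negative is an error, as is asymmetry beyond 1e-8.
* Standardization uses the sample standard deviation (m - 1); constant
  columns are dropped with a warning and the group structure is rebuilt.
* Missing dosages are mean-imputed per SNP at standardization time only;
  I/O preserves missingness, and QC computes MAF over observed calls.
* QC attribution order MAF -> missingness -> HWE (1-df chi-square
  goodness-of-fit); a SNP failing several filters is counted under the
  first, making the report deterministic.
* Gene buffers: 10 kb both sides, boundaries inclusive, 1-based inclusive
  coordinates; SNPs in several buffered genes go to the nearest gene body
  (ties to the lexicographically smallest gene id); SNPs outside every gene
  become singleton groups, so grouping never changes the design matrix.
* PR-AUC: trapezoid over the achievable curve with the recall = 0 endpoint
  anchored at the first point's precision (not average precision).  The
  anchor gives the estimator a small positive bias at chance level
  (~ +0.002 at 15/2000 prevalence), which the tests bracket rather than
  assume away.  Curves are evaluated only at distinct score values; ties
  share a threshold.

## Problem sizes used in the tests

Unit and property tests run on panels of 20-500 samples and 40-5000 SNPs,
chosen to make every oracle (dense MVN densities, explicit inverses,
brute-force pairwise statistics, exhaustive threshold enumeration)
computable exactly.  The end-to-end acceptance run uses the full default
study conditions (five datasets, n = 1130, p = 2000, 50 resamples x 10
lambdas); the delta-recovery check uses m = 500 with 20 replicates.

## Known limitations

* Non-overlapping groups only; a SNP in two genes' buffers is assigned to
  one of them.  Overlapping-group penalties are out of scope.
* One variance component; no covariates beyond the implicit intercept
  (mean centering).
* Selection frequencies are descriptive: no per-SNP p-values or FDR control
  is attached to the stability output.
* Full eigendecomposition (O(m^3)): designed for panels up to ~10k samples,
  not biobank scale.
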