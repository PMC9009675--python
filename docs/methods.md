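# Methods

This note documents the statistical model, the algorithms, the numerical
choices, and the limits of what the bundled simulations can show.

## The mixed model

Each trait is analyzed separately with

    y = X beta + Z_g a + Z_ge u + e

where `y` stacks the plot observations of a trial with `g` genotypes, `e`
environments and `b` blocks per environment; `beta` holds the fixed
environment and block-within-environment effects (`e*b` parameters); `a ~
N(0, sigma2_g I)` are genotype main effects, `u ~ N(0, sigma2_ge I)`
genotype-by-environment interaction effects, and `e ~ N(0, sigma2_e I)`
residuals. Blocks are treated as fixed. Missing plots are simply absent
rows: the fit uses whatever records exist, with no imputation.

**Design coding.** The fixed design uses an intercept, treatment-coded
environment columns, and block-within-environment *sum-to-zero* contrasts.
The contrast coding matters for one thing only: block columns coded this way
are orthogonal to the environment indicators, so deleting the `e-1`
environment columns is a well-defined rank-`(e-1)` reduction for the
fixed-effect test (treatment-coded block dummies would span the environment
indicators and make that reduction vacuous).

**REML.** Writing `V = sigma2_e * H(gamma)` with `H = I + gamma_g Z_g Z_g' +
gamma_ge Z_ge Z_ge'` and `gamma = (sigma2_g, sigma2_ge)/sigma2_e`, the
residual variance is profiled out analytically and the restricted
log-likelihood is maximized over the non-negative ratios `gamma` with
L-BFGS-B (bounds at zero, two starts) followed by a Nelder-Mead polish;
function tolerance 1e-8 on the log-likelihood, at most 500 quasi-Newton
iterations. Because the ratios are bounded below at zero, boundary
solutions report *exact* zeros rather than tiny positives. All linear
algebra goes through the Woodbury identity, factorizing an `m x m` matrix
(`m = g + g*e`) instead of `n x n`, which keeps Monte-Carlo suites cheap.
On balanced designs the estimates coincide with the expected-mean-squares
ANOVA estimators whenever those are non-negative (verified to 1e-6
relative in the tests); with one environment the interaction ratio is fixed
at zero since `Z_ge = Z_g` there.

Fixed effects are GLS estimates at the optimum; BLUPs are the conditional
means `sigma2_term * Z' V^-1 (y - X beta)`. The grand mean is the fitted
fixed part averaged over the full environment-by-block grid (so block
contrasts drop out and environments weigh equally). A constant response
short-circuits to the degenerate fit (all components zero, BLUPs zero).

**Tests.** Random terms are tested by REML likelihood ratio against the
model without the term, referred to chi-square with 1 df. This matches
common package behavior but is conservative: the correct boundary reference
is a 50:50 mixture of chi2(0) and chi2(1), so true size at nominal 5% is
about 2.5% (the null-calibration test asserts <= 5%). The fixed
environment effect is tested by *maximum-likelihood* ratio with `e-1` df,
because restricted likelihoods are not comparable across fixed structures.

## Genetic parameters

From the variance components, with trait grand mean `mu`:

- broad-sense (plot-basis) heritability `vg / (vg + vge + ve)`;
- mean-basis heritability `vg / (vg + vge/e + ve/(e*b))` — the headline
  variant, whose square root is reported as selection accuracy (published
  accuracies in this literature reproduce as the square root of the printed
  heritability);
- genotype-environment correlation `rge = vg / (vg + vge)` by default; the
  alternative `vge / (vge + ve)` sits behind `rge_variant="interaction"`
  because reported tables in this literature do not always disambiguate the
  two;
- `CVg = 100*sqrt(vg)/mu`, `CVr = 100*sqrt(ve)/mu`, and their ratio (ratio
  above 1: genetic signal exceeds residual noise).

All are invariant to positive rescaling of the trait. `mu` is the grand
mean over both environments; a zero grand mean makes the CVs undefined and
raises.

## The genotype-ideotype distance index

Input is the genotype x trait matrix of BLUP-based predicted means across
both environments (selection "simultaneously for control and drought"); a
per-environment run is possible by passing any other mean matrix.

1. *Rescaling.* Each column is mapped affinely onto [0, 100] with 100 at
   the desirable extreme: `(min, max) -> (0, 100)` for increase-sense
   traits, `(min, max) -> (100, 0)` for decrease-sense traits (sodium and
   stomatal conductance in the wheat preset). Affine maps preserve the
   correlation structure up to sign. A constant column is an error —
   upstream callers (pipeline, CLI) exclude traits whose genotypic variance
   hit the zero boundary, since a constant predicted-mean column carries no
   selection signal.
2. *Factor analysis.* Eigen-decomposition of the correlation matrix `R` of
   the rescaled matrix; factors with eigenvalue strictly greater than 1 are
   retained (Kaiser criterion; minimum one factor). Initial loadings are
   eigenvectors scaled by the square root of their eigenvalues; retained
   loadings are varimax-rotated (raw criterion, no Kaiser row
   normalization; `rotate=False` gives the unrotated solution). Each
   factor's sign is fixed so its largest-magnitude loading is positive.
   Scores follow `F = Z (A' R^-1)'` on the column-standardized (ddof=1)
   rescaled matrix; a numerically singular `R` (condition number > 1e12) is
   pseudo-inverted with a warning.
3. *Ideotype.* The vector `[100, ..., 100]` is standardized with the
   genotype columns' means and standard deviations and scored with the same
   `A` and `R`, so it lives in the same score space.
4. *Index.* `MGIDI_i = sqrt( sum_j (F_ij - F_ideotype_j)^2 )` — the
   Euclidean norm over factors, i.e. the root of the sum, not a sum of
   roots. Per-factor shares `omega_ij = D_ij^2 / sum_j D_ij^2` decompose
   each genotype's distance; the *smallest* share marks the factor whose
   traits are closest to ideal for that genotype. A genotype exactly at
   the ideotype has distance 0 and its (undefined) shares are reported as
   zeros.

Selection takes the `floor(p * g)` lowest-index genotypes (at least one;
ties broken by genotype id, so selection is deterministic); the default
proportion 0.25 gives 4 of 18. Selection differentials per trait are
`Xs - Xo` (selected mean minus overall mean, original scale) and `SD% =
100 * SD / Xo`, with a goal-met flag comparing the sign of SD with the
trait's desired sense.

## Exploration layer

Pearson correlations of the (genotype, environment) BLUP matrix carry
two-sided p-values from the `t` reference with `n-2` df; no
multiple-testing correction is applied (significance flags at 5% and 1%
mirror the conventional annotation). PCA diagonalizes the correlation
(standardized, default) or covariance matrix; per-variable contributions
are squared loadings (100 per component), and the "contribution to total
variation" summary weights the first two components by their eigenvalues —
the quantity biplot packages display.

## The synthetic trial generator

The generator draws from exactly the model the fitter assumes:
`y_tijk = mu_t + tau_tj + rho_jk + alpha_ti + ge_tij + eps_tijk`, with
genotype effect vectors correlated across traits via a genetic correlation
matrix `K` (lower-triangular square root; Cholesky when positive definite,
eigen square root with clipped negatives otherwise) and interaction and
residual effects independent per trait. Each (trait, term) pair has its
own seeded substream, so appending a trait never perturbs existing draws.

The wheat-drought preset fixes the study conditions: 18 genotypes, control
and drought environments, 3 blocks, 12 traits. Per-trait grand means come
from the trial's published overall means; `vg` and `ve` are backed out of
the published CVg% and CVr%; `vge` is solved from the published mean-basis
heritability at `e=2, b=3`. Drought shifts are centered fixed environment
effects sized from the published response ranges (yield about -20%,
stomatal conductance -40 to -45%, proline +130% of its mean, antioxidants
+10-15%); block gradients are 0.3 residual sd. The genetic correlation is
block-structured over the four published trait groups (0.6 within, 0.1
between). These values were fixed once from the published summaries and
are not tuning knobs.

What the generator does *not* emulate: spatial field trends, multi-year
effects, non-Gaussian or multiplicative noise, dominance/epistasis, and
cross-trait correlation of the interaction effects (only genotype main
effects carry `K` — the simplest structure consistent with the univariate
fits). One visible consequence: a trait with a very large genotypic CV
(proline, CVg ~57%) can dip below zero under the control environment,
which a real concentration cannot; the additive Gaussian model has no
mean-variance coupling. Passing tests therefore certify the estimation
machinery under the assumed model, not robustness to real-data pathologies.

## Problem sizes and tolerances in the test suite

Monte-Carlo suites use 200 replicate trials for variance-component
recovery at `g=18, e=2, b=3` (mean estimate within 15% of truth), 500
replicates for null calibration of the interaction LRT, and 100 replicates
for planted-ideotype recovery — sizes at which the Monte-Carlo error is
comfortably below the asserted tolerances while the whole suite stays in
the minutes range. Oracle comparisons are exact-arithmetic where the
quantity is exact (selection differentials, score products at 1e-10) and
1e-5..1e-6 relative where an optimizer is involved.

## Known limitations

- The likelihood surface is optimized over two ratios; with two free
  ratios and pathological data multiple local optima are conceivable. Two
  starts plus a simplex polish have been sufficient in all suites, but the
  fitter will not detect a missed global optimum.
- The chi-square(1) reference for variance-component LRTs is conservative
  (see above); callers wanting the boundary-mixture p-value can halve it.
- `rge` definitions differ across the literature; both variants are
  exposed and the default is declared, but published tables cannot always
  be reproduced without knowing which was used.
- The factor-analysis step is principal-component extraction with varimax,
  not maximum-likelihood factor analysis; with few genotypes (18) the
  loading pattern is sampling-noisy, and the retained-factor count can
  change between simulated replicates.
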