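# Methods

## Scope and model

`qgtrial` analyzes balanced randomized-complete-block (RCBD) variety trials
in which G genotypes are each observed once in every one of r complete
blocks, for T traits per plot. The observational model is

    y_ijt = mu_t + g_it + b_jt + e_ijt

with genotype effects `g_i` (a T-vector per genotype) drawn from a zero-mean
multivariate normal with covariance `Sigma_g`, block effects
`b_jt ~ N(0, sigma2_b * sigma2_e_t)`, and independent plot errors
`e_ijt ~ N(0, sigma2_e_t)`. Everything downstream is method-of-moments
estimation under this design's expected-mean-squares algebra — no REML, no
mixed models, no multi-environment terms.

## Variance components and genetic parameters

Per trait, a two-way fixed-layout ANOVA partitions
`SS_total = SS_genotype + SS_block + SS_error` with degrees of freedom
G−1, r−1 and (G−1)(r−1). From `E[MS_G] = sigma2_e + r*sigma2_g`:

    sigma2_e = MS_E
    sigma2_g = (MS_G − MS_E)/r     (truncated at 0; raw value retained)
    sigma2_p = sigma2_g + sigma2_e  (exact identity by construction)

Negative `sigma2_g` estimates are a known small-sample artifact of the
moments estimator; truncation prevents imaginary coefficients of variation
downstream while the raw value and a `W-NEGVAR` warning preserve the
diagnostic. Blocks are treated as a fixed stratum, the classical RCBD
convention consistent with this algebra. Missing cells are an error, never
imputed: the design contract is balance.

Derived parameters: `GCV = 100*sigma_g/mean`, `PCV = 100*sigma_p/mean`,
broad-sense heritability `h2b = sigma2_g/sigma2_p` classed low (<0.50),
medium (0.50–0.80, closed interval — the conventional "50–80%" phrasing is
boundary-ambiguous, so both endpoints are assigned to medium), and genetic
advance `GA = K*h2b*sigma_p` with `K = 2.06`, the standardized selection
differential at 5% selection intensity. GA uses the unrounded heritability
and phenotypic standard deviation; feeding it rounded intermediates loses
the third decimal. Trait means always come from the data (or the simulation
config), never from a published summary table, because printed GCV and
GA%-of-mean rows in this literature frequently imply mutually inconsistent
means.

## Genotypic and phenotypic correlations

The estimator is the analysis-of-covariance companion of the variance
decomposition. Per stratum, the mean cross-product of traits x and y comes
from the sum-trait identity `MCP(x,y) = [MS(x+y) − MS(x) − MS(y)]/2`
(implemented for trait pairs; the matrix route computes the identical
bilinear forms directly and the tests assert agreement). Then
`cov_g = (MCP_G − MCP_E)/r`, `cov_e = MCP_E`, `cov_p = cov_g + cov_e`, and

    rg = cov_g / sqrt(s2g_x * s2g_y),   rp = cov_p / sqrt(s2p_x * s2p_y).

Method-of-moments ratios can exceed |1|; such entries are clamped to ±1 and
flagged (`W-CLAMP`) with pre-clamp values retained — clamping never changes
sign. Traits with a non-positive genotypic variance estimate get a missing
rg row rather than a fabricated one. Significance is offered for rp only
(t approximation, G−2 df); rg has no agreed small-sample distribution and
is reported without stars.

## Path analysis

Direct effects P of predictor traits on a response solve `R P = r` exactly,
where R is the predictors' genotypic correlation matrix and r their
correlations with the response. Indirect effect of i via j is `R[i,j]*P[j]`;
the rows therefore reconstruct r to solver precision (asserted at 1e-10).
The residual effect is `sqrt(1 − P·r)`.

The solve is deliberately unregularized. With a near-collinear predictor
block (here moisture / carbohydrates / calories, pairwise |rg| ≈ 1 by the
compositional arithmetic below) the inverse inflates the direct effects to
magnitudes far beyond 1 — that inflation is the result, not a numerical
accident, so the package surfaces a `W-COLLIN` warning when the condition
number exceeds 1e3 (configurable) instead of damping it. When
ill-conditioning drives `P·r` above 1, the residual is reported as 0 with
the raw value retained and flagged. Exactly singular systems (rank deficient
at 1e-12 relative) are rejected with the null-space direction named, since
direct effects are then non-identifiable.

## Multivariate structure

PCA eigendecomposes the correlation matrix of per-genotype trait means
(standardization divisor n−1), so eigenvalues sum to the number of traits;
loading vectors are sign-fixed so each one's largest-magnitude entry is
positive. Clustering is Lloyd's algorithm from k-means++ starts, best of
`n_restarts` (default 10) by the within-cluster sum-of-squares objective J;
the objective is checked for monotone non-increase at every iteration and an
empty cluster is repaired by reseeding its centroid at the point farthest
from its current centroid. Euclidean distance throughout. Silhouette widths
use `S_i = (b_i − a_i)/max(a_i, b_i)` with the singleton-cluster convention
`S_i = 0`. For the reproduction report k defaults to 8 clusters; the source
material describes both 7 and 8 groups for the same panel, a contradiction
we surface here rather than resolve.

## Derived compositional traits

Carbohydrate is obtained by difference, `100 − (ash + moisture + fat +
fiber + protein)`; energy by Atwater factors `4*protein + 9*fat + 4*carb`
(kcal per 100 g — the per-100 g basis is the field convention, reported as
such); protein from Kjeldahl nitrogen as `N × 6.25`; color difference as the
Euclidean ΔE*ab in CIE 1976 L*a*b*; DPPH inhibition as
`100*(A_t0 − A_t30)/A_t0` at 517 nm. Physically implausible results
(negative carbohydrate, protein above 100%, negative inhibition) raise
`W-QC` flags rather than exceptions so batch QC proceeds.

## The synthetic-trial generator

The default configuration (`table1_like_config`) emulates a 64-genotype ×
3-block panel with 15 nutritional traits whose per-trait genotypic and error
variances follow the published ANOVA table for such a panel; the four error
variances printed as 0 (rounded) are floored at 1e-4 to keep the error
stratum nondegenerate. Trait means are the values implied by the published
GA and GA%-of-mean pairs. The genotypic correlation structure sets every
published pairwise value exactly (the −1 moisture–carbohydrate correlation
clipped to −0.99) and fills unpublished pairs with values chosen for
internal consistency — the near-collinear trio forces
`corr(x, carbohydrates) ≈ −corr(x, moisture)` for every other trait — so the
matrix is PSD as specified and the safety-net projection (eigenvalue
clipping + diagonal rescaling) is a no-op on the defaults. Block variance
defaults to 0.1 × the trait's error variance: block effects are rarely
published, and a small nonzero value exercises the block stratum without
dominating. Errors are independent across traits (no published error
covariances) and values are not truncated to physical ranges, since
truncation would bias the variance-recovery checks.

What the generator does not emulate: genotype-by-year or
genotype-by-environment structure (single environment only), selfing or
generation structure, non-normal trait distributions, and measurement
error correlated across traits. Passing recovery tests therefore
demonstrate estimator correctness under the stated model, not robustness to
those real-data features.

## Problem sizes and numerical choices

The test suite simulates at the panel's own scale (G=64, r=3) with 100–200
replicate trials for recovery checks and 1,000 random ≤5×3 tables against
the brute-force ANOVA oracle; the whole suite runs in well under a minute.
PSD tolerance for covariance inputs is 1e-8 (relative to the largest
eigenvalue); singularity rejection at 1e-12 relative; sums of squares agree
with oracles at 1e-9 relative. Constant data give F = 0 with p = 1 by
convention. Seeds are explicit everywhere randomness exists; identical
seeds give bit-identical tables and cluster assignments.

## Known limitations

- Moments estimators only; no shrinkage, no standard errors for rg or for
  path coefficients.
- Heritability here is broad-sense on a genotype-mean basis implied by the
  RCBD algebra; narrow-sense or realized heritability is out of scope.
- The k in k-means is user-chosen; no gap statistic or model selection.
- Correlation clamping is a reporting convention, not a PSD repair of the
  whole rg matrix; downstream path solves use the clamped entries.
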