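# Methods

## The gene-level statistic

For one gene with n SNPs tested against m phenotypes, the inputs are
the m × n univariate association P-values (Wald test from linear
regression for continuous phenotypes; 1-df likelihood-ratio χ² from
logistic regression for binary ones). Ordering the present P-values
ascendingly, the gene-level P-value is the minimum weighted P-value

    P_gene = min_j q_e · p₍j₎ / q_ej ,  capped at 1,

with q_ej the effective number of independent tests among the top j,
computed from the eigenvalues of the j × j submatrix of the expected
test correlation matrix Φ: q_ej = j − Σ(λᵢ − 1) over eigenvalues above
1. Independent tests give q_ej = j (the weighted minimum is then the
classical Simes statistic); perfectly correlated tests give q_ej = 1.
Because every weight q_e/q_ej is at least 1, the scan over j can stop
as soon as the running minimum is ≤ the next ordered P-value; this
early stop is exact, not an approximation (verified against the full
scan in the test suite). For the same reason, whether P_gene ≤ α can be
decided by examining only ranks whose raw P-value is ≤ α — the
simulation harness uses this exact shortcut when only rejection counts
are needed.

Numerical guards: eigenvalues within 1e-10 of 1 count as ≤ 1;
q_ej is floored at 1 and weights at 1 (Φ is produced by a polynomial
map and can be slightly non-positive-definite, see below); ties among
P-values are broken by the phenotype-major test index with a stable
sort, making results platform-independent; P-values of exactly 0
(upstream underflow) are floored at 1e-300 with a warning; missing
tests (a SNP present for some phenotypes only) are dropped test-wise
together with their Φ rows/columns — no imputation.

## The P-value correlation model

Φ is approximated elementwise from the phenotype correlation matrix Σ
and the SNP LD matrix Ω as f(Σ ⊗ Ω), where f is a fixed sixth-order
polynomial (coefficients in `mgas.corr_model.PVALUE_CORR_COEFFS`)
calibrated on null simulations of two correlated SNPs × two correlated
phenotypes. The test index is phenotype-major (t = p·n + s) throughout
the package. Three deliberate choices:

* f(1) = 0.9781 ≠ 1, so the diagonal of Φ is reset to exactly 1;
  off-diagonals are left as the polynomial produced them (the
  polynomial was fitted as is — renormalising would bias it).
* The map is applied to signed products; no absolute value is taken
  (the polynomial is even-dominated, |f(x) − f(−x)| ≤ 0.003).
* Outputs are clamped to [0, 1]: correlations of null P-values are
  nonnegative in the calibration study, and the clamp removes the tiny
  negative dip of the raw polynomial near 0.
* Φ is not repaired to positive semi-definiteness: the effective-number
  sum only uses eigenvalues above 1 and ignores negative ones, and the
  floors above absorb the residual noise.

### Calibration replication

`mgas.calibration` re-derives the polynomial's target quantity: for a
grid of phenotype correlations ρ and LD values r, it simulates N
subjects per replicate (two SNPs by haplotype-pair sampling under
Hardy–Weinberg, two phenotypes from a bivariate normal, or a bivariate
Bernoulli via a Gaussian copula with the tetrachoric transform for the
binary case), runs the four univariate tests, and estimates the Pearson
correlation of the two *cross* P-values, whose dependence is governed
by the product x = ρ·r. Desk-scale defaults: grid ρ, r ∈ {0, 0.1, …,
1.0} (endpoints included — the endpoint cells double as exact
self-checks), 2000 replicates per cell, N = 4000, MAF 0.3; full-scale
settings (step 0.05, 10 000 replicates) are available through the
function arguments and the `mgas calibrate` CLI. Validation reports
R² = 1 − SS_res/SS_tot of the frozen polynomial against the fresh
estimates; the coefficients are never refit into the package constant.
Logistic fits for the binary grid use a Newton solver batched across
replicates; the scalar `chi2_logistic` falls back to the score test
under separation, with a warning.

Two measured facts worth knowing: (i) at ρ = r = 1 the two cross tests
are identical, so the empirical correlation is exactly 1 while the
polynomial's endpoint is 0.9781 — a small, known endpoint error of the
fitted curve; (ii) the estimator's Monte-Carlo noise (SD ≈ 0.017 at
2000 replicates) is what bounds the reduced-scale R² near 0.985–0.99.

## Divide and conquer

For genes where m·n exceeds a threshold (default 500), the tests are
clustered by single linkage on Φ at a cutoff of 0.50 (implemented as
connected components of the thresholded graph, relabelled by first
appearance — deterministic). Each block is combined by the extended
Simes test on its Φ submatrix; the test attaining the block minimum is
the block's key test; the block P-values are then combined by a second
extended Simes pass using the Φ submatrix of the key tests. The
reported q_e in this mode is the sum of blockwise effective numbers
(the full-matrix eigendecomposition is exactly what the algorithm
avoids). On random small instances with realistic structure the
blockwise result stays within |Δlog₁₀P| ≤ 0.2 of the exact statistic
(asserted in the suite; this tolerance is this package's own
calibration of the approximation, measured, not a published property).

## Comparator gene tests

* `gates_sum`: phenotypes summed to one score, one Wald test per SNP,
  combined by the univariate (m = 1) special case of the statistic.
* `multiple_regression_gene`: the sum score on all SNPs jointly,
  overall F-test; aliased dosage columns are dropped by pivoted-QR rank
  detection (with a warning), reducing the numerator df accordingly.
* `manova_gene`: all phenotypes on all SNPs; Wilks' Λ from the
  residual/hypothesis SSCP matrices, mapped to F by Rao's approximation
  (exact for one response or one predictor; cross-checked against
  statsmodels' MANOVA in the suite). Wilks was chosen among the MANOVA
  statistics as the standard likelihood-ratio-based one. MANOVA
  requires continuous phenotypes and N > m + n. Under the settings used
  here (unrelated subjects, no covariates, additive coding) MANOVA is
  equivalent to canonical correlation analysis.
* `gates_manova`: one single-SNP MANOVA per SNP, P-values combined by
  the univariate combination with Ω.

Covariates are handled by residualising phenotypes before testing
(`genescan.phenotype_corr` residualises by least squares and correlates
the residuals); the same residualisation must underlie the univariate
scans and the Σ supplied to the gene test.

## Synthetic data generator

The generator reproduces the simulation study conditions the method was
evaluated under; its defaults are those conditions, not tuning knobs.

*Genotypes.* A gene is 10 SNPs (small) or 60 SNPs (large), MAF 0.2,
arranged in LD blocks with haplotypic r = 0.9 within and 0 between
blocks. Within a block, haplotype alleles are exchangeable
equicorrelated Bernoulli draws: allele j copies a block-shared draw
with probability √r and a private draw otherwise. This reproduces the
two-SNP haplotype frequencies implied by (MAF, r) exactly for every
pair in the block and extends them blockwise; dosages are sums of two
independent haplotypes, so genotypic correlations equal the haplotypic
r. Joint higher-order haplotype structure beyond pairwise is a modelling
choice (no published map exists for it). The large gene uses 8 blocks
of sizes 8,8,8,8,7,7,7,7 — the reference block layout is not published
in detail, so an even split is used and documented here.

*Phenotypes.* Twenty standard-normal phenotypes under six models.
Factor models use equal loadings √0.56, giving within-factor
correlations 0.56; the 4-factor model correlates factors at
0.13/0.56 ≈ 0.232 so between-cluster phenotype correlations are 0.13.
(The loadings are a reconstruction from the stated correlation targets,
not published values.) Network models are linear structural systems
y = Wy + ε with equal within-/between-cluster edge weights; W and the
innovation variance are solved in closed form by matching the
eigenvalues of the stationary covariance (I−W)⁻¹dI(I−W)⁻ᵀ to the
target correlation structure — the solution is exact (machine
precision), e.g. w = 0.0420, d = 0.4777 for the unclustered network.

*Causal effects.* Each disease-susceptibility locus (DSL) enters with
weight ±√v on the standardised dosage, v = 0.005 (small gene) or 0.01
(large gene). "Variance explained" is defined at the point of
injection — the latent factor, the phenotype, or the network innovation
— before propagation through loadings or the network; the directly
affected variable's residual is rescaled so its model variance stays 1.
With several DSL in LD the marginal per-DSL R² exceeds v through the
cross terms (the LD augmentation effect; asserted in the suite), so
power is comparable within, not across, scenarios. Opposite-effect
variants follow the scenario table: with several DSL, half the weights
are negated; with a single DSL, latent-factor models split the factor's
indicators into positively and negatively affected halves, and
direct/network models hit two phenotypes with opposite signs — by
convention the first phenotype of the target cluster and either its
neighbour (same cluster) or the first phenotype of the next cluster.
The affected-phenotype identities in the opposite-effect variants are
conventions; no published assignment exists.

*Experiment harness.* `run_scenario` draws fresh data per replicate,
estimates Σ and Ω empirically from that replicate (matching analysis
practice), and reports rejection rates with binomial standard errors
for any subset of the five methods.

## What the tests do and do not show

The simulations use exchangeable within-block LD, exact
Hardy–Weinberg, equal MAF, equal loadings and Gaussian phenotypes. Real
data have heterogeneous LD decay, allele-frequency spectra, non-normal
phenotypes and population structure; passing tests demonstrate
correctness of the implementation under the stated generating models,
not robustness to those complications (the procedure inherits whatever
robustness the upstream univariate tests have).

A measured property of weighted-Simes statistics worth stating plainly:
under strong dependence (e.g. within-block LD 0.9 and phenotype
correlations 0.56) the *mid-range* of the null gene-level P-value
distribution deviates from uniform (KS D ≈ 0.1–0.3 at 2000 replicates,
for the univariate combination as much as the multivariate one), while
the *tail* — the part that decides significance — stays calibrated
(empirical type-I 0.043–0.057 at α = 0.05 and ≈ 0.010–0.013 at
α = 0.01 across the suite's scenarios). The suite therefore asserts
full-distribution uniformity where it is theoretically expected (mild
dependence, ρ = r = 0.2) and tail calibration at the strong-dependence
scenario conditions. Exact comparator tests (overall F, Wilks) are
uniform everywhere.

## Problem sizes

Desk-scale defaults used by the suite and the acceptance script: 10 000
replicates for the α = 0.01 type-I estimate (N = 2000 each), 2000
replicates per cell on an 11 × 11 calibration grid (N = 4000), 2000
replicates for power orderings and the per-method type-I checks, and
N = 20 000 for generator moment checks. These sizes give binomial /
Monte-Carlo errors comfortably inside the asserted tolerances.

## Known limitations

* The polynomial correlation model is an approximation; its endpoint
  f(1) ≠ 1 and small mid-range biases propagate into mild conservatism
  or liberalism of the combined P-value far from the tail (see above).
* Φ's clamping to [0, 1] discards (rare, tiny) negative dependence.
* The divide-and-conquer combination is an approximation with a
  measured, not proven, error bound.
* Summary statistics from non-overlapping samples violate the
  correlation model and are not supported; LD from a reference panel
  that mismatches the study sample makes the test liberal or
  conservative.
* MANOVA-path comparators refuse binary phenotypes; the main
  combination accepts them through the logistic univariate engine.
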