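# Methods

## Model

`pathblup` analyses replicated phenotypes on a panel of inbred lines with the
genomic linear mixed model

    y = X b + Z g + e,      g ~ N(0, G sigma_g^2),   e ~ N(0, I sigma_e^2),

where `y` stacks all observations, `X` holds the fixed covariates (intercept,
*Wolbachia* infection status, five polymorphic-inversion factors, experimental
block), `Z` is the observation-to-line incidence and `g` is the vector of
line-level genomic values.  The genomic relationship matrix is
`G = W W' / m` with `w_i = (a_i - 2 p_i) / sqrt(2 p_i (1 - p_i))` per marker,
`a_i` the minor-allele count column and `p_i` its sample minor allele
frequency.  SNP heritability is `h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)`.

On fully inbred lines the allele count is twice a Bernoulli draw, so the
`2p(1-p)` denominator leaves column variances near 2 and `diag(G) ~ 2`.  We
keep this scaling as the default because it is the printed definition;
`scale_genotypes(empirical=True)` provides unit-variance columns for
sensitivity analysis.  The consequence that matters is the *scale* of
`sigma_g^2`: it is the coefficient on `G`, not the sample variance of `g`
(which is about twice as large on inbred data).  Everything in the package —
simulation ground truth, estimation and tests — uses the `G`-scale
consistently (see "Synthetic data" below).

## REML estimation

The restricted likelihood is profiled on the variance ratio
`lambda = sigma_g^2 / sigma_e^2`.  With the eigendecomposition
`Z G Z' = U diag(d) U'`, the rotated model is heteroscedastic ordinary
regression with weights `lambda d + 1`, giving a closed-form profiled
`sigma_e^2` and a one-dimensional criterion in `lambda`.  The optimiser scans
`lambda = 0` plus 141 log-spaced points on [1e-6, 1e8] and refines the best
bracket by bounded scalar minimisation (xatol 1e-10 in log-lambda).
Non-negativity is enforced by the parametrisation, so boundary estimates
(`sigma_g^2 = 0`) are reported as such rather than clipped.

Degeneracies are handled explicitly: collinear fixed-effect columns are pruned
by pivoted QR (logged); when `Z G Z'` is proportional to the identity (e.g.
`G = I` with one observation per line) only the sum of the two components is
identified, and the fit warns and flags `identifiable=False`.

`reml_loglik` evaluates the same criterion (`-1/2 [log|V| + log|X'V^-1 X| +
r'V^-1 r]`, constants dropped) directly by Cholesky factorisation.
`grid_search_reml` brute-forces that function on a 100 x 100
`(sigma_g^2, sigma_e^2)` lattice over `[0, 3 var(y)]`, zooming twice around
the argmax; because it shares no code path with the profiled optimiser it
serves as an independent audit, and the test suite requires the optimiser to
dominate the lattice and to match its argmax heritability to 1e-3.

Bootstrap confidence intervals for `h2` resample observations with
replacement (10,000 replicates by default; smaller counts in the bundled
suites, stated per call), rebuild the line incidence per replicate, and take
the 2.5%/97.5% nearest-observation quantiles.  A line-mean resampling mode is
available behind a flag.  Genomic correlations between traits are Spearman
rank correlations of the line BLUPs on shared lines.

## Marker effects and the rotation SNP-set test

Per-marker effects are back-solved from the line BLUPs as the minimum-norm
solution `s_hat = W'(W W')^+ g_hat`.  Because `g_hat` is constructed as
`G Z' V^-1` times a residual, it lies in the column space of `W` and the
reconstruction `W s_hat = g_hat` is exact to numerical precision; the relative
residual is recorded on every result.

Markers (and hence effects) are ordered along the concatenated chromosome
arms 2L, 2R, 3L, 3R, X, 4 (configurable; any fixed order is valid).  A
SNP-set is the deduplicated union of markers within 5 kb (inclusive at the
boundary) of the genes annotated to one GO term; sets are retained when they
have more than ten genes and at least 200 markers.  The set statistic is the
signed sum `T_sum` of its marker effects.

The null distribution rotates the genome-ordered effect vector to a uniformly
drawn start marker `j` (identity allowed) while holding the set-to-index map
fixed.  Rotation preserves the multiset of effects and every cyclic adjacency
— hence the local LD-induced correlation of effects — while breaking set
membership.  All sets are evaluated against the same rotations, so the joint
pattern of sub-threshold sets across traits remains meaningful for the
overlap test.  The default p-value is the add-one estimate
`(r + 1)/(B + 1)` with `r` the count of rotations with `T >= T_obs`, which is
a valid p-value under exchangeability and never exactly zero; the raw strict
proportion `#{T > T_obs}/B` is available as `p_mode="strict"`.  A two-sided
`|T|` variant exists behind a flag but is off by default, because the signed
one-tailed sum is the statistic of record.  Note its known blind spot: within
a causal set, effects of opposite sign cancel, so per-set power is modest for
dense bidirectional architectures; the cross-trait overlap analysis is the
intended complement.

## Cross-trait overlap

Per GO class, an incidence matrix marks sets with empirical `p < 0.05`
(strict) per trait.  Each of 10,000 permutation rounds independently shuffles
every column (margins fixed) and records pairwise overlaps; the one-tailed p
is the fraction of rounds with overlap at least the observed count.  Under
independence that distribution is exactly hypergeometric, which the test
suite uses as an oracle (agreement within 0.01 at 10,000 permutations, on
configurations whose exact tail is below 0.1 so that the Monte-Carlo standard
error is well inside the bound).  Analytic expectations `n_sets * alpha`
(false positives per trait) and `n_sets * alpha^2` (pairwise overlap) are
reported unrounded and rounded half-away-from-zero.

## Per-gene variance partitioning

Within an associated set, each member gene's per-line genetic value is
`f_gene = W[:, markers(gene) ∩ markers(set)] s_hat[...]`; when the genes
partition the set's markers these vectors sum exactly to the set-level
vector.  The per-gene measure is `VarF = Var(f_gene) / m_gene` (sample
variance across lines, n-1 denominator; the choice cancels in shares),
normalised to shares within the set.  Shares are invariant to rescaling all
marker effects and sum to one; genes with share strictly above 20% are
flagged as dominant contributors.  Markers shared by two member genes count
toward both genes' vectors, so the additivity identity is asserted only on
partitions.

## Synthetic data

The generator emulates a small inbred reference panel:

- **Genotypes.** 30 lines x 3,000 markers by default (500 per arm, 500 bp
  spacing), fully inbred ({0,2}; a `het_rate` option introduces residual
  heterozygous calls).  LD comes from two-haplotype block copying: within
  each block of 10 consecutive markers, every line copies one of two ancestral
  haplotypes with a 1% per-call mutation rate, giving strong within-block and
  negligible between-block correlation.  Per-marker sample MAF is constrained
  to (0.05, 0.5] by construction (out-of-range columns are repaired), and
  markers are coded on the sample minor allele.
- **Annotation.** 120 genes of 2 kb at 10 kb pitch, allocated to arms
  proportionally to arm length; 30 BP / 12 MF / 8 CC GO sets of 11-25 genes
  drawn without replacement within a set.
- **Traits.** Marker effects are iid N(0,1) on the causal markers (the union
  of markers within 5 kb of the causal sets' genes, or all markers for a
  polygenic trait) and zero elsewhere; `g = W s` exactly, with the same `W`
  the estimator uses.  The realised genetic variance on the `G` scale is
  `sigma_g^2* = g' G^+ g / rank(G)` and the residual variance is set to
  `sigma_g^2* (1 - h2)/h2`, so the realised heritability equals the target
  exactly and is directly comparable to the REML estimate.  Fixed effects:
  Wolbachia ~ Bernoulli(0.5) x 0.25, five Bernoulli(0.5) inversions x 0.15
  with alternating signs, three experimental blocks (round-robin over the
  five replicates per line) x 0.2.

What the generator does **not** emulate: coalescent-realistic LD decay and
recombination maps, allele-frequency spectra, genotype errors or missingness,
overlapping gene models, GO term nesting, or selection-induced
genotype-covariate correlation.  Passing tests therefore demonstrate
correctness of the estimators and permutation machinery under the stated
model, not robustness to every property of real panel data.

## Problem sizes in the bundled suites

The statistical suites run at sizes chosen to give stable Monte-Carlo
margins while keeping the default test run quick: heritability recovery uses
50 panels per level (30 lines, 3,000 markers, 5 replicates); the REML audit
uses five fixtures with at most 60 observations; rotation calibration uses
10,000 markers, 500 sets and 1,000 rotations; power uses 50 panels at 400
rotations; the overlap oracle uses 20 margin configurations at 10,000
permutations.  `scripts/acceptance.py` recomputes all of these from scratch
with seeds derived from `--seed` and prints each measured value.

## Known limitations

- Single-trait REML only; no dominance or epistatic relationship matrices.
- The rotation test conditions on marker order and set definitions; it does
  not model gene-length or LD-score covariates beyond what rotation
  preserves.
- The bootstrap treats observations as exchangeable across lines; with very
  few lines the interval can be optimistic (the empirical coverage is not
  calibrated here).
- p-values from 10,000-rotation runs are bounded below by ~1e-4; strict-mode
  p can be exactly 0 and is kept only for fidelity to the printed rule.
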