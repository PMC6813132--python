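# Methods

## The model

One SNP-CpG pair is analysed at a time.  Methylation is modelled at the
allele level: allele *l* of individual *i* contributes
`y_il ~ Bin(r_il, pi_il)` with

    logit(pi_il) = mu + x_il beta + g_i + u_i + e_il,

`x_il ∈ {0,1}` the allele genotype.  `g ~ MVN(0, sigma_g^2 K)` captures
polygenic background and relatedness (K standardized so its mean
diagonal is 1, repaired to PSD by clipping negative eigenvalues at 0);
`u_i ~ N(0, sigma_u^2)` is an individual-level environmental effect
shared between alleles; `e_il ~ N(0, sigma_e^2)` is an allele-level
residual.  A single `beta` is shared by the allele contrast within
heterozygotes and the dosage contrast across individuals (the equal
effect-size assumption appropriate for nearby *cis* variants; it can
fail under imprinting, where the allele contrast shrinks).

Background heritability is defined as
`h2 = sigma_g^2 / (sigma_g^2 + sigma_u^2 + sigma_e^2/2)` — the `1/2`
because the individual-level latent mean averages two independent
allele residuals.

### Homozygote collapse

For homozygotes only `y_i = y_i1 + y_i2`, `r_i = r_i1 + r_i2` are
observed.  Assuming reads split between alleles as `r_i1 ~ Bin(r_i, 1/2)`,
the exact collapsed distribution is a double sum over the unobserved
split (`exact_homozygote_pmf`, O(r^2), guarded at r <= 10,000).
Conditional on the two allele probabilities, `Bin(r_i, (pi_i1+pi_i2)/2)`
reproduces the exact distribution's mean and variance *exactly* (shown
analytically; the package's tests verify it to rounding and against a
10^6-replicate Monte-Carlo of the allele-level model).  The model
therefore represents each homozygote by one binomial row with covariate
`genotype/2` and residual variance `sigma_e^2/2`, i.e. replacing the
average of the two allele probabilities by the logistic of the averaged
linear predictor.  That last step is first-order: its marginal variance
error grows with `sigma_e^2` and with distance of the methylation level
from 1/2 (~10% at sigma_e^2 = 0.7), which is one reason the collapsed
likelihood is an approximation rather than exact.

Heterozygotes whose reads cannot be assigned to alleles are collapsed
the same way with covariate 0.5 (flagged per pair in the output).

### Estimators

* `joint` — allele rows for phase-assignable heterozygotes plus
  collapsed rows for homozygotes;
* `ind` — collapsed rows for everyone (classical count-based mQTL
  mapping with relatedness);
* `allele` — heterozygote allele rows only (pure ASM; refuses to run
  with fewer than 5 phase-assignable heterozygotes);
* `bb` — per-site beta-binomial ML regression on individual-level
  counts, intra-class over-dispersion on (0,1), observed-information
  Wald test, falling back to a binomial GLM when the over-dispersion
  collapses to the boundary;
* `lmm` — REML kinship linear mixed model on M-values
  (`log2((y+c)/(r-y+c))`, offset c = 0.5, a standard half-count
  continuity correction), variance ratio profiled in the kinship
  eigenbasis.

### PQL fitting

The binomial mixed model is fit by penalized quasi-likelihood: iterate
the working response `z = eta + (y - r pi)/(r pi (1-pi))` and weights
`w = r pi (1-pi)` with one average-information REML step per iteration
for `(sigma_g^2, sigma_u^2, sigma_e^2)` under
`V = sigma_g^2 K_rows + sigma_u^2 B + sigma_e^2 D + W^-1`
(B = same-individual indicator, D = diag of 1 for allele rows, 1/2 for
collapsed rows), followed by GLS for `(mu, beta)` and a BLUP update of
the linear predictor (`eta = z - Pz/w`).  Numerical choices:

* initialization: `(mu, beta)` from a binomial logistic IRLS, variance
  components at 0.1;
* convergence: max absolute parameter change < 1e-5, at most 200
  iterations; non-convergence returns the last iterate flagged;
* variance components floored at 1e-6; the AI system is ridge-damped
  (1e-8) with step-halving, falling back to a scaled-gradient step when
  the AI matrix is not usable.  With all-collapsed designs,
  `sigma_u^2` and `sigma_e^2` are exactly collinear and near-identity
  kinship makes `sigma_g^2` weakly identified; only their total
  matters for the test, and the damped updates keep it stable;
* `pi` clamped to [1e-6, 1-1e-6] so boundary counts (y = 0 or y = r)
  keep finite working responses;
* monomorphic genotypes and degenerate systems yield NA rows with a
  reason code so batch runs continue.

The Wald statistic `(beta/se)^2` is referred to chi-square(1).  Two
known small-sample behaviours, both measured by the test suite: point
estimates are mildly attenuated (slope of `beta_hat` on the generating
`beta` about 0.85-0.9 at baseline conditions), and the null is slightly
anti-conservative (type-I error at nominal 0.05 around 0.06-0.09 at
n = 100).  This is why discoveries should be calibrated against the
permutation null rather than the parametric p-values.

### Permutation FDR

Sampling units are the two alleles of each phase-assignable heterozygote
plus each collapsed individual; genotype labels are permuted across
units (counts and individual assignment stay put), B = 10 by default.
The empirical FDR at threshold t is the mean permuted discovery count
over the observed discovery count, made monotone in t; permuted
p-values are pooled across pairs.  An alternative strategy permutes the
per-individual count pairs across individuals and redraws heterozygote
allele splits as Bin(., 1/2) on methylated and unmethylated reads
separately; it is exchangeable only approximately and is recommended
for larger samples (n > 150).  On simulated data the label-permutation
FDR at nominal 0.05 yields a realized false-discovery proportion at or
below 0.10 (slightly conservative).

For simulations with known truth, power is reported at a fixed realized
false-discovery proportion: pool p-values, take the largest rank K
whose realized FDP is <= alpha (ties enter together), and report the
fraction of true pairs in the top K.

## The synthetic-data generator

The generator emulates a population bisulfite-sequencing mQTL study.
Defaults are the baseline study conditions: n = 100 individuals,
h² = 0.3, π₀ = 0.5, MAF bin (0.25, 0.35), ρ = 0 (shared-environment
proportion), TR = 20 (mean total reads), φ = 3 (NB dispersion),
σ² = 0.7 (total over-dispersion variance), PVE = 0.1, 10% of pairs
true.  Per study: a genotype panel (1,000 SNPs, frequencies uniform on
(0.05, 0.5), unrelated individuals) yields the centred/scaled GRM,
standardized to unit mean diagonal; per pair: one fresh focal SNP from
the MAF bin, total reads `r_i ~ NB(mean TR, var TR + TR²/φ)`, allele
split `r_i1 ~ Bin(r_i, q_i)` with `q_i ~ Beta(10,10)` (93.5% of splits
between 0.3 and 0.7), genetic effects
`g ~ MVN(0, c K)` with `c = (1+ρ) h² σ² / (2 + (ρ-1) h²)`, environmental
pairs `(u+e_1, u+e_2)` bivariate normal with variance `(1-PVE-h²) σ²`
and correlation ρ (PVE term set to 0 for null pairs), and effect
`beta ~ N(0, PVE σ² / ((1-PVE) V(x)))` with V(x) the dosage variance.
Heterozygotes keep allele-level counts; homozygotes are collapsed;
zero-read individuals are dropped.

Two bookkeeping facts about these generating formulas, measurable with
`empirical_h2_decomposition`:  the genetic coefficient c is the unique
solution of `h² = c/(c + (σ²-c)(1+ρ)/2)` — i.e. it treats the
environmental variance as `σ² - c` — while the simulated environmental
variance is `(1-PVE-h²) σ²`.  Consequently the realized genetic share
of latent variance at baseline is ≈ 0.37, not the nominal 0.30.  Both
formulas are implemented exactly as specified and the decomposition is
reported rather than reconciled.

What the generator does *not* emulate: linkage disequilibrium between
focal SNPs, genuinely related individuals or population structure (K is
near-identity, so the kinship machinery is exercised but its benefits
are not), reference-allele mapping bias, bimodal genome-wide
methylation landscapes, or covariates.  Passing power tests therefore
demonstrate correct behaviour of the estimators under the stated
generative model, not performance on any particular real data set.

## Problem sizes and reproduction

The reproduction script (`scripts/acceptance.py`) runs each power
scenario at 2,000 SNP-CpG pairs (200 true), a desk-scale version of the
reference 10-replicate x 10,000-pair grid; at this size the Monte-Carlo
spread of a power estimate is a few percentage points, and the
`power_at_fdr` procedure itself was checked to be scale-unbiased.  Null
calibration uses 1,000 null-only pairs and permutation-FDR checks use
400 pairs with B = 10.

## Known limitations

* PQL attenuates large effects and is slightly anti-conservative at
  n ≈ 100; permutation calibration is the supported inference route.
* Under the generative model above, the measured power of the joint
  estimator at known-truth FDR 0.05 (baseline, 2,000 pairs) is in the
  25-30% range, with the allele-only and individual-level special cases
  near 10% and 4-14% — the joint model dominates its special cases, as
  expected from information pooling.
* Only adjacent (same-read or phased) SNP-CpG pairs are supported; no
  distant-pair extension, no 5-hmC/5-mC distinction, no
  imprinting-specific model.
* The beta-binomial baseline ignores relatedness by design; the M-value
  LMM inherits the usual ratio-normalization caveats at low depth.
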