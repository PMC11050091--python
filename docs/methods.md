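# Methods

`tetrags` implements a genomic-selection analysis pipeline for autotetraploid
populations genotyped by sequencing (GBS), of the kind used in alfalfa
breeding: parent plants are genotyped at biallelic SNPs via allelic read
counts, their half-sib progenies are phenotyped in replicated multi-
environment trials, and ridge-regression BLUP models predict family values
from markers under several genome parametrizations and filter settings. This
note documents the models, the defaults and their rationale, the numerical
choices, and what the synthetic data generator does and does not emulate.

## Genome parametrizations

Let `A` and `a` be the reference and alternative read counts at a cell
(sample × locus); cells with `A + a = 0` are missing.

**Allele ratio.** `AR = a / (A + a)` in `[0, 1]`, computed only where
`A + a >= min_reads`; no genotype calling involved.

**Tetraploid dosage.** The number of alternative-allele copies `d` in
`{0..4}` is inferred per locus from a five-component binomial mixture:

    a_i | n_i, d  ~  Binomial(n_i, xi_d),
    xi_d = (d/4) b / ((1 - d/4) + (d/4) b),   xi_0 = e,  xi_4 = 1 - e,

where `b > 0` is a per-locus multiplicative allele-detection bias (allele-
specific amplification or mapping) and `e` is a sequencing error rate that
floors/ceils the homozygous classes. The class prior is a discretized normal
over `{0..4}` (mean and sd re-estimated each M-step, sd clipped to
`[0.25, 4]`), which regularizes rare classes without fixing a population-
genetic model. Parameters are fit by EM per locus:

* E-step: class posteriors from the binomial likelihood and the prior;
* M-step: prior moments from the posteriors; `e` in closed form from the
  two homozygote classes; `b` by bounded 1-D optimization of the expected
  complete-data log-likelihood over the heterozygote classes
  (`log b` in `[-3, 3]`).

The likelihood surface has shifted-assignment local optima when the true
bias is large (every class moved up or down by one, with `b` and `e`
partially compensating), so EM is restarted from three fixed bias
initializations (`b0 = 1, e^1.5, e^-1.5`), each with a prior histogram built
from the dosages the observed ratios imply under that `b0`; the restart with
the best log-likelihood wins. Convergence: absolute log-likelihood change
below `1e-6`, at most 200 iterations; a locus that never converges is
dropped with a logged reason. Loci with fitted `b` outside `[e^-1, e^1]`
are discarded (strong-bias loci are unreliable for dosage assignment).
A cell whose maximum posterior is below `call_threshold` (default 0.9) is
set missing. This caller is a deliberately simplified model in the spirit of
polyploid genotyping tools: it omits overdispersion and outlier components
and keeps only the parts the downstream analysis consumes (the calls and the
bias filter).

**Diploid dosage.** The tetraploid calls with the three heterozygote classes
collapsed into a single intermediate bin: `0 -> 0`, `{1,2,3} -> 1`,
`4 -> 2`. The marker set is unchanged by construction.

## Filter stack and ordering

Import-time: sites with VCF `QUAL < 40` or pooled folded read-based minor
allele frequency `< 0.05` are removed; multi-allelic sites are skipped. MAF
is computed from pooled read counts because it is applied before any
genotype calling; it is folded to the minor allele.

Per configuration, the order is fixed: (1) per-cell depth mask
(`A + a < min_reads` is missing) — applied identically to all
parametrizations, so they differ only through calling; (2) for dosage, the
EM call, the bias filter, and the confidence mask; (3) the per-marker
missing-rate filter (`missing fraction > max_missing` drops the marker).
The grid defaults are `min_reads in {10, 20, 30, 40}` and
`max_missing in {0.05, 0.10, 0.20}`. Because calling only adds missingness
and locus drops on top of the ratio mask, ratio marker counts dominate
dosage counts in every grid cell, with the gap widest at strict missing-rate
settings. The depth threshold is interpreted per cell (not per locus
average): this is what lets the missing-rate filter act on ratio matrices.

## Trial analysis

Replicated trials are solved per trait and environment with the mixed model
`value = mu + rep + g + e`, `g ~ N(0, sigma_g2 I)` random,
replicates fixed with sum-to-zero contrasts (so the intercept is the overall
mean). The incomplete-block structure of real alfalfa platform trials is
simplified to randomized complete blocks: the downstream analysis needs only
the genotype random effect and a replicate term, and the synthetic data
carry no block effects. Variance components are estimated by REML profiled
over `gamma = sigma_g2/sigma_e2`, using one eigendecomposition of `Z Z'` and
bounded scalar optimization on `log gamma` in `[-12, 12]` with tolerance
`1e-8`; on balanced data this reproduces the ANOVA method-of-moments
estimator `sigma_g2 = (MS_family - MS_error)/n_reps`, which the tests use as
an independent oracle. Family BLUPs are `mu + g_hat`; entry-mean broad-sense
heritability is

    H2 = sigma_g2 / (sigma_g2 + sigma_e2 / n_reps)

and `CVg`, `CVe` are `100*sqrt(variance)/mean`.

Cross-environment genetic correlation uses the variance-component estimator
`r_g = cov_g(1,2) / sqrt(sigma_g2(1) sigma_g2(2))`. The genetic covariance
is the between-family covariance of per-environment family means: plot
errors are independent across environments, so that covariance estimates
`cov(g1, g2)` without an error term; the per-environment genetic variances
come from the REML fits. The estimate is clipped to `[-1, 1]` and reported
as NaN when either genetic variance is ~0. Clipping plus REML sampling error
give the estimator a small upward bias at high true correlation (about +0.04
at `r_g = 0.82` with 143 families x 3 replicates), well inside the
recovery tolerance used in the tests.

## rrBLUP

The regression model is `y = mu + X u + e` with i.i.d. marker effects
`u ~ N(0, sigma_u2 I)`. The ridge parameter `lambda = sigma_e2/sigma_u2` is
estimated by the same profiled REML through the equivalent GBLUP form with
kinship `K = Xc Xc'` (spectral work stays `n x n` even for tens of
thousands of markers), and effects are recovered as
`u = Xc'(K + lambda I)^{-1}(y - mu)`, which makes the marker-effect and
kinship formulations identical by construction (tested to 1e-8 against
directly computed closed forms). Missing cells are mean-imputed per marker
and columns are centered, with no variance standardization; an imputed cell
contributes exactly zero after centering and an all-missing sample predicts
at the intercept. A constant phenotype short-circuits to `u = 0`,
`mu = mean(y)`. Note that `lambda` is weakly identified when heritability
approaches 1 (the likelihood is nearly flat in the ratio); predictions are
insensitive to this.

## Cross-validated predictive ability

For each repeat, samples are shuffled with seed `seed + repeat`, split into
`k` nearly equal folds (default `k = 10`, 10 repeats), each fold predicted
from a model trained on the remainder, and Pearson's correlation computed
between the observed vector and the pooled out-of-fold predictions;
per-fold averaging is available behind a flag but pooled is the default (a
single correlation on the full vector is the more stable statistic at
n ~ 143). The mean and sd over repeats are reported. One calibration
property worth knowing: the pooled statistic is not null-centred at zero —
for a trait with no genetic signal its expectation is about
`-1/sqrt(n/k)` (a held-out value is anti-correlated with the mean of its
fold's training complement, and with near-flat predictions that shift
dominates the correlation). The shift is common to every configuration of a
grid, so comparisons and improvements are unaffected; the per-fold
statistic (`pooled=False`) is the null-calibrated one, since each held-out
sample is independent of its training fold. Zero-variance
predictions score 0 with a warning rather than NaN. Grid configurations
yielding fewer than 2 markers are reported as NA and the run continues.
Per-configuration fold seeds are derived from the grid seed and a CRC of the
configuration label, so any sub-grid of the same run is reproducible in
isolation.

The grid summary reports, per trait, the best configuration (ties broken by
fewer markers, then lexicographic configuration id), the marginal means by
parametrization and by SNP subset, and pairwise percent improvements
`100 (mean_x - mean_y)/mean_y` between marginal means.

## Synthetic data generator

The generator's defaults describe the nominal study conditions: 143
genotypes, Hardy-Weinberg autotetraploid dosages `Binomial(4, p)` with
`p ~ Uniform(0.05, 0.5)` per locus (random chromosome pairing, no double
reduction — no population-genetic model is imposed beyond HWE),
negative-binomial cell depths (mean 60, dispersion 2, giving the heavy
depth skew typical of GBS), per-locus log-normal allele bias with
`sd = 0.3` (keeping most loci inside the `[e^-1, e]` acceptance band),
sequencing error 0.005 applied at the homozygous classes, 5% of cells
dropped to zero depth, and 73.9% of markers genic. Gene intervals are laid
out so positional overlap reproduces the genic flags exactly. Traits are
polygenic (default 100 QTL with normal effects); trial phenotypes use a
genotype effect built from the standardized true breeding value carrying
`additive_fraction` (default 0.5) of the genetic variance plus a
non-additive deviation, with the non-additive cross-environment correlation
set so the total genetic correlation equals `r_g_target` (default 0.82),
and plot error variance inverted from the target entry-mean heritability,
`sigma_e2 = n_reps * sigma_g2 (1 - h2)/h2`. The default
`additive_fraction = 0.5` doubles as the half-sib transmission coefficient:
after the additive component is rescaled to a target variance share, a
separate multiplicative transmission factor would be unidentifiable, so one
knob controls both.

What the generator does **not** emulate: linkage and LD along chromosomes
(loci are independent, so marker-based prediction relies on the causal loci
being genotyped and absolute predictive abilities are lower than in real
panels with LD and family structure), GBS restriction-site fragment
economics, incomplete-block field structure, genotype-by-environment
interaction beyond an exchangeable correlation, and meiotic transmission to
progenies (half-sib phenotyping is abstracted into the additive fraction).
Passing recovery tests therefore demonstrates the statistical machinery is
correct under the stated model, not that real-data predictive abilities
will match any particular value.

## Problem sizes used in the automated checks

The test suite and the acceptance script run the pipeline at deliberately
compact sizes chosen to exercise every code path at full statistical
fidelity: dosage-caller recovery on 50 x 300 cells at mean depth 60,
filter-structure checks on 80 x 800, determinism on a reduced
2 x 2 x 3 x 3 grid over 100 x 2000, and Monte-Carlo recovery of H2 and r_g
over 200 replicate trials of 143 families x 3 replicates. These are the
package's own study conditions for verification and are stated here so the
reported numbers can be reproduced exactly.

## Known limitations

* The dosage caller assumes a common error rate and a unimodal class prior
  per locus; loci with extreme allele-frequency structure may be called
  conservatively (more low-confidence cells).
* The genetic-correlation estimator requires both environments' genetic
  variances to be positive and is undefined otherwise.
* Only biallelic SNPs and ploidy 4 are supported; generalizing the mixture
  to other ploidies would change only the class set but is not implemented.
* `heritability_summary` ranges are ranges of family BLUPs, not of raw
  plot values.
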