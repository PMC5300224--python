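# Methods

`introgress` re-implements, as a tested library, the workflow used to
quantify breed introgression in composite cattle such as Canchim (a planned
5/8 Charolais x 3/8 Zebu composite): genotype quality control on PLINK
panels, linkage-disequilibrium statistics and effective-population-size
trajectories, PCA-based stratification checks, and three independent
ancestry estimators whose outputs are compared against pedigree
expectations. Because real breed panels of this kind are rarely public, the
package ships a first-class synthetic-data module that generates purebred
references and admixed cohorts with known ancestry, so every downstream
stage is validated end to end against ground truth.

## The admixture model

All three estimators address the same quantity: the ancestry matrix
Q = {q_ik}, the fraction of individual i's genome derived from each of k
source populations, with per-population allele frequencies F = {f_kj}.
Genotypes g_ij count copies of allele 1 at SNP j. Under random union of
gametes with independent loci, g_ij ~ Binomial(2, pi_ij) with
pi_ij = sum_k q_ik f_kj, giving the log-likelihood

    L(Q, F) = sum_ij { g_ij ln(pi_ij) + (2 - g_ij) ln(1 - pi_ij) }

over non-missing entries.

**Maximum likelihood (`ancestry_ml`).** L is maximized by EM block updates:
each allele copy is attributed to source k with responsibility proportional
to q_ik f_kj (allele 1) or q_ik (1 - f_kj) (allele 2); Q rows average the
responsibilities over the individual's non-missing copies and F takes the
allele-1 share per source and locus. EM is a block-relaxation scheme and
weakly increases L at every iteration — the test suite asserts this
monotonicity (1e-9 slack) on every fit. Convergence is declared when the
absolute change in L drops below `tol` (default 1e-6, configurable); a fit
that reaches `max_iter` first is returned with `converged=False`. Multiple
random starts (Dirichlet(1) rows for Q; observed frequencies jittered by
U(-0.05, 0.05) for F) guard against local optima; the best final likelihood
wins. F and Q entries are clamped away from the boundary by eps = 1e-6 to
keep L finite. A supervised option pins labeled purebred reference rows of
Q at (near-)unit vectors. EM's per-iteration cost is a handful of I x J
matrix products; the likelihood is evaluated inside the same pass as the
update, at the pre-update state.

Model order k is chosen by masked-entry cross-validation: the non-missing
genotype entries are partitioned into folds, each fold is set missing in
turn, the model refit, and held-out entries scored by mean binomial
deviance against the fitted 2 * Q F. On data generated with two source
populations, k = 1 shows the clearly highest error; this qualitative
pattern, not the error's numeric value, is the validated surface.

**Bayesian (`ancestry_bayes`).** The same likelihood is augmented with
latent origins z for every allele copy and conjugate priors
p_kl ~ Beta(lambda, lambda), q_i ~ Dirichlet(alpha, ..., alpha), defaults
lambda = alpha = 1. A Gibbs sweep samples z | p, q (copies of the same
allele within a genotype are exchangeable, so origins are drawn as
conditional multinomial counts — identical in law to per-copy sampling and
vectorizable), then p | z and q | z from their conjugate full conditionals.
Posterior means over post-burn-in sweeps summarize Q and P; retained-sweep
count is exactly n_iter - burn_in, with no thinning. Library defaults are
30,000 sweeps with 10,000 burn-in; the tests and the acceptance script run
shorter chains (1,500/500 at J <= 1,000), which suffices for the mixing
behaviour of this conjugate sampler at those sizes.

Two known behaviours matter for interpretation. First, with alpha fixed
at 1 the prior pulls corner ancestries toward the interior of the simplex,
so posterior means for purebreds are biased inward — the same direction of
underestimation the Bayesian method shows in field comparisons. An optional
Metropolis update infers alpha from the data (uniform prior on (0, 10],
normal random walk) and largely removes that shrinkage; it is off by
default for reproducibility, and the truth-recovery test enables it
explicitly. Second, at low divergence (F_st 0.1) and ~1,000 SNPs the
posterior is honestly diffuse: no summary of it recovers corner truths to
within 0.05, which is a property of the data, not the sampler. Sampler
correctness is therefore validated where exact answers exist — at k = 1 the
marginal posterior of p is Beta(lambda + n1, lambda + n2) in closed form,
and the sampler's moments match it — plus cross-estimator agreement with
the ML fit (mean absolute Q difference below 0.05 on well-separated
cohorts, F_st 0.15).

Label switching (the likelihood is invariant to permuting source labels) is
resolved by exhaustive alignment (k <= 8): the permutation maximizing the
summed matched-column products between two Q matrices, or between Q and
reference labels.

**Regression (`regression_composition`).** Genotypes are transformed to
allele-1 dose {0, 0.5, 1} and regressed on reference-breed allele-frequency
vectors, y = X beta + e; coefficients are clipped to [0, 1] (negative to 0,
above 1 to 1) and divided by their sum to give simplex compositions. Two
modes are provided. The `per-breed` default regresses y on one breed's
frequency vector at a time (with intercept), matching the classical
single-column description of the method. The `joint` mode is a single
multiple regression on all breed columns without intercept; it is the
correctly specified estimator here, since E[y_j] = sum_b q_b f_bj exactly
under the generative model. The distinction matters: reference breeds
derived from a shared ancestral pool have strongly correlated frequency
vectors (correlation ~0.8 at F_st 0.1), so the per-breed marginal slope on
a wrong breed is large (~cov/var), and purebred compositions come out near
(0.55, 0.45) rather than (1, 0). That is an estimator property, visible on
any correlated reference panel, and the per-breed tests assert only ordinal
correctness (own breed ranks first). Quantitative recovery — purebreds
above 0.9, the 5/8-Charolais design point within 0.625 +/- 0.03 — is
asserted for the joint mode. If every coefficient clips to zero the
composition is flagged undefined rather than silently made uniform.

## Synthetic data

Breed allele frequencies follow the Balding-Nichols model: ancestral
frequencies p_j uniform on [0.05, 0.95] (configurable, or supplied
directly, which allows hierarchical two-lineage panels), and each breed's
frequency Beta-distributed with mean p_j and variance p_j (1 - p_j) F_b.
Default divergences F in 0.05-0.15 match the scale of pairwise F_st
typically estimated between cattle breeds within and across the
taurine/indicine lineages. Admixed genotypes are Binomial(2, q' F) draws —
exactly the estimators' assumed model, so recovery tests are
correctly-specified by construction. Missingness is uniform at random.
Loci are in linkage equilibrium by default; a first-order Markov haplotype
generator (stationary frequency 0.5, adjacent correlation rho, hence
r2 = rho^(2 lag)) exists solely to exercise the LD machinery and returns
its phased haplotypes for use as an oracle.

Crossing schemes are directed mating graphs whose founders are purebreds.
Gametes pick one parental allele copy per locus independently; each copy
carries its breed of origin, so realized ancestry is the mean origin
indicator over 2 x n_loci copies — its expectation is the exact parental
mean (the pedigree expectation) and its variance shrinks as 1/n_loci. The
shipped Canchim graphs give CA = 5/8 Charolais, MA = 21/32, C2 = 41/64,
C3 = 21/32 as exact rationals. (Field pedigree averages for real animal
cohorts differ slightly from these design values because realized pedigrees
vary; the design values are what the calculator reproduces.)

What the generator does not emulate: linkage beyond the first-order Markov
option (no recombination maps, no coalescent history), ascertainment bias
of SNP arrays, genotyping error, or relatedness within breeds. Passing
recovery tests therefore demonstrate correctness of the estimators under
their own assumptions, not robustness to real-data violations of them.

## Genotype handling and QC

PLINK text (PED/MAP) and binary (BED/BIM/FAM, SNP-major, magic bytes
0x6c 0x1b 0x01) filesets are read and written natively, with byte-exact
round-trips in both dialects. Allele 1 is recoded to the minor allele at
read time; frequency ties at 0.5 keep the lexicographically smaller allele
name for determinism. Merging intersects SNP sets, unions samples,
reconciles swapped allele codings by allele-pair matching, and re-derives
the minor-allele coding on the merged data; irreconcilable pairs raise a
conflict listing the SNPs.

The QC cascade applies, in this fixed documented order: autosome filter
(chromosomes 1-29), sample call rate (missing fraction > `mind`, default
0.10), SNP call rate (> `geno`, default 0.05), Hardy-Weinberg exact test
(p < 1e-5), then optional MAF (< 0.05). Order can change counts when
filters interact (removing SNPs changes per-sample missing fractions);
tests pin the behaviour with interaction-free constructed panels where
every removal is hand-countable. The HWE test is the exact conditional
test: given the allele counts, heterozygote counts of the observed parity
are enumerated with log-gamma weights and the p-value sums all outcomes no
more probable than the observed one; it matches a rational-arithmetic
enumeration oracle to 1e-12.

## Population statistics

Expected heterozygosity is 2p(1-p) per SNP and group; observed is the
heterozygote fraction among non-missing genotypes; all-missing SNPs are
excluded from summaries, never counted as zero. Pairwise F_st defaults to
the Wright ratio-of-averages form sum_j (p_a - p_b)^2 / 4 over
sum_j pbar (1 - pbar), clamped to [0, 1]; a Hudson-form option
(sum (p_a - p_b)^2 over sum [p_a(1-p_b) + p_b(1-p_a)]) is provided. The two
differ systematically on Balding-Nichols pairs: with each breed at
divergence F from the ancestor, the Wright form converges to F/(2 - F)
(the two-population variance is half the expected squared difference) while
the Hudson form converges to F. `synthetic_data.expected_pairwise_fst`
computes both moment oracles, and the recovery tests compare each estimator
against its own oracle.

The genomic relationship matrix is VanRaden method 1 (centered dosages,
per-SNP mean imputation of missing values, scale 2 sum p(1-p)); PCA is its
eigendecomposition with eigenvalue-ordered components, coordinates scaled
by sqrt(eigenvalue), and the sign convention that each component's
largest-magnitude loading is positive. The outlier filter replaces visual
cluster inspection with an explicit rule: per group (minimum 3 samples),
robust z-scores on the first 2 PCs (median centroid, MAD scale x 1.4826),
removing samples whose z-norm exceeds 3.0 in a single pass; all parameters
configurable.

## Linkage disequilibrium and Ne

r2 between two loci is the Hill-Robertson squared correlation computed
from the two-locus haplotype frequency p_ij and margins. Genotypes are
unphased, so p_ij is the maximum-likelihood estimate from an EM over the
double-heterozygote ambiguity (the only ambiguous genotype pair); with no
double heterozygotes the direct gamete count is returned. Against phased
truth at n = 2,000 the per-pair discrepancy has mean ~0.006; tests bound
the mean and the 95th percentile by 0.02 (the maximum over a growing pair
set is an order statistic and is not bounded). A genotype-correlation r2
(squared Pearson correlation of dosages) is the default inside pruning for
speed parity with standard tools.

Pruning slides a `window`-SNP window (default 50) by `step` SNPs (default
10); within a window, offending pairs (r2 above the threshold, one of
0.10 / 0.05 / 0.01) are scanned in map order and the member with the lower
MAF is removed (tie: the later map position) until no pair offends.
Kept-set size is monotone in the threshold. Decay profiles average r2 in
half-open distance bins ([0, 0.02), ..., [0.40, 0.50) Mb by default);
empty bins are reported as undefined.

Effective population size uses Sved's relation Ne = (1/(4c)) (1/r2 - 1)
at genetic distance c Morgans, converting physical distance at 1e8 bp per
Morgan (1 cM/Mb) and dating each estimate to 1/(2c) generations ago, for
horizons {1, 5, 10, 20, 50, 100, 200}. The r2 entering each horizon is the
mean over pairs within a relative band (default +/-10%) around the target
distance; the inversion round-trips its defining relation exactly, and
empty bands are undefined rather than zero.

## Comparison reporting

Pedigree expectations propagate as exact `Fraction` parental means through
the mating graph. Agreement between two per-sample composition vectors is
D = -log10(mean squared difference), floored at 1e-12 inside the log
(identical inputs report the cap, 12); base and sum-versus-mean aggregation
are configurable since the metric's aggregation convention varies in use.
D = 2 (mean squared difference 0.01) is exposed as the conventional
"highly similar" threshold. Group summaries report mean, SD, min, max and
the signed deviation from pedigree expectation.

## Problem sizes

Recovery and validation runs use desk-scale sizes chosen to make the
statistical assertions decisive while keeping the full suite and the
acceptance script each around a minute or two of compute: ML recovery at
J = 5,000 SNPs, I = 300 (RMSE(Q) ~ 0.04 versus the 0.05 bound);
cross-validation at J = 1,500, I = 150, k = 1..3; Gibbs chains of
1,500/500 sweeps at J <= 1,000; LD oracles at n = 2,000 samples; F_st at
J = 10,000. Library defaults remain at the conventional analysis scale
(tol 1e-6, 30,000/10,000 sweeps, 50/10 pruning windows).

## Known limitations

- No VCF input, no sex chromosomes, no strand-ambiguity resolution beyond
  allele-pair matching.
- Two-locus EM only; no multi-locus phasing, no recombination-map
  distances.
- The Bayesian module implements the independent-loci admixture model
  only (no correlated-frequencies prior, no linkage model, no model
  evidence for k; k selection is delegated to cross-validation).
- No constrained (simplex) least squares in the regression module — the
  clip-and-renormalize convention is the method being reproduced, not an
  optimal estimator.
- Numeric equality with published tables from any particular cattle data
  set is out of reach without those genotypes; validation is against
  synthetic ground truth and exact hand-computable cases.
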