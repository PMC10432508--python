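# Methods

This note documents the models, estimators and numerical choices behind
`resistscan`, what the synthetic-data generator does and does not emulate,
and the problem sizes used by the test suite and `scripts/acceptance.py`.

## Study design the pipeline assumes

The unit of analysis is a *sample set*: mosquitoes of one species,
collected at one location (typically as larvae and raised to adulthood),
phenotyped against one insecticide. Phenotype is binary — alive
(resistant) or dead (susceptible) after a standardized exposure designed
to separate the phenotypic extremes. Genotypes come from whole-genome
sequencing: diploid SNP calls (0/1/2 alt-allele dose, with an explicit
missing sentinel), optionally statistically phased haplotypes, a genome
accessibility mask marking reliably callable regions, per-sample
normalized coverage in 300-bp windows, and a per-sample contamination
abundance estimated externally.

## Sample QC and sex calling

Exclusion rules apply sequentially — low coverage (strict < 10×), then
cross-contamination (strict α > 4.5%), then technical replicates (genetic
distance < 0.006; the higher-coverage member of each surviving pair is
retained) — and a sample is counted under the first rule it fails only.
This yields disjoint per-reason counts that sum with the pass count to the
input size. Sex is classified from the X/autosome modal coverage ratio:
[0.4, 0.6] male, [0.8, 1.2] female, boundaries inclusive (the ranges are
stated as closed intervals; inclusivity is pinned here), anything else
excluded.

## Kinship and sibling handling

Larval collections contain full-sib families. Pairwise kinship uses the
KING-robust between-family estimator,

    phi_ij = (N_AaAa − 2·N_AAaa) / (N_Aa(i) + N_Aa(j)),

with counts over sites called in both samples. It is robust to allele
label swaps and to population stratification; expected values are 0.5 for
identical samples, 0.25 for full sibs, ≈0 for unrelated pairs. A pair with
no informative heterozygous sites is flagged and treated as unrelated.

Sibling edges are strict (φ > t); full-sib groups are connected components
of the resulting graph, and a group is *inconsistent* when transitivity
pulled in a pair at or below the threshold. The working threshold is the
grid value (default 0.15–0.35 by 0.005) minimizing the proportion of
inconsistent groups; at thresholds producing no groups the proportion is
defined as 0, and ties break toward the **largest** minimizer — the most
conservative sibling calling. Downstream, statistics either average over
sib-pruning permutations (each keeps one random member per group plus all
non-sibs, sampled without replacement, so at most ∏ group sizes distinct
subsets exist) or use a single fixed pruned subset where averaging would
make p-values uninterpretable (the GWAS).

## Windowed selection scans

All windowed statistics use non-overlapping, left-aligned blocks of 1000
post-filter SNPs per chromosome; the trailing partial window is dropped.
Site filters (accessibility, missingness, minor-allele count, singleton
removal, segregation) are applied before windowing; MAC thresholds are
inclusive ("at least"), and a singleton is a site whose minor allele
appears exactly once across the analysed samples.

**Hudson F_ST** is computed per window as the ratio of summed per-site
components,

    num = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1),

the standard block ("ratio of averages") estimator, numerically stable and
unbiased at the site level. A consequence worth noting: two groups with
literally identical allele counts give a slightly *negative* value (the
sampling-variance correction), vanishing as sample size grows; the
estimator is unbiased around 0 over repeated sampling from one
population. Windows with zero summed denominator are undefined (NaN) and
excluded from peak detection. The scan value is the mean over up to 100
sib-pruned subsets.

**PBS** for the resistant branch is (T_RS + T_RO − T_SO)/2 with
T = −log(1 − F_ST), each F from the same Hudson block estimator. F values
are clamped to [0, 1 − 1e−8] before the log so fixed differences produce
large finite branch lengths rather than infinities; negative F (possible
with the unbiased numerator) clamps to 0. The outgroup should be a
conspecific population sampled away from the focal cohort. The three
branch lengths satisfy PBS(R)+PBS(S)+PBS(O) = (T_RS+T_RO+T_SO)/2 exactly.

**H12** treats a window's phased haplotypes as strings; with sorted
haplotype frequencies p1 ≥ p2 ≥ …, H12 = (p1+p2)² + Σ_{i≥3} pi². Pooling
the top two classes makes the statistic sensitive to soft sweeps where two
haplotype backgrounds carry the adaptive allele. ΔH12 is
H12(resistant) − H12(susceptible), positive when a sweep is concentrated
in the resistant class.

**Peak calling.** Genuine association peaks are one-sided, so the left
tail of the per-window distribution calibrates the null spread: with mode
m and d = m − min(values), windows strictly above m + 3d are provisional
peaks. The mode of a continuous sample is not well defined; the default
estimator is a Gaussian KDE (Silverman bandwidth) evaluated on a 512-point
grid over the data range, with a histogram-mode alternative exposed. Both
are translation invariant, so peak calls are too. All-identical input
(d = 0) yields no peaks.

**Permutation filtering.** Extended swept haplotypes inflate window
variance and can create F_ST peaks unrelated to phenotype. Each
provisional peak is therefore re-tested against 200 random
phenotype-label permutations and retained only if the observed value
strictly exceeds the 99th centile (linear-interpolation quantile) of its
permuted values. The permutation recomputation uses one fixed sib-pruned
subset rather than re-averaging all sib permutations per label
permutation — a ~10⁴-fold cost reduction that leaves the null
exchangeable. Under a fully null cohort the long-run retention rate is
≈1–1.5% (the observed value must land among the top ~3 of 201
exchangeable values), which the calibration tests verify.

## Haplotype-cluster association

Within a window of interest, D_xy between two haplotypes is the
proportion of differing sites. Clustering is agglomerative with
**complete linkage**, cut at height 0.001 (non-strict, ≤), so every
within-cluster pair differs at ≤ 0.1% of sites — "haplotype clusters" of
near-identical sequences; average and single linkage are exposed as
options. Clusters strictly larger than 20 haplotypes are tested with a
binomial-logit GLM of phenotype on per-sample cluster dose (0/1/2), the
p-value from a 1-df likelihood-ratio test (complete separation falls back
to the score test, flagged); a dose with no variance is untestable and
flagged. SNP enrichment on a cluster uses a one-sided Fisher exact test
(alternative: more frequent on-cluster) at α = 0.001, the one-sidedness
matching the question asked — which SNPs ride the swept haplotype.
Combining sample sets is simply the same analysis on concatenated
haplotypes and phenotypes; there is no special code path.

## GWAS

Sites enter with no missing data and MAC ≥ 5, from one sib-pruned subset.
The per-SNP model is logit P(alive) = a + b·dose; because dose takes only
values {0,1,2}, the likelihood depends on six counts per SNP and
thousands of SNPs are fitted simultaneously by a vectorized two-parameter
Newton iteration (damped steps, gradient tolerance 1e-10); the surface is
exactly the one a generic IRLS fit maximizes, and the test suite checks
agreement with statsmodels to 1e-6. Separation (divergent slope) is
detected and the p-value falls back to the 1-df score/trend test,
flagged.

SNPs whose genotype correlates with per-sample contamination abundance
(Pearson correlation t-test p < 0.05 by default; Spearman optional) are
excluded before FDR — plate-structured bacterial contamination otherwise
creates artefactual associations. FDR uses BH step-up q-values by
default; a Storey π₀-adjusted option approximates empirical-null local-fdr
approaches. The candidate-window step depends only on p-value ranks, so
the choice of FDR flavour does not move it. Candidate regions: the 1000
smallest-p SNPs (ties at the boundary broken by (p, chrom, pos)), located
on a fixed non-overlapping 100-kb tiling anchored at position 0; tiles
holding ≥ 10 top SNPs are reported, adjacent qualifying tiles merged.
Fixed tiles rather than sliding windows are a pinned interpretation;
they make "a window" well defined and counts disjoint.

Known-marker and copy-number association uses forward stepwise selection:
the pool is markers at frequency ≥ 10% (mutant-allele frequency
mean(dose)/2 for SNPs; carrier fraction — copy number ≠ 2 — for CNVs, a
pinned choice since "allele frequency" is not well defined for a
multiallelic copy-number distribution); at each step the candidate with
the smallest 1-df deviance-test p enters if p < 0.05, and selection stops
otherwise. Perfectly collinear markers add zero deviance and never enter
after their proxy.

## Copy number

Coverage is normalized per sample by its autosomal median (the upstream
production pipeline additionally GC-corrects; that correction is out of
scope here and the generator does not simulate GC bias). Copy-number
states 0–12 are decoded by Viterbi with Gaussian emissions
N(state/2, σ) — σ estimated from windows near the diploid baseline
(0.75–1.25) unless supplied — and transitions that stay with probability
0.9999, jumping uniformly otherwise; breakpoints are rare at the 300-bp
scale, and the high stay probability suppresses single-window noise
flips. Gene copy number is the modal state over the windows a gene
overlaps, ties resolving to the larger state (pinned, so amplification
calls are consistent), and a gene is amplified when its modal state
exceeds 2.

## Power simulation

The simulation asks what cohort size lets a truly associated SNP survive
FDR control against a genome of null tests. An observed effect is
summarized by its allele frequency in each phenotype class; per
replicate, 10 independent true loci draw genotypes Binomial(2, class
frequency) under within-class HWE for n/2 resistant and n/2 susceptible
samples and are tested with the same logistic LRT as the GWAS; 7 million
null p-values are drawn Uniform(0,1) (chunked generation bounds memory);
BH is applied jointly at q < 0.05 (the FDR flavour and level are pinned
defaults — the original analysis's empirical-null settings are not
recoverable, which is the main reason exact historical percentages are
not targeted); detection is the fraction of true loci significant. The
joint BH cutoff is computed by rank arithmetic against the sorted null
block rather than materializing 7M q-values. Defaults are 500 replicates
per sample size; the scaled-down mode used in tests and the acceptance
script (n_null = 7e4, 50–60 replicates) preserves the zero-effect null,
the large-effect limit and monotonicity in n.

## Synthetic cohorts

The generator emulates exactly the structure the analyses assume:

* one population allele-frequency vector drawn Beta(a, b) (default
  (0.8, 0.8), giving a realistic U-shaped folded spectrum); founder
  haplotypes drawn site-independently from it. No background LD by
  default — this keeps every downstream oracle tractable; an optional
  block-copy mode creates LD for sweep realism.
* families: two unobserved parents each; every child receives one
  recombined gamete per parent, crossovers Poisson (default rate 1 per
  transmitted copy, uniform positions). Realized sib-sharing variance at
  rate 1 is large (few independent segments); recovery tests raise the
  rate to 10 to concentrate the estimator near its 0.25 expectation.
* phenotype: Bernoulli(logistic(β0 + Σ βk·gk)), purely additive — no
  dominance, matching the additive 0/1/2 coding used by every association
  layer.
* sweeps: carrier haplotypes in a window are overwritten by a shared core
  haplotype plus Bernoulli(noise) flips; carrier fractions can differ by
  phenotype class so sweep–phenotype association is controllable (equal
  fractions give an unassociated sweep).
* coverage: Normal(CN/2, σ) per 300-bp window truncated at 0, CN = 2
  outside CNV spans; default σ = 0.1.
* contamination: a per-plate-column gradient (96-well plates filled
  column-major) plus Gaussian noise, mimicking plate-structured
  contamination.

Not emulated: chromosomal inversions and their long-range LD, linked
selection, GC-coverage bias, genotyping error, or coalescent demography.
Passing recovery tests therefore demonstrates estimator correctness and
calibration under the assumed structure, not robustness to inversion
polymorphism or reference bias in real data.

## Problem sizes and numerical conventions

Internal coordinates are 0-based half-open; VCF positions (1-based) and
BED intervals convert at the boundary. Missing genotypes are a distinct
sentinel (−1), never conflated with homozygous reference. Site filtering
is idempotent, and genotype/haplotype consistency is asserted after every
read and filter.

The test suite and acceptance script use desk-scale sizes chosen so every
statistical check retains adequate Monte-Carlo resolution: 20k variants
for kinship recovery; 2000 windows × 200 permutations for the
permutation-filter null; 15 replicates of a 200-sample, 5000-SNP cohort
for causal-SNP ranking; 20 replicates for sweep-cluster power; 40 samples
× 500 windows for HMM accuracy; 50–60 replicates with 7e4 nulls per power
point. All randomness is seed-derived and reproducible.
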