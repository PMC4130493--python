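# Methods

`varstrat` re-implements the bespoke analysis layer of a multi-population
short-read sequencing study as a reusable pipeline: a Wright's F_ST
stratification scan, functional-class and GWAS-locus enrichment with a
matched-permutation null, call-set concordance and QC metrics, an
imputation-accuracy evaluation, and a discovery-power model. Because the
headline numbers of such studies come from hundreds of real genomes and
external reference panels, every stage is exercised instead on a bundled
synthetic cohort generator whose statistical structure matches what the
analyses assume. This note records the models, the defaults and why, the
numerical choices, and what the synthetic experiments do and do not show.

## The synthetic cohort

**Allele frequencies.** Each variant draws an ancestral frequency
p ~ Beta(a, b) truncated to [0.001, 0.999]; each population then draws its
own frequency from a beta with mean p and variance F·p(1−p) — the
Balding–Nichols model, the standard single-parameter drift/structure
generator. F is per population and dimensionless in (0,1). The default
ancestral spectrum is Beta(0.3, 0.3), a U-shaped neutral-like spectrum.
Where an experiment needs a realistic *non-reference* (alt-skewed)
spectrum — most alt alleles rare — we use Beta(0.3, b) with b chosen from
the closed form below.

**Genotypes.** Diploid genotypes are Hardy–Weinberg draws
Binomial(2, q_pop) per sample, sites independent. Under a site spectrum
p ~ Beta(a, b), the expected per-sample Het/Hom(alt) ratio is
2·E[pq]/E[p²] = 2b/(a+1); solving 2b/(a+1) = 1.55 at a = 0.3 gives
b ≈ 1.0075, which is how the "high-coverage" Het/Hom ratio of 1.55 is
realised when an experiment requires it.

**Low-coverage genotype errors.** At ~4x coverage the dominant genotyping
failure is undercalling heterozygotes: with few reads, the alternate
allele of a het may never be sampled. The error model renders each true
het homozygous with probability m, collapsing to the reference homozygote
by default (`ref` mode); an even-split mode (0 or 2 with equal
probability) is available. In `ref` mode the observed Het/Hom ratio is
(1−m)× the true ratio in expectation, so the default
m = 1 − 1.05/1.55 ≈ 0.323 maps a true ratio of 1.55 onto an observed
ratio of 1.05 — the depression characteristic of low-coverage call sets.

**Functional classes, constraint and novelty.** Each variant gets exactly
one class label (nonsynonymous, synonymous, stop, splice, utr5, utr3,
intronic, intergenic, other), drawn with genome-like proportions (coding
classes ~2% of sites). An optional per-class *constraint* multiplier
shrinks the drift F of that class (coding classes drift less under
purifying selection), giving enrichment/depletion analyses a controllable
truth. Novelty (absence from the known-variant catalogue) is assigned at
rates depending on the cohort frequency class — rare 0.50, low-frequency
0.15, common 0.02, matching the usual pattern that almost all novel
discoveries are rare — and, when constraint is active, coding novelty is
additionally suppressed outside the rare bin (new functional alleles
rarely reach high frequency), which is what produces the coding-depletion
signal among common novel variants.

**Sentinels and gene track.** Gene intervals are drawn with density ~1
gene per 150 kb (human-like), since the matched-permutation test needs a
workable pool of variants within ±10 kb of a sentinel's
distance-to-nearest-gene. Sentinel catalogues are sampled from the
simulated variants with covariates recorded (allele frequency, distance
to nearest gene, gene count within 250 kb); an enrichment mode weights
sampling by exp(strength × normalised between-population divergence) to
create positive controls.

All draws flow from a single seeded `numpy` Generator; every output is
bit-reproducible. Sites are independent: there is no linkage
disequilibrium, no haplotype structure, and no admixture. Analyses whose
behaviour on real data depends on LD or shared ancestry (e.g. regional
clustering of stratified SNPs) are therefore only exercised for
correctness of the computation, not for realism of the spatial pattern.

## F_ST estimation

Per site, two estimators over the pair of allele frequencies (p1, n1),
(p2, n2):

* `nei_gst` — the parameter-level definition (H_T − H_S)/H_T with
  H_T = 2·p̄(1−p̄), H_S the mean within-population heterozygosity, and p̄
  the *unweighted* mean of the two frequencies. Unweighted because a
  reference panel's chromosome count would otherwise dominate H_T when
  comparing a sequenced cohort against a much larger panel.
* `hudson` (default) — numerator
  (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1), denominator
  p1(1−p2) + p2(1−p1). The correction terms remove sampling noise, making
  the per-site numerator unbiased; the estimator is suited to cohort-vs-
  panel comparisons with unequal n.

Sites monomorphic for the same allele in both populations are flagged
undefined and excluded. Negative per-site estimates are clipped to 0 in
the `fst` column used for threshold selection (a stratified SNP is one
with clipped F_ST strictly above the threshold, default 0.10); the
unclipped value is kept in `fst_raw` because clipping inflates means near
F = 0.

Multi-locus summaries are emitted in three conventions, which differ
materially near F = 0: the ratio of summed numerators to summed
denominators (the standard combined Hudson estimator, and the headline
mean here — under the Balding–Nichols model its expectation is exactly
the generating F, and it recovers F within a few percent at 20,000 sites
and 100 diploids per population), the arithmetic mean of per-site ratios
(biased low by ~15–20% at these sizes, reported for comparison), and the
mean of clipped values. `nei_gst` carries positive finite-sample bias
under the null; the test suite asserts the hudson null mean sits below
it.

## Enrichment

**Class enrichment.** For a stratum of variants (high-F_ST SNPs, or the
novel variants within a frequency bin) and one functional class, the 2×2
in/out-stratum × in/out-class table is tested with Pearson's chi-square
without continuity correction. Fold = (class fraction in stratum)/(class
fraction in background), background defaulting to all analysed variants
(a complement-background mode exists). When any expected cell falls below
5, the p-value falls back to Monte-Carlo resampling of the stratum-class
cell from the fixed-margin hypergeometric null (add-one estimator), so
toy-sized tables stay safe. The chi-square's type-I error is calibrated:
~5% rejections at α = 0.05 over 1,000 null simulations.

**Matched-permutation GWAS enrichment.** Observed = number of *distinct*
stratified SNPs within a closed window [pos−w, pos+w] (default
w = 500 kb) of any sentinel; union semantics, each SNP counted once even
inside overlapping windows, because double counting would inflate
observed and expected asymmetrically with sentinel clustering. The null
is built from random sentinel sets matched to the real ones on allele
frequency (±0.02), distance to nearest gene (±10 kb) and gene count
within 250 kb (±2) — "gene proximity" is implemented as
distance-to-nearest-gene tolerance, with the covariate stored explicitly
so the alternative (within-gene status) can be swapped in as data.
Matches are uniform among eligible pool variants, without replacement
within a set, with replacement across the n_perm sets (default 10,000); a
sentinel with no eligible match is dropped from both the observed count
and the null, so both sides of the comparison keep the same sentinel
structure. Expected = null mean; fold = observed/expected;
p = (1 + #{null ≥ observed})/(1 + n_perm) — the add-one permutation
estimator, always positive.

The add-one p is discrete; with small expected counts its tie mass makes
it visibly conservative (p-values skew high). Calibration experiments
therefore use designs with enough count resolution — thousands of pool
variants, ~20% stratified, ~25 sentinels — under which the empirical fold
averages 1.00 and the p-values pass a Kolmogorov–Smirnov uniformity test
over 200 independent null datasets at 1,000 permutations each.

## Call-set metrics and the discovery-power model

Site identity everywhere is (chrom, pos, ref, alt); multiallelic VCF
records are split into biallelic records at the reader, with per-allele
dosages whose sum preserves each genotype's total alt count. Sensitivity
is the fraction of reference-polymorphic sites recovered by the
experimental set; PPV the fraction of experimental polymorphic calls
confirmed; genotype concordance and the |ΔAF| > 0.01 discordance fraction
are computed over sites polymorphic in both sets on non-missing pairs.
Ti/Tv counts A↔G and C↔T as transitions; Het/Hom is per sample, with the
cohort value the mean ± SD of per-sample ratios. Missing genotypes never
enter any denominator.

Discovery power uses a per-copy binomial model: a cohort of N diploids
carries Binomial(2N, f) copies of an allele of frequency f, each copy is
detected independently with probability s (the observed per-copy
sensitivity), and a variant is discovered iff at least one copy is
detected — power = 1 − (1 − f·s)^{2N} for one cohort, with independent
cohorts multiplying their miss probabilities. At the study's printed
inputs (s = 0.919, N = 168 whole-genome; s = 0.992, N = 147 whole-exome)
this yields 95.5% power at f = 1.0% for the genome arm alone and 95.1% at
f = 0.5% combined, matching the ">95%" statements those inputs
accompany. The sensitivity could alternatively be read as per-site rather
than per-copy; the per-copy reading is adopted because it reproduces both
printed power statements, and the closed form is cross-checked against a
Monte-Carlo oracle (10⁶ replicates) in the tests and the acceptance
script.

## Imputation accuracy

Per site, accuracy is the squared Pearson correlation between imputed
dosage (real-valued in [0,2]) and observed genotype over non-missing
pairs; sites with constant observed genotypes are flagged undefined and
counted, never silently dropped. Bin means are unweighted averages of
per-site r² within allele-frequency bins (default edges 0, 0.01, 0.05,
0.1, 0.2, 0.5 on the *minor*-allele frequency — folding is the standard
convention for accuracy curves, and an unfolded mode exists) or within
integer allele-count bins for small panels.

The synthetic experiment hides a fraction (default one half) of each
site's genotypes and replaces them with the true genotype shrunk toward
the population mean dosage 2p plus Gaussian noise. Shrinkage is affine
and leaves r² untouched; the noise term is what degrades accuracy, and a
fixed noise level hits rare sites hardest because their genotype variance
2p(1−p) is smallest — which is exactly the characteristic decay of
imputation-accuracy curves at low minor-allele frequency, and why a
single noise parameter ("panel quality") yields curves that dominate each
other uniformly across bins.

## Problem sizes and numerical conventions

Default experiment sizes — 20,000 independent sites and 100 diploids per
population for F_ST recovery; 200 null datasets at 1,000 permutations for
permutation calibration; 1,000 simulations for chi-square calibration;
10⁶ Monte-Carlo replicates for the power oracle — were chosen as the
smallest designs at which the targeted properties are statistically
clean, and run in well under a minute each on one core.

Coordinates are 1-based inclusive internally (VCF convention); BED input
is converted from 0-based half-open at the reader. Frequency classes are
rare (af < 1%), low-frequency (1% ≤ af < 5%), common (af ≥ 5%), lower
boundaries inclusive; frequencies are non-reference (alt) frequencies
throughout, not folded, except in imputation binning as noted. When an
annotation source lists several classes for one variant the most
consequential wins (stop > splice > nonsynonymous > synonymous > utr5 >
utr3 > intronic > intergenic > other). Windows are closed intervals.
Genotype dosage is int8 with −1 for missing.

## Known limitations

* Independent sites: no LD, no haplotype sharing, no admixture — the
  generator cannot reproduce the regional clustering of stratified SNPs
  or admixture-specific sharing gradients seen in real cohorts, so
  passing tests demonstrate correctness of the statistics, not realism of
  those spatial patterns.
* The error model is a single Bernoulli undercall per het; real
  low-coverage callers have depth-, allele-balance- and
  recalibration-dependent error structure.
* The pseudo-imputation model is a shrink-plus-noise caricature; it
  produces the right orderings (panel quality, frequency dependence) but
  its absolute r² values are not calibrated to any real imputation
  engine.
* The discovery-power model treats copies as independent within and
  across cohorts; cryptic relatedness or shared carriers between arms
  would break the independence assumption.
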