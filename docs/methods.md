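# Methods

`cnvx` implements an integrative analysis of copy-number variation (CNV),
gene expression and breeding-value phenotypes in a half-sib livestock
cohort: founders (sires) crossed to unrelated dams, with SNP-array-inferred
CNV calls on the whole cohort, RNA-seq on a subset, genomic estimated
breeding values (GEBVs) as phenotypes, and sequencing-based CNV calls on
the founders for validation. This note records the models, the defaults
and the design choices, and what the synthetic cohort does and does not
emulate.

## CN genotyping

Per-sample CNV calls (deviations from diploid, integer states 0–4) are
collapsed onto predefined CNV regions. A sample is assigned a call's state
when the call covers at least `min_overlap_frac` (default 0.5) of the
region; absent calls mean diploid (2n). Reciprocal overlap is not required
— a call may exceed the region, as SNP-inferred calls typically do. When
several calls qualify, the one covering the largest fraction wins; exact
ties resolve to the state nearest 2n (conservative), then the lower state,
and every conflict is logged. Coordinates are 0-based half-open (BED)
throughout.

## Expression association

Counts are modeled per gene as NB2 (variance mu + alpha·mu²) with a
log-link GLM whose only covariate is the region's CN-state factor with 2n
as reference, and log effective library size (library size × normalization
factor) as offset. Normalization factors are trimmed means of log
expression ratios against a reference sample (the one whose upper-quartile
count rate is closest to the cohort mean upper quartile), trimming 30% of
log-ratios and 5% of average log-abundances, geometrically centered to
product 1.

Two filters precede testing: (i) a gene is tested for a region only if the
maximum over the region's CN groups of the group **mean** cpm reaches
`r_cpm` — the mean (not median) is robust to the extreme group-size
asymmetry of rare CN states; (ii) deviating CN states with fewer than
`s_min` samples are dropped, their samples excluded, and regions with no
surviving deviating state are skipped. Defaults are `r=3, s=4`, nominal
alpha 0.05 for local tests (genes overlapping the region, few and
biologically motivated) and `r=25, s=10` with Benjamini–Hochberg control at
0.01 jointly over all tested (region, gene) pairs for the genome-wide
distal scan.

The test is a likelihood-ratio test of the full one-way model against the
intercept-only model, df = number of deviating states — the ANOVA-like
"any group differs from 2n" hypothesis. With one deviating state it is the
usual two-group NB comparison. Per-state log2 fold changes are reported
against 2n; the dosage direction is the sign of the group-size-weighted
least-squares slope of state log2FCs on CN, so a deletion region whose
carriers over-express is correctly labeled down-with-gain. States whose
log2FCs imply conflicting directions beyond 0.1 log2 units yield `mixed`.

**Dispersion.** A common dispersion maximizes the summed Cox–Reid adjusted
profile likelihood (the adjustment subtracts half the log determinant of
the per-group Fisher information, countering small-sample bias) on a
log-spaced grid with golden-section refinement; gene-wise dispersions
maximize the per-gene APL plus a pull toward the common curve worth 10
observations, with parabolic interpolation between grid points. The
pipeline estimates dispersion once under the intercept-only design; this
slightly over-estimates dispersion for genes with real CN effects (a
conservative bias accepted for simplicity across many regions), and the
null simulations show the type-I error at nominal 0.05 stays within
[0.04, 0.06] at both 4+4 and 30+30 group sizes.

Group-wise NB means are fit by Fisher scoring on log rates (the one-way
layout decouples into 1-D problems, vectorized across genes), with step
clipping at ±5, convergence at |step| < 1e-10, at most 60 iterations, and
a rate floor of 1e-12 for all-zero groups. Non-converged fits are flagged
and reported with p = NaN.

**Summaries.** Per region, significant genes are tallied by direction and
regions with ≥10 significant genes flagged as high-impact; the region×gene
adjacency keeps genes significant for at least `min_regions` regions
(default 3), ordered by marginal. The synergy score for two regions'
effect states is computed on the log2(cpm + 0.5) scale as
mean(both) − [mean(onlyA) + mean(onlyB) − mean(neither)]; an OLS
interaction p-value is attached only when every cell has ≥3 samples,
otherwise the statistic is reported descriptively (double carriers are
rare by construction). The 0.5 pseudocount is used for all log-scale
descriptive statistics.

## Dosage compensation

For genes with a substantial full-spanning one-copy-loss (1n) group, the
compensation statistic is median cpm(1n) / median cpm(2n): 0.5 under
strict dosage, 1 under full buffering. Confidence intervals come from a
percentile bootstrap (default 10,000 replicates) resampling samples with
replacement within each group — the simplest scheme consistent with a
ratio of group medians; BCa was not used because the statistic's bootstrap
distribution at the group sizes of interest is already near-symmetric and
the percentile method's 92–98% coverage at nominal 95% is verified by
simulation. Classification by CI membership (contains 1 → compensated;
contains 0.5 → dosage; ratio > 1 with CI excluding 1 → inverse; else
partial) is a package convention: the class boundaries are not canonical,
only the ratio is.

## Enrichment

Region-level feature enrichment compares the weighted count of feature
intervals overlapping a region with 1000 same-length regions placed
uniformly on the same chromosome (rejection-sampled against an exclusion
list); p = (1 + #{null ≥ obs})/(n_perm + 1), with a depletion tail
available. No GC or gap matching is attempted beyond the exclusions.
Promoter TFBS enrichment uses a strand-aware window around the TSS
(default −2000..+500, configurable; the window is a convention, not a
measured quantity) and a two-sided Fisher exact test per TF on
bound/unbound × query/background, BH-adjusted (FDR 0.1 conventionally).
Generic gene-set over-representation uses the same machinery with set
membership in place of promoter binding.

## Phenotype association

GEBVs are inputs (their estimation from raw phenotypes is out of scope).
Each (region, trait) pair is tested twice: an additive model (OLS of GEBV
on CN dosage; closed-form, transparent, and exactly what a dosage
hypothesis predicts) and a genotypic model (one-way ANOVA across CN
groups, which catches non-additive and multi-allelic patterns). Deviating
states below `s_min`=10 phenotyped samples are dropped, missing phenotypes
pairwise-deleted, and BH runs across all pairs per model at FDR 0.1.

## Fine-mapping and concordance

Pileups count, per bin (default 10 kb, matching the ±0.04 Mb resolution
at which consensus breakpoints are typically reported) and per deviating
state, the distinct samples whose calls cover the bin; the consensus
breakpoint interval is the maximal-count run of bins (leftmost on ties,
flagged). Inheritance of a region is assessed by the overlap of offspring
and sire peak intervals plus the cosine similarity of cohort-size-
normalized profiles.

Sequencing-based calls are filtered before comparison: length < 1 kb or
> 1 Mb, q0 > 0.5, quality < 10, or ≥50% overlap with an exclusion
interval; rules are applied independently (they commute) and per-rule drop
counts are reported. Concordance of SNP-array calls with sequencing calls
is measured in base pairs of SNP-call territory (robust to fragmentation
of sequencing calls; a per-call metric is deliberately not the default),
per sire, in three modes: any overlap, type-matched (same side of
diploid), and deletions-only (both sets restricted to CN < 2 first, since
duplications are the known weak spot of sequencing-based callers).
Cohort medians are reported on the percent scale.

## Synthetic cohort generator

The generator is first-class, tested code. It emulates:

* a half-sib pedigree — default 9 sires × 20 offspring (180 transcriptomed
  animals, the scale of the expression cohort it mimics); carrier sires
  are heterozygous by default (one variant allele, transmitted with
  probability 1/2); dams are unrelated, contributing one allele at
  `dam_allele_freq` — whether dams carry CNV alleles at all is exposed as
  a parameter rather than assumed;
* CN states 2 + signed allele dosage, clipped to 0..4 (the states the
  downstream analyses distinguish);
* SNP-like calls with Gaussian border jitter (default sd 5 kb, truncated
  at the locus midpoint so calls stay non-degenerate — the simplest model
  producing a call-density peak at the true breakpoints), plus exact
  "sequencing" calls for sires; an optional sub-interval mode emulates
  intersecting rather than full-spanning deletions;
* NB counts with mean L_i·q_g·f_local·f_distal, dispersion 0.2 (a typical
  bulk RNA-seq value), library sizes log-uniform on 15–25M so
  normalization is non-trivially exercised; local factor
  f = c + (1−c)·CN/2 with compensation c ∈ [0,1]; distal factor 2^beta per
  regulator locus at which the sample deviates, plus a 2^synergy term on
  shared targets when both partner loci deviate;
* baseline expression log2-uniform over 1–8 log2 cpm for generic genes;
  genes designated as local or distal effect carriers draw from 5–8 log2
  cpm — the genes in which such effects are observable are by construction
  well-expressed (they must clear the cpm filter), and placing them there
  mirrors that;
* GEBVs linear in CN (effect per copy plus Gaussian residual), so
  tri-allelic phenotype patterns emerge from bi-allelic expression ones;
* the default cohort: two regulator loci (one deletion with
  expression-increasing targets, one duplication with decreasing targets,
  |log2FC| = 1, 20 targets each of which 5 shared with a +1 synergy term)
  and one local locus carrying genes at c = 0, 0.5 and 1.

It does **not** emulate: linkage disequilibrium or any SNP-level
structure, read-level artifacts (mismapping into deleted loci), GC or
mappability bias, batch effects, or relatedness beyond the single
paternal generation. Passing tests therefore demonstrate correctness of
the statistical machinery under its stated model, not robustness to those
real-data complications.

All randomness flows from a single seed through named SHA-256-derived
substreams (pedigree, calls, counts, GEBVs, per-stage in the pipeline), so
outputs are byte-reproducible and stages are individually replayable.

## Problem sizes used in the test suite

Null calibration uses 5000 genes at 4+4 and 30+30 samples; distal power
uses the default 180-animal cohort with 1000 genes over 20 generator
seeds; bootstrap coverage uses 500 replicates of 20+20 samples at
dispersion 0.2; inheritance recovery uses 100 simulated cohorts. These
sizes give Monte-Carlo error comfortably below the asserted tolerances.

## Known limitations

* The LRT relies on the chi-square approximation; no exact small-sample NB
  test is provided, and group sizes below ~4 are filtered rather than
  tested.
* No covariates beyond CN state (no batch, no kinship correction in the
  expression or phenotype models).
* The distal multiple-testing correction is plain BH over all tested
  pairs; permutation-based FDR schemes are not implemented.
* Compensation is quantified for losses only; gains would need a
  different normalization of the expected ratio.
* Quasi-likelihood dispersion variants are not implemented; the shrinkage
  prior (10 observations) is fixed, not estimated.
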