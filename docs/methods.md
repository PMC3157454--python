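# Methods

## The measurement model

Two reciprocal F1 crosses are sequenced: Col×Ler (Col mother) and
Ler×Col (Ler mother). For a gene with `n1` informative reads in the
first cross and `n2` in the second, the Col read counts are modelled as
independent binomials, `X1 ~ Bin(n1, p1)` and `X2 ~ Bin(n2, p2)`. The
no-imprinting null fixes both Col fractions at the tissue's parental
genome dosage: `(1/2, 1/2)` in the diploid embryo and `(2/3, 1/3)` in
the triploid endosperm (two maternal : one paternal genomes). The exact
fraction 2/3 is used throughout, never the printed rounding 0.67.

One library per tissue per cross is assumed (no replicate-aware or
beta-binomial overdispersion modelling; that is an explicit non-goal).

## Exact unconditional imprinting test

The test must handle an *asymmetric* point null, for which the classic
equal-proportions construction is not directly applicable. The default
ordering works on dosage-adjusted Col fractions: with maternal weight
`w = p2_0/p1_0` (1/2 in endosperm, 1 in embryo),

    f1(i) = w·i / (w·i + (n1 − i))        (Col is maternal in cross 1)
    f2(j) = j / (j + w·(n2 − j))          (Ler is maternal in cross 2)

Both fractions are centred at 1/2 under the null, the statistic is
`T = |f1 − f2|`, and the p-value is the exact sum of
`Bin(i; n1, p1_0)·Bin(j; n2, p2_0)` over all outcomes with
`T(i,j) ≥ T(x1,x2) − 1e−12` (the absolute tolerance makes floating-point
ties count as extreme). For the embryo this reduces to the classic
`|p̂1 − p̂2|` ordering. Three properties motivated choosing this
ordering over the raw deviation statistic
`|(p̂1 − p1_0) − (p̂2 − p2_0)|` (which remains available via
`statistic="deviation"`):

1. it is exactly invariant to pure strain effects — a common Col:Ler
   odds fold shifts `f1` and `f2` identically, so cis effects do not
   leak into the imprinting test;
2. its realised type-I error at nominal 0.01 under the endosperm null
   (negative-binomial depths, mean 50/cross) is ~0.009;
3. on the published per-cross counts of previously known imprinted
   genes it reproduces the printed p-value behaviour closely (e.g. the
   low-count maternal gene whose printed p is 3.59e-03 gets 3.33e-03
   here; the deviation ordering gives 0.016 and would change its
   category).

Degenerate inputs: `n1 = 0` or `n2 = 0` gives p = 1 (a single cross
carries no reciprocal information). The statistic is separable and
monotone in each count, so the two tails are evaluated with sorted
cumulative sums in O(n log n); counts up to ~2×10^4 per cross are
tested directly. A full-grid O(n1·n2) enumeration oracle (in the test
suite and the acceptance script) verifies the fast path exactly.

The cis test uses the classic pooled construction on the *maternal*
counts — `a1` of `n1` versus `b2` of `n2` — since equal maternal
fractions across crosses characterise "no strain effect" at any degree
of imprinting, with outcome probabilities at the pooled estimate.

BH correction is applied across the genes meeting the informative-read
floor (the tested universe); the calling threshold applies to raw p by
default with q reported alongside, switchable to q via
`CriteriaConfig.use_adjusted_p` — the source criteria are phrased as
p-value cutoffs even though BH is computed, so both must be available.

## Fold factors

Confidence-bound factors express effect size independently of depth.
All use a Katz-type normal interval on a log ratio with Haldane
pseudocount 0.5, applied after dosage adjustment so the null log-ratio
is centred at zero:

* imprinting factor: `exp(|log(r1/r2)| − z·SE)`,
  `SE = sqrt(Σ 1/adjusted count)`, z = 1.96 (95% CI); direction is
  maternal when `r1 > r2`;
* cis factor: `exp(|log(r1·r2)|/2 − z·SE/2)` (confident geometric-mean
  Col:Ler fold);
* DE factor: the same construction on upper-quartile-normalised counts.

A cross with zero reads yields factor 0. The choice of interval was
pinned by two published behaviours it must reproduce simultaneously: a
low-count gene that passes p < 0.01 yet has factor < 2 (13,0 | 6,16
gives 0.87), and a very deep, weakly biased gene (15,636 reads, 37%
paternal) whose factor is ≈ 1.25. Wilson- or Clopper–Pearson-based
ratio intervals did not reproduce both.

## Calling criteria

`low_info` below 15 informative reads (combined crosses, inclusive);
candidate when p < 0.01 and factor ≥ 2 (inclusive); `cis_dominant` when
additionally `q_cis < 0.01`, cis factor ≥ 2 and cis factor > imprinting
factor (the source analysis only says a few genes with strong cis
effects were removed, so the conjunctive rule and thresholds are
configurable); otherwise MEG/PEG by direction. The seed-coat filter
runs between the p-value stage and reporting: MEG candidates with
reference log2(seed coat) − log2(tissue) strictly greater than 1.04 are
demoted with a recorded reason. The threshold is strict-greater so that
"less than 1.04" defines the kept mass; a data-driven alternative (95th
percentile of candidate-PEG differences, requiring ≥ 20 PEGs for
stability) is provided, with the fixed 1.04 as default. Genes lacking
reference data are retained, and PEGs are never filtered — maternal
contamination can only hide them.

## Read counting

Reads are classified from SAM via pysam. A read counts when it is
uniquely mapped (MAPQ above a configurable floor, default > 0, or an
explicit NH=1 tag — the closest SAM-level proxy for discarding
equal-score multi-mappers) and its aligned blocks intersect the exon
union of exactly one gene. At each overlapped SNP the read base is
compared with the Col and Ler alleles; all SNPs must agree, a third
allele or a mixture is `conflicting` (conservative: such reads are
tallied but never counted as either strain), no SNP is `ambiguous`.
Positions under deletions or introns are skipped. Coordinates are
0-based half-open internally; SNP tables 1-based, GFF3 1-based
inclusive, BED 0-based half-open. The SNP input is a single pre-merged
table — when upstream sources disagree at a position, the precedence
rule is the caller's responsibility. SNPs whose known consensus support
is below 0.95 are dropped (inclusive boundary; missing support is
kept).

## Differential expression

RPKM is `10^9 · count / (length · total_unique_reads)`. DE between two
libraries compares a gene's counts against the ratio of the libraries'
75th-percentile counts (loci with zero counts in both excluded; linear
interpolation between order statistics) with a two-sided Fisher's exact
test on `[[c1, c2], [round(q75_1·S), round(q75_2·S)]]`. The reference
row's magnitude is not pinned by the source description; S defaults to
making the larger entry ≈ 1000 and is exposed as a sensitivity knob —
only the null behaviour (p = 1 at equal normalised ratios) is
guaranteed. Pearson/Spearman library correlations are provided as a QC
utility only.

## Genomic context

A gene is DMR-associated when any DMR intersects the gene span extended
by 2 kb on either side (half-open intersection). Enrichment compares
the imprinted set's association count against the mean over 1,000
seeded random draws of equally many informative genes (a single-draw
expectation is too noisy to be reproducible), with a two-sided Fisher's
exact test on the observed-vs-expected table. Mini-clusters chain genes
whose boundary-to-boundary distance is ≤ 10 kb (single linkage, which
for intervals equals the transitive closure of the pairwise predicate);
the anchor is gene boundaries, not midpoints, since the source phrase
"within 10 kb of one another" does not define one. Clusters report an
adjacency flag when no other informative gene lies between consecutive
members.

## Synthetic data

The generator emulates the study conditions rather than idealised data:

* depths: negative binomial, mean 50 informative reads per gene per
  cross, dispersion 2 — overdispersed so a realistic share of genes
  falls below the 15-read floor, and combined depths span roughly
  10–400;
* classes: 5% MEG, 2% PEG, 2% cis by default (MEGs outnumber PEGs, a
  minority of the transcriptome is imprinted);
* effects: per-gene maternal fractions Uniform(0.85, 1) for MEGs and
  Uniform(0, 0.40) for PEGs — partial imprinting is the default,
  complete imprinting the extreme; cis folds 2^±Uniform(0.5, 2);
* contamination: `kappa` is the mass fraction of maternal seed-coat RNA
  in the dissected sample. Contaminant reads are 100% maternal-strain
  (Col in cross 1, Ler in cross 2) and are allocated across genes in
  proportion to seed-coat expression, normalised so the
  transcriptome-wide contaminant fraction is ~kappa. The contaminant
  pool is dominated by a strongly seed-coat-enriched gene set (10% of
  genes at 8–256-fold, log2 excess 3–8, the storage/protective
  transcripts that dominate seed-coat RNA); this matches the causal
  account that contamination traces to genes *highly* expressed in the
  seed coat and reproduces the key asymmetry — contamination fakes
  MEGs, never PEGs, and the affected genes are exactly those the
  reference-expression filter can see;
* reference expression: log2 scale; strongly enriched genes exceed the
  1.04 threshold by construction; missingness (default 15%) is
  concentrated on the weakest-expressed genes, as array probes fail
  mainly for low-expression loci — uniform missingness would leave
  contaminated genes unfilterable at a rate no threshold could fix.

What the generator does **not** model: transcript structure, sequencing
error, mappability variation, replicate structure, or correlation
between expression level and informative depth. Passing recovery tests
therefore demonstrate the statistical pipeline's behaviour under the
assumed binomial sampling model, not robustness to alignment artefacts
or overdispersed allelic noise in real libraries.

Read-level fixtures place one 36 bp read per informative count so that
each read overlaps exactly one SNP of one single-exon gene; counting
the resulting SAM recovers the generating table exactly, which is the
round-trip oracle for the counting stage.

## Problem sizes and determinism

All randomness flows through seeded `numpy` generators; identical
config + seed give byte-identical outputs, and the pipeline manifest
records parameters, seed and input checksums. The simulation-based
checks use 10,000 genes for null calibration and 2,000 genes for
recovery and contamination studies — sizes at which the measured rates
are stable across seeds (null p<0.01 rate 0.008–0.011, recovery
sensitivity 1.0, post-filter MEG FDR 0.00–0.03) while the full suite
runs in about a minute.

## Known limitations

* The exact ordering the original analysis used for the asymmetric
  endosperm null is not recoverable; printed p-values are matched in
  category and magnitude, not digit-for-digit.
* Whether the published confidence interval was computed on raw or
  dosage-adjusted ratios is inferred from reproduced behaviours, not
  stated.
* The binomial model ignores read-level dependence (overlapping
  fragments, PCR duplicates); with one library per condition, true
  biological overdispersion is not estimable.
* The headline gene counts of the original study require its raw
  sequencing data and microarray reference and are out of scope here.
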