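# Methods

This note documents the models, parameters and numerical conventions
behind `zwstrata`, and what the simulator does and does not emulate.

## The biological model

Females of a ZW species are the heterogametic sex (ZW), males are ZZ.
Three consequences drive the pipeline:

* **Z-specific regions** (W homolog lost or too diverged to co-assemble)
  appear at half depth in a female genomic library: log₂(F:M) ≈ −1.
* **Young ZW strata** stopped recombining recently; Z and W still
  co-assemble (full female dose), but fixed Z/W differences show up as
  sites heterozygous in every female sample and homozygous in every male
  sample ("ZW-consistent").
* **Dosage**: females carry one copy of every Z-specific gene.  Without
  compensatory regulation, female expression of the Z is halved
  (median F:M ≈ 0.5); full compensation equalizes the sexes.

The mirrored patterns (pseudo-X coverage at +1; XY-consistent SNPs)
cannot occur in a true ZW system, so their rates measure noise.

## Coverage assignment

Scaffolds are filtered before any ratio is formed: length strictly
greater than `min_len` (default 5 000 bp; 1/2/10 kb available for
sensitivity checks), depth in the homogametic reference sex (male for ZW,
female for the pseudo-X control) at least ¼ of that sex's genome-wide
average, and depth in each sex at most 4× its average.  The ¼ floor keeps
hemizygous scaffolds (≈ ½ dose in the other sex) while dropping
unsequenced or repeat-collapsed scaffolds.  "Average" is the
length-weighted mean depth by default; an unweighted per-scaffold median
is available via `center="median"` since either summary is defensible and
they differ little on real data.

log₂(F:M) is centered on its unweighted median across retained scaffolds,
which makes every assignment invariant to global library-size differences
(adding a constant to all ratios changes nothing).  Zones are offsets
from that median: Z = [−2, −0.5] closed on both ends, autosome =
(−0.5, +2) open — an exact-boundary scaffold goes deterministically to Z.
Three stricter presets (`t1`–`t3`, Z upper bound −0.6/−0.7/−0.8 with the
autosome floor moved symmetrically) support robustness sweeps; by
construction the Z call set shrinks monotonically across them.
Scaffolds removed by the filters are reported as `filtered`, retained
scaffolds outside all zones as `unassigned`, so the output is a partition
of the input.

## Genotypes and young-stratum detection

Sites are biallelic SNPs with per-sample allele depths (AD).  Site-level
QUAL must strictly exceed 20 (the flag applies the filter at the site,
not per-genotype, since only one quality is available in the input);
per-sample observations need ≥ 10 reads or they are treated as missing.
Genotype calls use the alt-read fraction *a*: hom-alt if a ≥ 0.85,
hom-ref if a ≤ 0.15, het only if the minor fraction strictly exceeds
0.30.  The band (0.15, 0.30] is deliberately a no-call: pooled samples
inflate spurious heterozygote calls, and the stricter 30% rule is applied
on top of the homozygote floors without inventing a genotype.  All
threshold comparisons use integer arithmetic on read counts (e.g.
`10·minor > 3·total`), because floating-point division makes a minor
fraction of exactly 30% appear to "exceed" 30% for some depths.

A site is ZW-consistent when all four female pools are het and all four
male pools are homozygous; any missing or no-call among the eight pools
makes it unassessable.  Only scaffolds the coverage step classed
`autosome` are scanned (Z-specific scaffolds are already found by
coverage; filtered scaffolds have unreliable depth).  A scaffold is
flagged as putative young stratum when it has ≥ 10 assessable SNPs of
which ≥ 20% are consistent.  Scaffolds with fewer than 10 assessable
SNPs are undetectable by construction — a real sensitivity floor of the
method, visible in the simulator as occasional misses on short scaffolds.

Flagged-scaffold consistent SNPs are cross-validated in the two DNA
individuals (both must yield a call at ≥ 10 reads; the same depth rule as
RNA, since only "sufficient coverage" is specified upstream) and compared
against the genome-wide DNA validation rate of all assessable RNA SNPs
with a Yates-corrected Pearson χ² on the 2×2 table, continuity correction
`max(0, |O−E|−0.5)` per cell, df = 1 (the R `prop.test` convention).  The
statistic is computed from the explicit formula rather than delegated to
a library so the test suite can cross-check it against an independent
implementation.  The two groups are treated as independent samples even
though one is a subset of the other, reproducing the published
convention.  The reverse control repeats everything at XY polarity and
compares, between polarities, the fraction of consistent SNPs that land
on flagged scaffolds.

## Expression analysis

RPKM = count · 10⁹ / (length · library size), with library size the
per-sample total count (the natural denominator when only a count matrix
is available).  Quantile normalization is applied within each tissue over
all four samples jointly: each sample's sorted values are replaced by the
across-sample mean of sorted values, ties receiving the mean of their
tied positions via average ranks.  With continuous expression values this
is idempotent and leaves every column with an identical multiset; exact
ties (e.g. many zeros) make both properties only approximate under the
mean-of-ties convention — a known, accepted limitation.

Genes are "expressed" in a tissue when RPKM ≥ cutoff (default 1; 0/2/5
for sensitivity) in all four samples.  Replicates are then averaged per
sex and a second quantile normalization across the two sex columns makes
the remaining female–male differences purely rank differences.  Wilcoxon
rank-sum tests (two-sided; exact enumeration below combined n = 25 when
tie-free, tie-corrected normal approximation otherwise; completely tied
input returns p = 1) compare F vs M on Z, F vs M on autosomes, Z vs A
within each sex, and the per-gene log₂(F:M) ratio distributions of Z
versus autosomal genes.  Ratios need no pseudocount because the
expressed filter removes zeros; unpaired tests are used throughout since
the Z and autosomal gene sets are disjoint.

Sex-specific genes: RPKM strictly below 0.1 in both replicates of one sex
and strictly above 1 in both replicates of the other, per tissue, on the
un-averaged normalized matrix.

Sex-biased genes use a deliberately simple DE stand-in, clearly labeled
non-DESeq2 in all outputs: median-of-ratios size factors, one
gamma-Poisson overdispersion φ moment-estimated from replicate scatter
pooled across genes (E[var] = μ + φμ² within each sex, genes with μ > 5),
and a per-gene Wald test on the log fold change with variance
(1/μ + φ)/n per group, BH-adjusted (`statsmodels`), significant at
padj < 0.05.  A rank test is impossible here — with 2 vs 2 samples its
smallest two-sided p is 1/3 — so the normal-approximation score route was
the only workable one.  The contribution being reproduced is the
thresholding policy, not the estimator; on simulated data the stand-in
controls the FDR at the nominal level and recovers 8-fold effects at
depth ~30× with recall ≈ 1.

## qPCR ΔΔCq

Per individual, ΔCq = mean Cq(target) − mean Cq(reference genes);
technical replicates average first.  The calibrator is the female-group
mean ΔCq (which sex anchors the calibrator is arbitrary and unstated
upstream; the female group was chosen, making the female mean fold 1 by
construction).  Fold = 2^(−ΔΔCq), i.e. amplification efficiency is fixed
at 100%; no efficiency correction is attempted.  The male:female ratio is
the geometric mean of male folds — scale-free in Cq, so adding a constant
to every Cq changes nothing.  Call windows are a design choice, not an
estimate: male:female fold in [1.5, 3.0] → Z-linked, [0.67, 1.33] →
autosomal, otherwise indeterminate; the gap bands avoid overconfident
calls near the midpoint.

## The simulator

`SimConfig` defaults define the validation conditions: 500 scaffolds
(430 autosomal / 50 Z / 20 young-Z), lengths uniform on 6–60 kb, female
28× and male 30× depth, four 5-individual pools per sex, one DNA
individual per sex from a line inbred by six generations of full-sib
mating, 2 tissues × 2 sexes × 2 replicates of RNA-seq, 2 000 transcripts
(lengths uniform 500–3 000 bp).

* **Coverage**: expected depth = sex depth × dose (dose ½ for females on
  Z, 1 otherwise) × one log-normal per-scaffold factor with
  CV = `depth_dispersion` (default 0.2) shared by both sexes — scaffold
  effects such as mappability and GC hit both libraries alike and cancel
  from the ratio — plus independent Poisson read sampling (100-bp reads),
  which is what actually perturbs log₂(F:M) and shrinks with scaffold
  length and depth as in real data.  `depth_dispersion = 0` short-circuits
  to exact expected depths so noise-free closed forms hold exactly.
* **Variants**: site counts are Poisson at `snps_per_kb` (default 3/kb,
  a realistic transcriptome-SNP density for a highly polymorphic
  crustacean and comfortably above the pipeline's 10-SNP floor for 6-kb
  scaffolds).  On young-Z scaffolds a fraction `zw_fixed_fraction`
  (default 0.5) of sites are fixed Z/W differences (true allele fraction
  0.5 in every female pool, 0 in male pools); everything else is ordinary
  polymorphism with the allele frequency drawn uniform on (0.1, 0.9) and
  pool allele counts binomial over 10 chromosomes.  The *intended*
  genotype call is derived from the true pool fraction, flipped with
  probability `genotyping_error` (het↔hom), and read depths are then
  binomial draws rejection-sampled into that call's region — so
  `genotyping_error` is the single source of call noise and error-free
  young-Z sites classify ZW-consistent with probability 1.  DNA
  individuals follow Hardy–Weinberg with heterozygosity scaled by (1−F),
  F from the full-sib recurrence F_t = ¼(1 + 2F_{t−1} + F_{t−2});
  F₆ = 0.734375, i.e. a ~73% heterozygosity reduction (the often-quoted
  "80%" for six generations does not follow from the recurrence; the
  recurrence is used).  `dna_missing_rate` (default 0.3) blanks DNA
  depths to mimic incomplete genomic coverage of transcriptome SNPs.
* **Counts**: per-transcript baseline log-normal (median 50 per kb,
  σ = 1), expected counts proportional to transcript length, per-tissue
  gene effects, gamma-Poisson overdispersion (φ = 0.05), ±10% library
  factors.  `compensation_scenario="none"` halves female expression of
  Z-linked transcripts; `"full"` leaves it equal.  `sexbias_fraction` of
  transcripts get `sexbias_fold` in their biased sex.
* **qPCR**: Cq = per-gene baseline − log₂(copies/2) + N(0, 0.1²);
  Z loci have 2 male / 1 female copies, references and autosomal loci
  2/2.

One RNG stream per artifact is spawned from the master seed, so each
output can be regenerated independently; identical configs give
byte-identical files.

What the simulator does **not** emulate: read-level artifacts (mapping
bias, duplicates, GC curves), indels and multi-allelic sites, linkage
between SNPs, recombination maps, allele-specific expression, and
between-tissue correlation structure beyond a shared gene effect.
Passing the recovery tests therefore demonstrates that the pipeline's
logic is correct under its own stated assumptions — not that those
assumptions hold for any particular real dataset.

## Validation scale

The recovery properties are run at the defaults above: 10 seeds × 500
scaffolds for coverage (precision and recall ≥ 0.95 required; observed
1.0), 10 seeds for the young-stratum scan (≥ 90% flagged, ≤ 1 autosomal
false positive per genome, XY control ≈ 0; observed ~98%, 0, 0), and 10
seeds per compensation scenario for the expression contrast (full:
F-vs-M on Z non-significant in ≥ 9/10; none: p < 0.01 in 10/10 with
median Z F:M ≈ 0.5).  These sizes keep the whole suite around a minute
while leaving the binomial error on each rate well inside the asserted
margins.
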