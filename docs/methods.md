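# Methods

`cernet` implements a competing-endogenous-RNA (ceRNA) inference pipeline for
a two-group bulk RNA-seq design — aged rats with erectile dysfunction (A-ED)
versus aged negative controls (NC) — together with a synthetic-data generator
that plants a known ceRNA truth network, so every stage of the pipeline can be
validated end to end without external data.

## The ceRNA model and the three screens

Under the ceRNA hypothesis a lncRNA that shares miRNA response elements with
an mRNA competes for those miRNAs ("sponges" them), de-repressing the mRNA.
The observable signature in expression data is: miRNA anti-correlated with
both partners, the partners positively co-expressed, and a larger-than-chance
overlap of their targeting miRNA sets.  The pipeline screens differentially
expressed features in that order:

1. **Anti-correlation.**  A predicted (miRNA, lncRNA) or (miRNA, mRNA) target
   pair is kept iff the Spearman rank correlation (SCC, mid-ranks for ties)
   across all samples of both groups is strictly negative.
2. **Co-expression.**  A (lncRNA, mRNA) pair sharing at least one surviving
   miRNA is kept iff the Pearson correlation (PCC) is strictly above 0.5.
3. **Sponge overlap.**  With N the universe of differentially expressed
   miRNAs present in the screened target table, K of them sponged by the
   lncRNA, n targeting the mRNA and x shared, the pair is retained iff the
   hypergeometric upper tail P[X >= x] is below 0.05.

Design choices that were genuinely open:

* The hypergeometric test is read as the **over-representation (upper) tail**:
  the procedure looks for significantly *many* shared sponges; the lower tail
  would reward disjoint target sets.  The tail is computed in exact integer
  arithmetic (`math.comb` rationals) so that it agrees with exhaustive draw
  enumeration exactly, and the *same* implementation backs the gene-set
  enrichment p-value.
* The universe N is the set of differentially expressed miRNAs appearing in
  the screened target table, and K/n are counted **after** the SCC screen
  (a target only counts as a sponge if it is anti-correlated), matching the
  step ordering of the procedure.
* Correlations are computed on **log2 TMM-normalized expression**
  (`log2(normalized count + 0.5)`) pooled across both groups.  Raw counts are
  heavily skewed under negative-binomial noise and their Pearson correlation
  is dominated by outliers; the log scale is the field's standard
  co-expression scale.  Group-mean separation is deliberately part of the
  signal — per-group correlation at small n would be hopelessly underpowered.
* No multiple-testing correction is applied to the sponge p (the filter is a
  raw p < 0.05); BH-adjusted values are available everywhere they are
  reported.
* Constant (zero-variance) expression profiles make a correlation undefined;
  such pairs fail the screen rather than erroring the run.
* Direction consistency is annotated on nodes, not enforced: the method does
  not forbid mixed up/down networks.

## Differential expression

Between-sample normalization uses TMM (trimmed mean of M-values): reference =
sample whose 75th CPM percentile is closest to the mean; per sample, M-values
are trimmed by 30% per tail and A-values by 5%, and the scaling factor is the
precision-weighted mean of the surviving M-values (delta-method binomial
weights); factors are renormalized to geometric mean 1.

The test is a self-contained **negative-binomial exact conditional test** with
a common dispersion, in the variance convention var = mu + phi mu^2:

* counts are rescaled to a common effective library size; the common
  dispersion phi is a pooled method-of-moments ratio estimator over all
  features and both groups, sum(v - m) / sum(m^2 - v/n), floored at 1e-8;
* a group sum of n i.i.d. NB(mu, phi) counts is NB(n mu, phi/n); conditioning
  on the (rounded) total gives a one-dimensional discrete distribution that is
  enumerated over its full support;
* the two-sided p doubles the smaller tail (observed point included in both),
  capped at 1.  log2 fold changes (A-ED over NC) use a pseudocount of 0.5.

This is a defined replacement for an edgeR-style analysis, not a re-implementation:
numerical agreement with edgeR is a non-goal; the contract is calibration
(null p-values uniform, rejection rate at the nominal level) and recovery of
planted effects, both of which the acceptance suite measures.

Filters follow the study design: miRNA/mRNA differential expression at
|log2FC| > 2 and p < 0.05 (both strict); lncRNAs additionally have a qPCR
candidate window of mean raw count strictly between 1 and 120 with fold
change > 2.  "Count number" is read as the mean raw count across all
sequenced samples — the window is a lowly-to-moderately-expressed band where
validation is practical.  Filters use raw p as stated; FDR is always reported
alongside.

## Raw-read QC

A read is kept iff it contains no adapter as an exact substring (no trimmer or
mismatch tolerance is defined, so the adapter list is an input), at most 10%
of its bases are N, and at most 50% of its bases have Phred quality <= 20.
"More than" is read strictly, so the boundaries are kept; failures are
attributed to the first failing rule in that order; reads are kept or dropped
whole.  FASTQ is the 4-line Phred+33 dialect.

## Phenotype and qPCR arithmetic

The erectile-function readout is the ratio of maximal intracavernous pressure
to mean arterial pressure (ICP/MAP); animals below 0.35 are A-ED, above 0.35
NC, and an animal exactly at the threshold is flagged unassigned because both
groups are defined with strict inequalities.  qPCR fold changes use the
2^-ddCt method normalized against beta-actin: replicates are averaged on the
Ct scale, dCt = Ct_gene - Ct_reference per sample, ddCt subtracts the
calibrator (NC) group's mean dCt.  Two-group comparisons use Welch's t
(unequal variances — the safer default) or Mann-Whitney (exact for combined
n <= 20 without ties, otherwise tie-corrected normal approximation); "auto"
requires Shapiro-Wilk non-rejection at alpha = 0.05 in both groups for the
t-test.

## What the generator emulates — and what it does not

`simdata` emulates the two-group corpus-cavernosum experiment: NB counts with
log-uniform per-feature baselines, log-uniform per-sample library-size
multipliers (so normalization has real work to do), planted ceRNA modules,
i.i.d. background miRNA targeting with 1–3 pseudo-tool votes per pair, gene
sets seeded with planted mRNAs, a 7/15 ICP/MAP cohort, qPCR plates with
per-sample Ct offsets, and reads with disjointly planted QC failures.  A
single seed drives all fixtures through documented `SeedSequence` stream
splitting.

Reference condition (the generator defaults, used throughout the tests):
10 samples per group; 120 lncRNAs, 120 miRNAs and 1,820 mRNAs of which 20
modules (one lncRNA, one mRNA, 4 sponge miRNAs each, drawn from a pool of 20
down-regulated miRNAs) carry 6-fold effects (miRNAs 1/6); NB dispersion 0.1;
baselines log-uniform on [20, 2000] (moderately-to-highly expressed features,
as after detection filtering); background target density 0.05; library
multipliers log-uniform on [0.5, 2].  Each planted pair shares a *set* of
sponge miRNAs because a single shared miRNA can never reach significance in
the hypergeometric filter (x = K = n = 1 in a universe of 20 gives
p = 1/20 = 0.05, not < 0.05): multi-miRNA sponging is both the biological
picture and the regime the overlap test is designed for.

What the generator does **not** model, hence what passing tests cannot show
about real data: miRNA repression is marginal (an opposite group fold change),
not kinetic, so correlation strengths are optimistic; there is no
gene–gene correlation beyond the planted modules and shared library size, no
GC/length bias, no outlier samples or batch effects; target tables have
uniform background error rather than tool-specific biases; sequences are
uniform random nucleotides.  Recovery numbers (mean F1 ~ 0.84 at the
reference condition, recall ~ 0.95, precision ~ 0.75) therefore characterize
the procedure under its own assumptions, not field performance.  The residual
false positives are cross-module pairs: all planted features are co-regulated
by construction, so pairs from different modules pass both correlation
screens and occasionally share enough sponge miRNAs to pass the overlap test
— exactly the false-positive rate the three thresholds imply.

## Numerical notes

* Hypergeometric tails are exact rationals converted to float once.
* The conditional NB enumeration rounds normalized group sums to integers;
  totals of zero give p = 1; a group with a single sample gets p = 1 and is
  flagged by precondition rather than tested.
* Ties in enrichment ranking are broken by set id; network assembly sorts
  pairs, making the graph independent of input order.
* The doubled-tail p-value is discrete; at the reference baseline range its
  null distribution is uniform to within KS tolerance at 10,000 features.
  At very low counts (totals of a few dozen) the test is conservative, as any
  non-randomized exact test is.

## Problem sizes

The test and acceptance workloads use the reference condition (about 2,000
features per run, 20 recovery seeds, 5 x 10,000-feature null calibrations),
sizes at which every statistical property under test is already stable; the
acceptance script uses 10 recovery seeds.
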