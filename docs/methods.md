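# Methods

This note documents the models, conventions and numerical choices
behind each stage of the pipeline, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Coordinates and interval conventions

All internal coordinates are 0-based half-open; GTF (1-based closed) is
converted on read, BED/narrowPeak is native. The midpoint of an
interval is `start + floor(length/2)`. Windows written as
"−a … +b around an anchor" are inclusive of both endpoints, so an
unclipped promoter window of −2000…+100 has length 2101 bp; windows
are clipped to chromosome bounds.

## Consensus ACRs and the stage partition

A stage's consensus accessible-chromatin regions are the maximal
intervals covered by at least one peak in *every* replicate of that
stage, computed by a coverage sweep over the merged per-replicate
intervals and then merged into contiguous runs. The wording "peaks
shared by all samples, merged" is ambiguous between
intersection-across-replicates and a union envelope of reproducible
peaks; intersection is the default because "shared by all" gates on
presence in every replicate, and a `mode="union"` switch provides the
other reading. No minimum-length filter is applied (configurable).

A stage's peak is **stage-specific** iff it has no ≥ 1 bp overlap with
any other stage's consensus set. **Common** peaks are represented in
the coordinates of a designated reference stage (the first stage by
default, i.e. the earliest time point) and are its peaks overlapped
(≥ 1 bp) by every other stage; this yields a single peak universe for
differential intensity testing. Both operations are verified against
per-base boolean-mask oracles on randomized toy genomes.

## Feature classification and annotation

Classification is by the position of the peak *midpoint*, not by any
overlap, which makes the five classes mutually exclusive and matches
distance-to-TSS reporting. Priority when windows overlap:
promoter > TTS > exon > intron > intergenic. Definitions:

| class | definition (strand-aware) |
|---|---|
| promoter | TSS − 2000 … TSS + 100 |
| proximal promoter (sub-flag) | TSS − 1000 … TSS + 100 |
| TTS | TES − 100 … TES + 1000 (100 bp into the gene body) |
| exon / intron | exon union / rest of the gene body |
| intergenic | everything else |

The TTS window is our definition; the feature class is conventional but
rarely given explicit bounds. One TSS per gene record is used
(transcript-level annotation is out of scope). The nearest gene is the
one minimising |midpoint − TSS|, ties broken by lexicographically
smaller gene id; the reported distance is signed in gene orientation
(negative = upstream). Class percentages over any annotated set sum to
100 by construction.

## Permutation fold enrichment

For each of `n_perm` permutations (default 5000; tests and the
acceptance script use 1000–2000 for speed) one random region per real
peak is drawn with the same length, on a chromosome sampled with
probability proportional to chromosome length among chromosomes long
enough, start uniform over the valid range. Length-weighted chromosome
sampling makes positions genome-uniform, the behaviour of the standard
random-interval tools; a `chrom_weighting="uniform"` switch implements
the literal "random chromosome" reading. Random regions are not
excluded from overlapping real peaks or each other — no exclusion is
part of the model. Fold = observed class count / mean permuted class
count; the permutation standard deviation is reported alongside, so the
standard error of the expected count is `sd / sqrt(n_perm)` and
tolerance checks can be principled. Classes with expected count 0
report fold = NaN.

The normalised chromatin length is
`total peaks × chrom length / total genome length`; the values sum to
the total peak count, and their Pearson correlation with the observed
per-chromosome peak counts (r and r²) quantifies how far peak density
tracks chromosome length.

Peak lengths across feature classes are compared by one-way ANOVA and
Tukey's HSD (statsmodels); classes with fewer than two peaks are
excluded with a warning. Letter groups are the maximal cliques of the
"not significantly different at α" graph, so classes sharing a letter
are statistically indistinguishable.

## FPKM, filtering and the differential engine

FPKM = count × 10⁹ / (feature length × library size), with library
size taken from the sample sheet (total mapped fragments) when present
and column sums otherwise. The expression filter keeps genes with
FPKM **strictly** greater than 1 in at least 3 samples of at least one
stage; the boundary value 1.0 everywhere is therefore dropped.

Differential testing for both assays (peak intensity and gene
expression) is a per-feature negative-binomial Wald test rather than a
bit-exact reproduction of any external package:

1. **Normalisation** — median-of-ratios size factors over the features
   positive in all samples (fallback to library-size ratios with a
   warning), rescaled to geometric mean 1.
2. **Dispersion** — per-feature moment estimate
   `α = (s² − μ)/μ²` from the pooled within-group variance, floored at
   10⁻⁸. No shrinkage or empirical-Bayes step: with ≥ 4 replicates per
   group the moment estimate is adequate for calibration, and the
   simplification keeps the estimator transparent (a deliberate
   simplification relative to shrinkage-based tools).
3. **Effect and test** — log₂ fold change of normalised group means
   with pseudo-count 0.5 (handles zero groups); the Wald statistic uses
   the delta-method variance of the log means under NB(μ, α), referred
   to a Student-t distribution with the within-group degrees of freedom
   (n₁ + n₂ − 2) — the small-sample analogue of the asymptotic normal
   reference, which would be anti-conservative at n = 4 + 4.
4. **Multiplicity** — Benjamini–Hochberg over the tested features;
   all-zero features are excluded from testing and from the BH
   denominator. Directions: `up` iff padj < 0.05 and log₂FC > 1,
   `down` for the mirror image, else `ns`; positive log₂FC in the
   contrast "B vs A" means higher in B.

Under null simulations (NB mean 100, dispersion 0.1, 4 vs 4) the raw-p
rejection rate at 0.05 sits near 0.05, and a planted log₂FC of 2
(mean 50→200, dispersion 0.05) is recovered to within ±0.3 on average;
both are re-measured by the test suite and the acceptance script. The
implementation is also cross-checked against an independent NB-GLM
package on planted effects (effect-size correlation > 0.99).

## Promoter-ACR / expression integration

Peaks are mapped to a gene when their midpoint lies in the gene's
proximal promoter window; a midpoint inside several windows goes to the
nearest TSS (ties to the smaller gene id) so the map is a function.

**Length groups.** Genes are sorted by an ACR-length statistic
(`single` for one-ACR genes; `max` or `total` for multi-ACR genes) and
cut into near-equal thirds — bottom (shortest), middle, top. A run of
equal values straddling a cut cannot be split meaningfully, so the
whole run moves to the side that initially held the majority of it; an
exact 50/50 split goes to the lower group. With 90 distinct lengths
this gives 30/30/30; with a three-way tie across the first cut
(2 members below, 1 above) it gives 31/29/30. The assignment depends
only on ranks and tie structure, so it is invariant under monotone
relabelling and input order.

**Expression bins.** Stage-mean FPKM (mean over the replicates of the
stage under analysis) is cut into [0,2), [2,5), [5,10), [10,30),
[30,∞); bins are left-closed/right-open, so 2.0 falls in the second
bin — the source convention for boundary values is unstated and this
choice is ours. Group-by-bin tables are row percentages summing
to 100.

**Clustering.** Expression of differential genes is z-scored per gene
across all samples, averaged within stage, and clustered by k-means on
the stage profiles (default k = 6, 10 restarts, fixed seed); cluster
labels are renumbered by descending cluster size for determinism. The
clustering method is a free choice — heatmap-derived cluster structures
do not pin one down — and both the method and k are configurable.

**Overlap tests.** Significance of a two-set overlap is the upper tail
of the hypergeometric distribution; the universe is the set of
expressed genes after the FPKM filter (the natural reference population
when it is not otherwise specified). Verified against direct
combinatorial enumeration on small universes.

## Motif enrichment

Sequences come from midpoint ± 100 bp windows (length 200 bp when
unclipped). PWM probabilities get a 10⁻³ pseudocount, are renormalised
and converted to log-odds against the motif background (uniform by
default). The default score threshold is 80 % of the motif's maximum
achievable score, configurable per motif. Scanning covers both strands
(reverse-complemented matrix on the forward encoding); windows
containing N are skipped. A sequence is a *hit* when ≥ 1 position
reaches threshold (zero-or-one per sequence, the known-motif enrichment
convention), and per-motif significance is the upper-tail
hypergeometric probability on the pooled target + background 2×2,
flagged at p < 0.01. The default background is the common-peak
windows, configurable — enrichment of stage-specific windows is then
relative to constitutively open chromatin rather than to naked genome.

## The synthetic study generator

`acrkit.synthetic_data.generate` emits a complete miniature study from
one seed (a single `numpy` Generator drives everything; identical seeds
give byte-identical bundles):

- **Genome and genes** — 5 chromosomes totalling 3 Mb (i.i.d. uniform
  ACGT), 300 non-overlapping genes allocated proportionally to
  chromosome length, 2–4 exons each. The scale is deliberately small
  so that a full pipeline run takes seconds; all statistical structure
  (replication, dispersion, effect sizes) is kept at study-realistic
  values instead.
- **Peaks** — 400 common peaks shared by all 3 stages plus 40/80/160
  stage-specific peaks (echoing the increase of specific open chromatin
  over developmental time), lengths 200–800 bp; 30 % are placed with
  their midpoint in a gene's proximal promoter window (each mapping
  unambiguously to its gene), the rest intergenic, all mutually
  non-overlapping with a safety margin. About 8 % of promoter
  placements give an already-hit gene a second, shorter ACR, so > 90 %
  of promoter-ACR genes carry exactly one ACR.
- **Replicates** — each of 4 replicates per stage contains each truth
  peak with probability 0.9 and ±20 bp end jitter, plus 25
  replicate-private noise peaks placed in reserved positions (so they
  can never survive the all-replicate intersection). With
  reproducibility 1.0 and jitter 0 the pipeline recovers the truth
  coordinates exactly; at the noisy defaults consensus sets shrink
  (0.9⁴ ≈ 0.66 survival per stage), which is the intended behaviour of
  an all-replicates gate under dropout.
- **Counts** — common-peak counts are NB(base mean × stage multiplier,
  dispersion 0.05) with lognormal base means around 100; 15 % of common
  peaks carry a planted |log₂FC| = 2 in one of three stage patterns
  (late-up, late-down, mid-peak). Gene counts follow per-stage FPKM
  targets through exonic length and a lognormal library size
  (~2 × 10⁷): 180 differential genes follow six temporal archetype
  profiles (late induction, monotone rise, monotone fall, early fall,
  mid peak, mid trough), 10 % of genes sit below the expression filter,
  and genes with a promoter ACR get expression increasing with ACR
  length (so the length-group × expression-bin tables show the planted
  monotone trend).
- **Motif** — a 10-bp consensus is written into the genome at the
  centre of 50 % of the last stage's specific peak windows, and the
  matching PWM (0.88 consensus probability per position) is emitted in
  MEME format.

What the generator does **not** emulate: Tn5 insertion bias,
fragment-length structure, GC or mappability effects, read-level noise,
overlapping genes/alternative TSSs, and correlated replicate dropout.
Passing tests therefore demonstrate that the statistical machinery is
correct and calibrated under the stated model, not that the pipeline is
robust to every artefact of real chromatin data.

## Numerical conventions and degenerate inputs

- p-values are clipped into (0, 1]; BH-adjusted values never fall below
  their raw p.
- Correlations on zero-variance vectors raise a dedicated signal
  (chromosome correlation) or return NaN with a flag (per-gene
  intensity–expression correlation).
- Empty peak sets annotate to an empty table; a genome with no genes
  classifies everything as intergenic; fold enrichment for a class with
  expected count 0 is NaN.
- Equal-size ties in k-means label renumbering fall back to the
  original label order; nearest-gene and length-group ties are broken
  lexicographically — all outputs are deterministic for a fixed seed.

## Known limitations

- No dispersion shrinkage: with 2–3 replicates per group the moment
  dispersion becomes unstable; the engine requires ≥ 2 and is
  calibrated at 4.
- The common-peak universe uses reference-stage coordinates; peaks
  private to later stages that merely touch the reference peak set are
  not re-segmented.
- Peak "intensity" is read counts in peaks; peak-call scores are not
  used as intensity.
- GO/KEGG annotation, IDR analysis, blacklist filtering and figure
  rendering are out of scope; outputs are plain tables.
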