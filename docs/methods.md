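# Methods

This note records the statistical procedures `lncforge` implements, the
parameters that matter, the design choices that were genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Preprocessing

**Detection filter.** A probe is kept when at least `min_flagged_samples`
(default 6) of its detection calls are in the acceptable set (default
{Present, Marginal}). With a 6 + 6 design this is the "detected in at
least half the arrays" rule. Filtering is monotone in the threshold and
preserves row order.

**Quantile normalization.** Every sample's sorted intensities are
replaced by the across-sample mean of sorted intensities; ranks within a
sample are preserved. Ties receive the mean of the reference values over
their tied ranks. Two consequences worth knowing:

- On tie-free (continuous) data all columns end up with exactly the same
  value multiset and the transform is idempotent. With ties, the
  averaging rule deliberately breaks exact multiset identity (and hence
  idempotence) in exchange for a deterministic, order-independent
  treatment of equal values — the same behavior as
  `limma::normalizeQuantiles(ties = TRUE)`.
- The transform remaps distribution *tails* most aggressively. At array
  scale (tens of thousands of probes) the remapping error per value is
  small; at the few-hundred-probe scale of the synthetic fixtures it can
  compress a large planted effect (we measured one of 60 planted probes
  dropping from |log2FC| 3 to 0.8 on one fixture), and it perturbs
  between-probe correlations by far more than the 0.002 margin the
  strict network threshold allows. Pipeline-level tests therefore assert
  high (≥ 90%) rather than perfect planted recovery, and the network
  calibration test measures `build_network` on the intensities the
  closed form refers to.

**Order of operations.** Whether detection filtering precedes or follows
normalization is exposed as `filter_order`; the default is
normalize-then-filter. Both orders are supported because array software
pipelines differ and the choice is not derivable from the data model.

## Differential expression

Per probe: group means of log2 intensities, log2FC = mean(group 2) −
mean(group 1), linear FC = 2^|log2FC| ≥ 1, direction "up" when the
comparison-group mean exceeds the baseline (ties reported as "up" with a
warning). The test is a two-tailed two-sample *t*; the default is the
pooled-variance Student form, Welch available by flag. Degenerate rows
(zero variance in both groups) get *p* = 1 on equal means and *p* = 0
with a warning otherwise. Multiplicity is handled by the
Benjamini–Hochberg step-up, applied within the lncRNA and mRNA probe
families separately by default (they are analysed as parallel
experiments; a joint mode exists). Significance requires all three of
FC ≥ 2, *p* < 0.05, *q* < 0.05 — note FC uses ≥ (boundary passes) while
*p* and *q* use strict <.

Hierarchical clustering for heatmap export uses average linkage on
1 − Pearson distance; it is presentation support only.

## Positional classification

Gene models are collapsed to one merged exon set per gene; coordinates
are 0-based half-open internally (GTF converted on ingest). Classes are
assigned by precedence, most specific relationship first:

1. same-strand exon overlap → exon_sense_overlapping
2. same-strand gene-body overlap without exon overlap →
   intron_sense_overlapping
3. opposite-strand exon overlap → natural_antisense
4. opposite strand, fully inside the gene body, no exon overlap →
   intronic_antisense
5. no gene overlap, head-to-head: TSS-to-TSS distance strictly < 1000 bp
   with divergent orientation (each TSS on the other's upstream side) →
   bidirectional
6. otherwise intergenic.

Open choices, resolved and configurable: "within 1000 bp" is taken as
strict < on TSS-to-TSS distance (a locus at exactly 1000 bp is
intergenic); an opposite-strand locus that overlaps a gene body without
touching an exon but also without lying fully inside it matches no
antisense rule and falls through to intergenic; classification is
against genes, not individual transcripts, and is invariant to gene
duplication and exon order in the input. Subtypes follow from the class:
intergenic loci overlapping a supplied enhancer BED are enhancer_like,
other intergenic loci are lincRNA, the two antisense classes are
antisense, sense-overlapping and bidirectional loci are "other" (no
target route). No default enhancer annotation is shipped — enhancer
regions must be supplied explicitly.

## Co-expression network

Pearson correlation across all samples (both groups pooled — the network
describes the study, not one group), edges strictly above |r| = 0.998.
Zero-variance probes are skipped with a warning. Edges join one lncRNA
and one mRNA only; raising the threshold can only remove edges. Reported
r is rounded to 4 decimals in exports, full precision internally. At
n = 12 the null probability of |r| > 0.998 is ≈ 10⁻¹³, so chance edges
are essentially impossible; every edge reflects near-exact affine
dependence.

## Target linking

Distance is the gap between closest interval ends (0 when overlapping),
symmetric, with ≤ window inclusive — a gene at exactly 300 kb is linked.
The 300-kb window is applied on both sides of the lncRNA. The
enhancer-like route keeps adjacent genes with r strictly greater than
`min_r` (default 0, i.e. any positive correlation; a stringent mode can
demand larger r). The antisense route links the overlapped sense
gene(s) recorded by the classifier, one link per gene. In the default
"restrict to DE" mode, targets are limited to genes that are themselves
differentially expressed and present on the array.

## Enrichment and prediction

The 2×2 table is [list∩set, set∖list; list∖set, rest-of-universe], the
two-sided Fisher p sums all fixed-margin tables with point probability
≤ the observed one, and the enrichment score is −log10 p. Significance
uses raw p < 0.05 — no correction across pathways by default (BH behind
a flag) — and the universe defaults to all array gene symbols surviving
the detection filter. Note a two-sided test also flags *depletion*; the
synthetic null gene sets are drawn from the whole universe precisely so
that chance overlap, not designed depletion, determines their p-values.

Predictions join three tables. Network route: for each significant
pathway and direction, each lncRNA partnered in the network to one of
the pathway's mRNAs receives a record (one per lncRNA × pathway ×
direction, listing all supporting genes). Genomic route: enrichment is
re-run on the union of linked gene symbols per (subtype, DE direction),
and a lncRNA inherits only the significant pathways its own linked genes
belong to. Routes are kept distinct; the same lncRNA–pathway pair can
appear once per route.

## Clinical statistics

Kaplan–Meier product-limit curves (lifelines), two-sided log-rank with
the hypergeometric-variance form and simultaneous risk-set decrement on
ties, and Pearson's chi-square **without** continuity correction — the
uncorrected form is what reproduces the published sex-comparison p-value
(0.65; the corrected statistic gives 1.0). Cohort t-tests from printed
mean ± SD summaries use the pooled form; on the published rows pooled
and Welch round to the same two decimals, so the two are empirically
indistinguishable there. ΔΔCt: per sample ΔCt = Ct_target − Ct_reference
(reference gene GAPDH), ΔΔCt subtracts the reference group's mean ΔCt,
relative expression is 2^−ΔΔCt with the baseline group (no-penetration
samples) as reference by default.

## Synthetic data

The generators emulate the study design the pipeline targets: 2 groups ×
6 arrays; per-probe baselines N(8, 1.5²) log2 units with N(0, 0.5²)
sample noise; 40 planted DE mRNA probes at |log2FC| = 3, half up and
half down (balanced directions, as on the real array, so whole-column
distributions are not shifted); 20 planted lncRNA–mRNA pairs as affine
copies (slope ±1) of the partner profile plus N(0, σε²) noise — by
r = b·σx/√(b²σx² + σε²) with σx² = 0.5² + 3²/4 = 2.5, the default
σε = 0.05 targets r ≈ 0.9995, just above the 0.998 edge threshold; 30
lncRNA loci tiled one per 400-kb cassette on a synthetic chromosome,
each cassette carrying a 3-exon plus-strand coding gene and the lncRNA
placed to satisfy exactly its planted class (bidirectional at 501 bp
TSS-to-TSS, intergenic at 40 kb — adjacent but outside the 1-kb
window); enhancer regions covering 5 intergenic loci; one gene set
planted on the DE genes among 6 chance-level sets of 20; exponential
survival times with default hazards 1/126 and 1/82 per month
(administrative censoring at 150 months, emulating the published mean
survivals) and 10 subjects per group as in the published cohort; Ct
values N(mean, 0.3²) with planted ΔΔCt shifts (−2 cycles for EGF → 4×,
+1 for ABCC6P1 → 0.5×) against a GAPDH reference at 20 cycles. A tenth
of unplanted probes get detection-call probabilities below the retention
rule and fail the flag filter by design.

Everything is driven by `numpy.random.default_rng` seeded from the
config with one fixed stream per generator, so identical configs yield
byte-identical files; ground truth is written alongside as JSON.

What the synthetic fixtures do **not** emulate: realistic probe
sequences, spatial array artifacts, batch effects, correlated noise
between probes, multi-chromosome genomes, transcript isoforms, or the
real array's 58,944-probe scale. Passing tests demonstrate correctness
of the statistics and the joins under the planted model, not performance
on real arrays — in particular the quantile-normalization tail effects
discussed above are more severe at fixture scale than at array scale.

## Problem sizes and numerical choices

Test fixtures use 120 lncRNA + 200 mRNA probes (1050 for the DE power
simulations, 20 seeds), 20 planted pairs, 30 loci, 200 null survival
replicates and 100 power replicates at n = 50/50 — sizes chosen so the
full suite and the acceptance script each run in well under a minute
while keeping Monte-Carlo bands tight. Correlations are clipped to
[−1, 1] after the vectorized product; BH q-values come from statsmodels'
step-up; Fisher p from scipy's exact implementation (checked against
full fixed-margin enumeration in tests); inter-stage files are written
with fixed float formatting (`%.10g`) so reruns are byte-identical.

## Known limitations

- Guilt-by-association is correlational; records are hypotheses, not
  regulatory claims.
- No moderated-variance (limma-style) test, paired designs, or > 2
  groups.
- The strict 0.998 threshold is sensible only for small-n arrays where
  near-affine pairs exist; at larger n it would be vacuous.
- Enhancer-like classification depends entirely on the supplied enhancer
  BED; no enhancer prediction is attempted.
- qPCR efficiency correction and Cox regression are out of scope.
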