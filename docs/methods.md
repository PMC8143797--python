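# Methods

## Overlap statistics

The central statistic is the hypergeometric point density of an observed
gene-set overlap. With a population (gene universe) of `N` identifiers of
which `K` belong to the reference set, and a query set of `n` identifiers
overlapping the reference in `k`,

    P(X = k) = C(K, k) · C(N−K, n−k) / C(N, n),
    HGD      = −log10 P(X = k),
    tail     = P(X ≥ k)  (inclusive enrichment p-value).

All binomial coefficients are evaluated as log-gamma differences and
summed with log-sum-exp, so configurations whose densities underflow
doubles (HGD ≫ 300) are still exact to relative 1e-12 (verified against
rational-arithmetic enumeration in the tests). An impossible configuration
(`k > min(K, n)`) yields density 0 and an explicit `+inf` HGD sentinel,
never a silent overflow.

Two tail conventions exist in the wild: the inclusive enrichment p-value
`P(X ≥ k)` (the default here) and the strict upper tail `P(X > k)` that
some environments produce when the boundary is excluded. Both are exposed
(`mode="inclusive" | "exclusive"`); for strongly enriched overlaps they
differ negligibly because the density at `k` dominates the tail — on such
configurations `−log10(tail)` provably lies in `[HGD − 0.5, HGD]`, which
the acceptance tests check on randomized enriched designs.

**Population choice.** For expression comparisons the population is the
set of genes with mean raw count ≥ 5 across all samples of the experiment;
for peak-derived comparisons it is the set of genes annotated across all
conditions. The population size is always an explicit argument — the
package does not decide per-contrast vs per-experiment universes for the
caller.

## DEG sets and PCA

DEG filtering is purely `padj < α` (default α = 0.05); no fold-change
cut is imposed and overlaps are identifier-only by default (a
direction-restricted mode exists since concordance requirements are a
legitimate analysis variant). Missing adjusted p-values (the output of
independent filtering) count as not significant.

The variance-stabilizing step used before PCA is deliberately simple:
median-of-ratios size factors (over genes with all-positive counts)
followed by `log2(x + 1)`. A fitted dispersion-based transform would
change distances only marginally at the scales involved, and PCA geometry
(condition clustering) is all the transform feeds. PCA is computed by SVD
of the mean-centered sample matrix with a fixed sign convention (the
largest-magnitude loading of each component is positive) so coordinates
are reproducible across BLAS builds.

## Peak annotation

Coordinates are uniformly 0-based half-open; GTF input is converted on
read. The TSS is `tx_start` on + genes and `tx_end − 1` on − genes.
Distance is measured from the TSS to the peak **midpoint** by default
(`nearest-edge` is available); the sign is negative upstream of the TSS on
the gene's strand. The nearest gene minimizes `|distance|` with ties
broken by lexicographic gene id for determinism.

Categories are assigned by precedence: Promoter ≤1 kb (either side of the
TSS), Promoter 1–3 kb, then gene-body features, then Downstream ≤3 kb,
then Distal Intergenic. When gene models carry exons, the body splits
into 5'UTR (the 5'-most exon — no CDS information is assumed), Exon and
Intron; exon-free models collapse these into a single GeneBody category,
which is what the synthetic annotation produces. Peaks on chromosomes
absent from the annotation are Distal Intergenic with a null gene and are
excluded from gene-set assignment. The headline distance bins (0–1 kb,
1–3 kb, ≥3 kb from the TSS) summarize promoter-proximal vs
distal/enhancer-type binding.

TSS occupancy profiles count peak base pairs per bin across `[−W, +W]`
(default W = 3000, 100 bins) around each TSS, with minus-strand windows
reversed so upstream always plots left. Total profile mass is conserved
across binnings that tile the same window.

## Motif scanning

PWMs hold per-position counts; probabilities add a per-cell pseudocount of
`pseudocount · background(base)` (default pseudocount 0.1). Scores are
log2 odds against a 0-order background — by default the base frequencies
of the scanned peak sequences themselves, the conventional scanner
behaviour (uniform background by flag).

The p-value of a score is exact: per-position scores are integerized at
ε = 1/1000 bit and the full distribution of a random background word's
total score is built by dynamic programming; `P(score ≥ s)` is then a
survival-function lookup. Integerization error is bounded by `w·ε` in
score units, and the DP distribution matches exhaustive enumeration over
all `4^w` words to 1e-9 in the tests. Scanning reports hits on both
strands (reverse-complement scoring), skips windows containing N, and a
peak "contains" a motif when ≥1 window on either strand passes the
p-value threshold (default 1e-4; the proportion does not weight multiple
hits). Set-level enrichment is reduced to a 2×2 Fisher exact test of
peak flags vs control-sequence flags.

Because the per-window threshold is a free parameter, motif *proportions*
on real data are threshold-dependent; the package treats the threshold as
an explicit input rather than claiming one true value.

## Accessible-chromatin sets

Consensus peak sets union-merge per-sample intervals and keep merged
intervals supported (≥1 bp overlap) by at least `min_overlap_samples`
samples (default 2 of 3 replicates; the required replicate support is a
configurable choice). The baseline accessible-gene set is the
intersection of the focal condition with *all* controls (including empty
vector); condition-unique genes are the focal set minus the union of
controls. The binding-affinity matrix is counts-per-million then
`log2(x + 1)`, used only to reproduce sample-level PCA geometry —
negative-binomial differential accessibility testing is intentionally out
of scope, since the headline claims are set-based.

## Interactome cascade

Dotplot entry requires iProphet protein probability ≥ 0.95 and ≥10
spectral counts in at least one biological replicate (satisfiable by any
bait for a given prey, matching dotplot display semantics); trypsin,
biotin and streptavidin are excluded as contaminants. BFDR tiers are
≤0.01, ≤0.05, >0.05.

Interaction change vs the cognate full-length control is classified on
average spectral-count ratios with an explicit tolerance δ (default 0):
increased if `fusion > (1+δ)·full`, decreased if `< (1−δ)·full`; a prey
absent from the full-length dotplot is increased, absent from the fusion
dotplot decreased. The cascade then runs, per fusion: (a) subtract
decreased preys, (b) subtract known Hippo-pathway components (a
user-supplied list; the shipped default covers the core kinases,
adaptors and TEADs), (c) retain increased-only preys, (d) intersect the
two fusions' lists, (e) remove preys weak for *both* fusions — lowest
dotplot bin on both average count (≤12) and relative abundance (≤1) with
BFDR > 0.05; the bin edges are configuration values. Steps (a) and (c)
are kept distinct and both counts reported, so either reading of
"subtract decreased, then require increased" is auditable. The final list
is ranked by combined average spectral count.

## Screen scoring

Proliferation is summarized per replicate as the fold change
`absorbance(day 10) / absorbance(day 0)`. An shRNA is a deficit when a
Welch (unequal-variance) two-tailed t-test gives p < α against **both**
the shEV and shNT control constructs and its mean fold change is below
both control means (single-control and direction-free modes by flag). No
multiple-testing correction is applied across shRNAs — calls are
per-shRNA by design, and the gene-level ranking (number of deficit
shRNAs out of 5, ties by stronger deficit then gene id) is the primary
output. Under the null the two-control requirement bounds the per-shRNA
false-deficit rate near α²; the tests verify ≤ 2α² empirically.

## Synthetic designs

The generators plant the exact structures the pipeline measures and
return ground truth alongside the data. All randomness flows from one
seed through independent spawned streams per generator, so adding a
generator never perturbs the others and equal seeds give byte-identical
files.

Default design parameters encode the study conditions at desk scale:

- **Expression** (per panel): fusion DEG set of 1,000 genes in a universe
  of 6,000 (5,000 above the population threshold); planted overlaps 70%
  with the activated full-length program and 9% with the C-terminal
  partner program (8% triple), leaving 29% fusion-unique; the second
  panel plants 53% / 0.2% with a near-empty partner program. Adjusted
  p-values are drawn below/above the 5% threshold by construction
  (misclassification rate 0 by default, configurable); counts are Poisson
  around log-uniform means with 2^log2FC condition effects, biological
  triplicates per condition.
- **Peaks**: 500 peaks of 200 bp per condition (1,000 in the planted-rate
  recovery test), 30% in promoter windows (±800 bp of a TSS) and 70%
  distal (≥3 kb from every TSS), mutually non-overlapping so a planted
  motif word belongs to exactly one peak; TEAD consensus (ACATTCCA,
  97:1:1:1 counts) planted at rates 61/58/38/51% per condition.
- **ATAC sets**: baseline of 2,000 genes shared across all conditions,
  unique sets of 315/30/66/50 (focal/EV/FL1/FL2) — a ~1:10 scale of the
  reported panel sizes — with per-membership flip noise 0.005, chosen so
  recovery sits near Jaccard 0.98 (annotation jitter scale), not at 1.
- **BioID**: 68 high-confidence preys in categories sized so the cascade
  retains 64/38 → 55/34 → 49/31 → 47/28 → 27 → 18; enriched counts are
  gamma-mixed Poisson (mean 45), weak shared preys sit exactly in the
  lowest count/abundance bin with BFDR > 5%, and background preys violate
  the detection or probability filter by construction.
- **Screen**: 15 genes × 5 shRNAs × 3 replicates plus shEV/shNT;
  log-normal multiplicative growth with control day-10 fold change 5,
  effective shRNAs at effect ratio 0.4 (log-sd 0.05), three genes with
  5/5 effective shRNAs, three with 3/5, three with 1/5, six with none.
- **Integration**: bound-gene fractions 13%/15% of the DEG set and
  knockdown-DEG-in-unique-open fractions 71%/74% planted exactly
  (noise-free joins).

What the generators do **not** emulate: read-level data (alignment and
peak calling are upstream), genomic sequence composition biases,
correlated replicate structure beyond simple jitter/noise, batch
effects, or the dispersion structure of real count data. Passing the
planted-recovery tests therefore demonstrates correctness of the set
algebra, statistics and filtering logic under the stated designs — not
robustness to every artefact of real sequencing data.

## Numerical and design choices

- Combinatorics in log-gamma space; densities reported to full precision
  in JSON, percentages rounded for report tables only.
- `padj = 0` (upstream underflow) is floored at 1e-320 before −log10, so
  the significance axis caps at 320.
- Per-gene ChIP score is the maximum over assigned peaks (sum/mean are
  alternatives); peak scores come from the caller and are never
  recomputed.
- Nearest-gene ties and all rankings have deterministic lexicographic
  tie-breaks.
- The pipeline runner hashes each stage's input files and parameters;
  unchanged stages are skipped on rerun, and a failed stage is recorded
  without blocking independent stages (exit codes: 0 ok, 2 configuration,
  3 stage failure).
- Annotation builds are treated as user inputs; the package does not
  reconcile assemblies between modalities.

## Problem sizes

Tests and the acceptance script run at desk scale on one CPU: populations
of 5–6k genes, 500–1,000 peaks on a 1 Mb two-contig toy genome, 4^w
enumerations for motif widths ≤ 6, 20-seed recovery sweeps, and 10,000
null simulations for the screen false-call rate. These sizes were chosen
so the planted effects are far above sampling noise while the full suite
completes in well under a minute per module.
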