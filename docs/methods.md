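# Methods

This note documents the models, conventions and design choices behind
`ganopan`, in the order the pipeline runs them.

## Coordinates and file dialects

All internal coordinates are 0-based, half-open. GFF3 (1-based inclusive)
and VCF (1-based, padding-base anchored) are converted at the I/O
boundary and nowhere else; the conversions are exact round-trips. For
structural variants, a deletion/duplication/inversion called at VCF
`POS=p, END=e` occupies the internal interval `[p, e)` (the VCF position
is the padding base before the event), so its length is `e − p`. An
insertion at `POS=p` is a zero-length anchor at internal position
`p − 1`; translocation breakends (`TRA`/`BND`) are likewise points.
Records without a usable `SVTYPE` are skipped with a logged warning
rather than aborting, because SV exports routinely mix in annotation
records. Gene identifiers are case-sensitive throughout.

## Occupancy classification

Families are binned purely by occupancy. The default band scheme
generalizes the four-category design (core / softcore / dispensable /
private) to any panel size *N* ≥ 2: core = *N*, softcore = *N*−2 … *N*−1,
dispensable = 2 … *N*−3, private = 1. For *N* < 5 the softcore and
dispensable bands clamp to empty instead of erroring, so every family is
still classified. Singleton genes — genes placed in no family by the
orthology inference — are reported as a separate private-unit tally and
are excluded from the family denominator; with that convention the
percentages of a 13 487-family composition with per-band counts
5917/1937/5058/575 come out as 43.87 / 14.36 / 37.50 / 4.26.

## Rarefaction

Pan and core curves are computed over full genome orderings (sampling
orderings uniformly, not bootstrap-resampling genomes), because the
quantity of interest is "families seen after adding the *k*-th genome".
A single integer seed drives one generator for the whole run; orderings
are drawn independently and may repeat. `rarefy_exact` enumerates all
*N*! orderings for small panels and is the reference the Monte-Carlo
path is tested against. Within any ordering, pan is non-decreasing and
core non-increasing by construction; at *k* = *N* they equal the total
family count and the core-band count. The default number of sampled
orderings is 100; the choice is a display-smoothness trade-off, and the
sampling error at *N* = 15 is far below the curve's dynamic range.

## SV impact rule table

Impact is a pure function of (variant type, region, frame features).
Region priority within a gene is CDS > non-coding exon > intron; a
variant not touching the gene body falls to the promoter window (default
1000 bp upstream of the transcription start, strand-aware) and then the
downstream window (default 500 bp). The table:

| variant | region | condition | impact |
|---|---|---|---|
| DEL/DUP | CDS | removed/duplicated coding length mod 3 ≠ 0, or start/stop codon bases removed | high |
| DEL/DUP | CDS | in-frame, terminal codons intact | moderate |
| INS | CDS | inserted length mod 3 ≠ 0 | high |
| INS | CDS | in-frame | moderate |
| INV | CDS | a breakpoint strictly inside a CDS interval | high |
| INV | CDS | spans coding sequence without a CDS breakpoint (e.g. contains the whole gene) | moderate |
| TRA | CDS | breakend inside CDS | high |
| TRA | gene body | elsewhere in the gene | moderate |
| any | non-coding exon | UTR-equivalent | low |
| any | intron | entirely intronic | modifier |
| any | promoter/downstream window | regulatory | modifier |

An inversion that merely contains a gene is *moderate*, not high: the
coding sequence itself is preserved and orientation effects are
uncertain. With multiple transcripts the most severe call across
transcripts is reported (the usual "most severe consequence"
convention). Summaries count each SV once at its maximum impact across
genes, and each gene once at its maximum impact across SVs. SNP-level
consequence calling (amino-acid changes) is out of scope; the classifier
handles structural variants only.

The window lengths are configurable; the defaults (1000/500 bp) are
conventional choices for compact fungal genomes, where intergenic
distances are a few kilobases.

## Differential expression

The DE caller is a fully specified, dependency-light test rather than a
negative-binomial GLM: counts → CPM → log2(CPM + 0.5) → two-sided Welch
*t* per gene → BH step-up FDR across the tested genes. The log2 fold
change is `log2((mean CPM_A + 0.5) / (mean CPM_B + 0.5))`; the 0.5
pseudo-count bounds behavior at zero counts. A gene is a DEG when
|log2FC| > 1 and FDR < 0.05. This deliberately does not reproduce
DESeq2's shrinkage model; with four replicates per group and the
moderate dispersions typical of isogenic laboratory cultures, the Welch
test on log-CPM is a defensible and fully transparent alternative, and
the tests quantify exactly what it recovers (see below). Genes with zero
variance in both groups get p = 1 when the means agree.

Cross-genome comparisons operate on homolog groups: families with
exactly one member in each of the five expression-profiled genomes. The
gene × sample matrix is collapsed to group × sample by taking, for each
sample, the counts of the group's member gene in that sample's genome.
The pipeline's report-level DEG flag is the union of anchor-vs-other
calls over all four comparisons and both tissues; the recovery
statistics in the acceptance checks use a single comparison, because
union-flagging accumulates false positives across comparisons by design.

Expression breadth counts the genomes (0–5) in which a group's member
gene has mean CPM ≥ 1 (configurable) in the chosen tissue. The
per-category expression profile uses per-gene mean CPM within a tissue
and a Kruskal–Wallis omnibus test across the four categories — a rank
test, so no distributional assumption; categories with no genes are
omitted with a warning, and a fully degenerate input (all values
identical) reports H = 0, p = 1.

The SV–DEG association is a Yates-corrected chi-square on the 2×2 table
of SV-affected × DEG status over homolog groups, replaced by Fisher's
exact test when a margin is zero. The sporulation ratio utility is the
field's standard 100 × spore yield / fruiting-body dry weight, guarded
against non-positive weights (some strains yield too little spore powder
to measure).

## Enrichment

One-sided hypergeometric over-representation per GO term: with K of N
population genes annotated and k of n study genes hit, p = P(X ≥ k),
X ~ Hypergeometric(N, K, n). Terms are flagged at raw p < 0.05; a BH
column is reported but does not drive the flag. Associations are flat
gene → term sets: no ontology-graph propagation of ancestor terms is
performed (that would require an ontology file), which is the one
deliberate divergence from DAG-aware tools and is why reported per-term
counts can be smaller than a propagating tool's.

## Synthetic data generator

The generator emulates the structure of a 15-genome study with five
expression-profiled cultivars (S1–S4, S6; S3 is the anchor): an
orthogroup table with planted per-band family counts (defaults are the
full-scale composition 5917/1937/5058/575 and 368 singleton genes,
scaled by `scale`, default 0.05 ≈ 675 families so the suite runs in
seconds), occupancies drawn uniformly within each band and genome
subsets uniformly at random; non-overlapping intronless and two-exon
gene models laid out over 12 chromosomes; SVs planted on the anchor
genome from a menu of kinds whose intended (region, impact) class is
recorded as ground truth — including, every run, a 440 bp promoter
insertion on a single-copy homolog with an expression effect, emulating
the regulatory-variant narrative such studies are built around; and
negative-binomial counts (variance = m + φ·m², default φ = 0.05, the
low-variability regime of isogenic laboratory cultures) for 2 tissues ×
4 replicates per genome, with per-sample library-size jitter of ±20%
and category-graded mean multipliers (8/4/2/1 from core to private, so
core genes are the most expressed, as observed in real panels).

Expression effects (|log2FC| = 2 by default) are planted on a fraction
(default 0.5) of SV-affected homolog groups; with `couple_sv_effects:
false` the same number of effects lands on uniformly chosen groups
instead, giving a true null for the association test. Everything is
driven by one seeded generator: a fixed seed yields byte-identical
output files.

What the generator does *not* emulate: sequence content (no FASTA or
reads), isoform structure beyond one transcript per gene, batch effects,
GC or length biases, correlated gene expression, or overlapping genes.
Passing the planted-recovery tests therefore demonstrates the pipeline's
internal correctness and statistical calibration under the stated noise
model, not robustness to every artifact of real RNA-seq or real
orthology inference.

## Problem sizes and numerical conventions

The test suite and acceptance checks run at: scale 0.02–0.05 synthetic
studies (270–675 families, ~1000–2600 genes, 40 samples), 10 replicate
simulations for pooled DEG sensitivity/FDR, 100 replicates for
association power, 10 000 sampled orderings when checking Monte-Carlo
rarefaction against exhaustive enumeration, and exhaustive per-base
sweeps for the impact classifier. Floating-point conventions: BH via the
standard step-up; chi-square with continuity correction; hypergeometric
tails via the survival function clipped to [0, 1]; percentage tables are
rounded to two decimals and sum to 100 within 0.01.

## Known limitations

- The DE test is not a count-model GLM; at very low counts its power is
  below DESeq2's, and dispersion information is not shared across genes.
- Orthogroup tables are trusted as given; mis-inferred orthology
  propagates into every downstream stage.
- Breakend (TRA) records are treated as isolated points; mate resolution
  is not attempted.
- The impact table is normative for this package: corner cases of other
  annotators (e.g. exon-boundary duplications) may be classified
  differently.
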