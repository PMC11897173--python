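# ganopan

Pan-genome analysis toolkit for small fungal genome panels, built around
the workflow used to compare cultivated *Ganoderma* (Lingzhi) varieties:
classify orthogroup families by genome occupancy, trace pan/core
rarefaction curves, annotate structural variants (SVs) with their
predicted impact on gene models, call differentially expressed genes
between cultivars, test whether SV-affected homologs are enriched for
differential expression, and run GO term over-representation — all
exercisable end-to-end on synthetic data with planted ground truth.

## Who it is for

Comparative genomicists who already have orthology calls (OrthoFinder
`Orthogroups.tsv`), gene models (GFF3), SV calls (VCF with
`SVTYPE`/`END`/`SVLEN`, e.g. a SyRI export) and RNA-seq count matrices,
and want a reproducible, tested path from those files to pan-genome
composition tables, impact-annotated variants and association statistics.

## The statistics at the core

**Occupancy classification.** A family's occupancy *o* is the number of
genomes (out of *N*) with at least one member. The default bands are

| category | occupancy |
|---|---|
| core | *N* |
| softcore | *N*−2 … *N*−1 |
| dispensable | 2 … *N*−3 |
| private | 1 |

Genes assigned to no family ("singletons") are tallied separately as
private units and never enter the family percentages.

**Rarefaction.** For a random ordering of genomes, pan(*k*) is the union
and core(*k*) the intersection of family sets over the first *k* genomes;
curves are averaged over sampled orderings (exhaustive enumeration is
available for small *N*).

**SV impact.** Each (variant, gene) pair gets a region (CDS, non-coding
exon, intron, promoter/upstream, downstream) and an impact class following
the SnpEff severity convention: frameshifting or start/stop-removing
coding changes are *high*, in-frame coding changes *moderate*,
UTR-equivalent hits *low*, and intronic or regulatory-window variants
*modifier*. Insertions are zero-length anchors, so a promoter insertion
(such as a 440 bp insertion upstream of a sporulation gene) localizes to a
single feature. The full rule table is in `docs/methods.md`.

**Differential expression.** log2 fold change of mean CPM with a 0.5
pseudo-count; two-sided Welch *t* on log2(CPM + 0.5); Benjamini–Hochberg
FDR; a gene is a DEG when |log2FC| > 1 and FDR < 0.05.

**SV–DEG association.** A 2×2 table of {SV-affected, not} × {DEG, not}
over single-copy homolog groups, tested with Yates-corrected chi-square
(Fisher's exact when a margin is empty).

**Enrichment.** One-sided hypergeometric test per GO term, raw p < 0.05
reporting cutoff, BH column included for reference.

## Worked example

Generate a small synthetic study (15-genome orthogroup table scaled to 270
families, five cultivar genomes with gene models, planted SVs and
negative-binomial counts), then classify it:

```sh
$ pangene -q simulate --outdir demo --seed 7 --scale 0.02
wrote 11 files under demo
$ pangene -q classify --orthogroups demo/orthogroups.tsv --out demo/classification.tsv
core        118  43.70%
softcore     39  14.44%
dispensable 101  37.41%
private      12   4.44%
```

The four percentages sum to 100 and reproduce the occupancy bands the
generator planted. Or run every stage end-to-end:

```sh
$ pangene -q run --outdir demorun --seed 7
```

which prints a report whose association section reads, for the default
simulation (effects planted on SV-affected homologs):

```
DEG proportion among SV-affected groups: 0.5; among others: 0.006897
(chi2 p=3.43e-33, statistic=144.1, n=362)
```

i.e. half of the SV-affected homolog groups are differentially expressed
versus under 1% of the others — the planted coupling, recovered. The run
directory contains every stage's TSV/JSON output plus `manifest.json`
(checksums, seed, wall times); re-running with the same config skips
up-to-date stages and reproduces byte-identical outputs.

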