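# tgmseq

Strand-specific analysis of intergenic RNA polymerase II transcription
near RNA polymerase III binding sites in *Saccharomyces cerevisiae*.

Assembled Pol III complexes (TFIIIC + TFIIIB + Pol III, bound at tRNA
genes and at extra-TFIIIC "*ETC*" sites) exert *extra-transcriptional*
effects on their neighborhood: they block cryptic intergenic Pol II
transcription, insulate promoters, and act as chromatin boundaries.
When Pol III complex assembly is compromised (for instance by depleting
a TFIIIC subunit), normally silent intergenic regions light up — as
5′-extended transcripts, 3′-extended transcripts, readthrough of an
upstream transcript across a tDNA, or outright de-repression.  Standard
gene-level expression analyses miss these events because they happen
*between* annotated genes.

`tgmseq` is the pipeline for finding and classifying them from
strand-specific RNA-seq of a two-condition comparison (e.g. wild type
vs. a Pol III factor mutant):

1. **annotate** — partition the genome, per strand, into annotated gene
   footprints and the remaining intergenic space; intergenic gaps longer
   than 500 bp are tiled into 500-bp windows.  tRNA genes and
   user-supplied *ETC* sites form a Pol III site registry.
2. **counting** — assign uniquely mapped, strand-specific
   reads/fragments to the single region containing their 5′-most base;
   QC statistics (antisense fraction, replicate correlation); bedGraph
   export for genome browsers.
3. **diffexp** — differential expression with median-of-ratios size
   factors $\hat s_j = \operatorname{median}_i\, k_{ij} / (\prod_v k_{iv})^{1/m}$,
   a method-of-moments dispersion fit $\alpha(\mu) = a_0 + a_1/\mu$
   (NB variance $\mu + \alpha\mu^2$), and the conditional negative-binomial
   exact test: conditional on a region's total $K = k_A + k_B$, the
   p-value is the probability mass of all splits $(a, K-a)$ no more
   likely than the observed one.  Benjamini–Hochberg adjustment with
   independent filtering, applied to gene regions and intergenic windows
   separately; calls at padj < 0.05.
4. **classify** — merge significant up-regulated intergenic windows into
   chains and assign each chain one category by geometry:
   **readthrough** (continues from an upstream gene's 3′ end across an
   overlapping tDNA and beyond it) ≻ **5′-UTR extension** (contiguous
   with a downstream gene's start) ≻ **3′-UTR extension** (contiguous
   with an upstream gene's end) ≻ **de-repressed intergenic** (isolated
   signal).  Every chain is annotated with its nearest tDNA/ETC site and
   a ≤ 500 bp proximity flag.
5. **simulate** — a first-class generator of synthetic genomes, site
   registries, truth tables, and NB count matrices (or read sets) with
   planted events of every class, so the whole pipeline is verifiable
   without any external data.

## Worked example

Simulate the standard scenario — 200 genes, 40 tDNAs, 10 *ETC* sites,
10 planted events per class at 16-fold, two replicates per condition —
and run the full analysis:

```python
from tgmseq import simulate, annotate, diffexp, classify

cfg = simulate.SimulationConfig(seed=1)
sim = simulate.simulate_genome(cfg)
catalog = annotate.partition_genome(sim.genes, sim.chrom_sizes)
counts, sheet = simulate.simulate_counts(sim.truth, catalog, cfg)
de = diffexp.run_de(counts, sheet, catalog)
classified = classify.classify_all(de, catalog, sim.sites)
summary = classify.summarize(classified, de, catalog, sim.sites)
print(len(catalog), summary.n_up_chains, summary.counts)
```

This prints (catalog of 1397 regions = 240 gene footprints + 1157
strand-specific intergenic windows):

```
1397 37 {'five_prime_extension': 10, 'three_prime_extension': 9,
         'readthrough': 10, 'derepressed_intergenic': 8}
```

68 intergenic windows are significant at padj < 0.05 and merge into 37
up-regulated chains; the classifier recovers 10/10 planted 5′-extensions,
9/10 3′-extensions, 10/10 readthrough events and 8/10 de-repressed
windows, each category call overlapping its planted locus, and every
chain lies within 500 bp of a Pol III site.  Scoring against the truth
table (`simulate.evaluate_recovery`) gives per-class precision 0.91–1.0
and recall 0.8–1.0.  The same analysis is available from the shell:

```sh
tgmseq simulate --seed 1 -o sim/
tgmseq run-all -c sim/config.yaml
```

which writes `catalog.bed`, `counts.tsv`, `de_results.tsv`,
`classification.tsv`, `category_summary.tsv`, and `recovery.tsv` under
`sim/analysis/`, alongside the resolved configuration that reproduces
them.

For real data, point `run-all` at a GFF3 annotation, a chromosome-size
table, a BED of extra Pol III sites, and either SAM/BAM alignments (via
the sample sheet) or a precomputed count matrix.

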