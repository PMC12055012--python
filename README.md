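# fatelink

Paired snRNA/snATAC multiome analysis centred on one question: how does a
developmental fate-map label partition the regulatory landscape — the
"regulome" — of a gene program? The motivating system is group 2 innate
lymphoid cells (ILC2s) carrying a transcriptional RAG fate map: cells with
any developmental history of RAG expression (RAG<sup>exp</sup>) transcribe a
tdRFP reporter, cells without it (RAG<sup>naïve</sup>) do not, and the two
populations can be compared at steady state (SS) and under atopic
dermatitis-like inflammation (AD).

The package provides, as a tested and reusable library:

- **I/O** for the standard formats: MatrixMarket count triplets, 5-column
  BED-like fragments files (plain or gzip), GTF or minimal gene tables, peak
  BED (`fatelink.io`). All coordinates are 0-based half-open internally.
- **Per-cell QC** — total RNA/ATAC counts, percent mitochondrial reads,
  percent ribosomal genes detected, nucleosome signal, TSS enrichment — with
  strict retention bounds, a lineage-marker computational filter
  (*Cd3d, Cd3e, Cd3g, Cd4, Cd19, Cd8a, Itgam*), and fate-map assignment from
  the barcode transcript (`fatelink.qc`).
- **Reduction and clustering**: log-normalization + PCA for RNA, TF-IDF +
  LSI (component 1 dropped) for ATAC, equal-weight joint SNN graph, Leiden
  clustering (`fatelink.reduce`).
- **Markers and the multiomic signature**: a gene-activity (GA) assay from
  fragment counts over gene-body + 2 kb upstream windows; one-vs-rest
  Wilcoxon markers for GEX/GA; differentially accessible (DA) peaks via a
  logistic likelihood-ratio test with total fragment depth as a latent
  covariate; closest-gene mapping within 10⁵ bp; and the 3-assay top-100
  signature with its Venn decomposition (`fatelink.markers`).
- **Peak-to-gene links (GPLs)** — the core statistic. For each (gene, peak)
  pair within 10⁶ bp of the TSS, the link score is the Pearson correlation
  across cells between normalized expression and TF-IDF accessibility;
  significance comes from a null of n=200 background peaks matched on GC
  content and mean accessibility: z = (r − μ₀)/σ₀, p = 1 − Φ(z), retaining
  links with p < 0.05 and r > 0.05 (`fatelink.links`).
- **Regulome comparison**: per-gene GPL counts and their
  RAG<sup>naïve</sup> − RAG<sup>exp</sup> difference ranking; non-redundant
  link-peak sets per condition group; UpSet-style exclusive intersections
  across the four fate-map × disease groups; "induced" peaks (present in
  both naïve groups and in inflamed RAG<sup>exp</sup>, absent from
  RAG<sup>exp</sup> at steady state); induced-gene ranking and the Th2-locus
  (*Il4, Il13, Rad50, Il5*) report (`fatelink.regulome`).
- **Motif enrichment**: PWM scanning (JASPAR text or toy motifs) against
  peak sequences, hypergeometric enrichment in a target peak set against a
  GC-matched background, and cross-referencing enriched motifs with TF
  expression per fate-map group (`fatelink.motifs`).
- **A synthetic paired-multiome generator** (`fatelink.simulate`) that
  emulates the study design — 4 condition groups, 6 cell types, planted QC
  failures, a detectable barcode transcript, and latent-factor-coupled
  peak–gene pairs planted per condition group at a target correlation — so
  every stage has ground truth.

## Worked example

```python
import numpy as np
from fatelink import simulate as sim, links, regulome, qc

design = sim.SimDesign(celltypes=("ILC2",), cells_per_condition=250,
                       n_genes=120, gene_spacing=2_000_000,
                       emit_fragments=False, seed=909)
genome, peaks = sim.make_genome(design, seed=909)
design.planted_links = sim.plant_links(
    genome, peaks, 4, groups={"naiveSS", "naiveAD"}, target_r=0.45,
    rng=np.random.default_rng(909), genes=list(sim.TH2_GENES), links_per_gene=3)
paired, cells = sim.simulate_counts(genome, peaks, design, seed=909)

tables = links.links_per_group(paired, genome, peaks, cells.df,
                               grouping="fatemap",
                               params=links.LinkParams(seed=909))
report = regulome.th2_locus_report(tables, known_genes=list(genome.genes["symbol"]))
print(report["gpl_summary"][["gene", "n_links_naive", "n_links_exp", "diff"]])
```

prints

```
    gene  n_links_naive  n_links_exp  diff
0   Il13              3            0     3
1    Il4              3            0     3
2  Rad50              3            0     3
3    Il5              3            1     2
```

Twelve links were planted at the four-gene Th2 locus only in the
RAG<sup>naïve</sup> condition groups. All twelve are recovered in the naïve
link table; one spurious link slips into the RAG<sup>exp</sup> table (the
cutoff-based retention admits ~2.6% of null pairs), so every locus gene
still shows a positive GPL difference — the locus reads as epigenomically
more active in fate-map-negative cells, which is exactly the planted truth.

A thin CLI mirrors the library: `fatelink simulate | qc | cluster | markers
| link | regulome | motifs` (see `fatelink --help`).

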