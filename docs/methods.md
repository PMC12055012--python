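# Methods

## Scope and model

`fatelink` analyses paired single-nucleus RNA + ATAC data from one pool of
barcoded cells carrying two labels: a fate-map state (RAGexp if the barcode
transcript, by default `tdRFP`, is detected with count ≥ 1; RAGnaive
otherwise) and a disease state (steady state SS vs AD-like inflammation).
The pipeline's central statistic is the gene-to-peak link (GPL): a retained
correlation between a peak's accessibility and a nearby gene's expression.
Counting GPLs per gene per cell population quantifies the "regulome
activity" of that gene, and set algebra on the peaks of GPLs across the
four fate-map × disease groups isolates inflammation-induced regulatory
elements.

## Per-cell QC

Metrics per barcode:

- `rna_total`: RNA column sum; `atac_total`: count-weighted fragment tally.
- `pct_mito`: percent of RNA counts from genes prefixed `mt-`.
- `pct_ribo` (default): percent of *detected* genes (count ≥ 1) whose symbol
  matches `Rps*/Rpl*`. The alternative percent-of-counts reading is
  implemented behind `ribo_mode="counts"`; the default follows the wording
  of the retention rule ("percent ribosomal genes detected").
- `nucleosome_signal`: (fragments of length 147–294 bp) / (fragments
  < 147 bp + 1). The pseudocount guards empty denominators.
- `tss_enrichment`: mean per-bp fragment coverage over TSS ± 100 bp windows
  divided by mean per-bp coverage over ±1,901–2,000 bp flank windows + 0.1.
  These are the common fragment-length-ratio and flank-normalized
  definitions; the pseudocounts make both metrics total functions.

Cells are retained only when all eight bounds hold with **strict**
inequality: nucleosome signal < 1.5, TSS enrichment > 1, 1,000 < RNA counts
< 15,000, 100 < ATAC counts < 75,000, mito < 5%, ribo < 10%. The lineage
filter removes any cell with a raw count ≥ 1 for any of Cd3d, Cd3e, Cd3g,
Cd4, Cd19, Cd8a, Itgam; "detectable transcript" is interpreted as raw
count ≥ 1 and is exposed as a parameter, as is the barcode-transcript
detection threshold for fate-map assignment (default raw count ≥ 1, no
prior normalization).

## Reduction and clustering

RNA: `ln(1 + 10⁴·x/cell_total)`, top-2,000 features by variance of the
normalized values, unit-variance scaling, PCA (components 1–25). ATAC:
TF-IDF (`ln(1 + TF·IDF·10⁴)` with TF = count/cell in-peak total, IDF =
n_cells/(1 + detection count)) then truncated SVD, dropping component 1,
which tracks sequencing depth (components 2–25). Signs are fixed by forcing
each component's largest-magnitude loading positive, which makes embeddings
reproducible bit-for-bit at a fixed seed.

Joint clustering z-scores each embedding per component, scales each
modality block to equal total weight, concatenates, builds a k = 20
shared-nearest-neighbor graph with Jaccard edge weights (weak edges below
1/15 pruned, the usual SNN convention), and runs Leiden community detection
(RB-configuration quality) at resolution 0.1 with a mandatory seed.
Variance-stabilizing regression and per-cell modality weighting (WNN) are
deliberately replaced by log-normalization and equal-weight concatenation:
downstream statistics operate on normalized values and the equal-weighting
intent is preserved; both replacements are pluggable. Cross-sample anchor
integration is omitted — the generator does not inject batch effects.

## Markers and signature

The gene-activity assay counts fragments (count-weighted) overlapping the
strand-aware window [gene body ∪ 2,000 bp upstream of the TSS], clipped at
chromosome bounds, then log-normalizes. GEX/GA markers are one-vs-rest
Wilcoxon rank-sum tests (exact for small untied samples, tie-corrected
normal approximation otherwise), reported only when max(pct_in, pct_out) ≥
0.20 and log2FC ≥ 0.25, where log2FC = log2((mean(expm1 x_in)+1)/(mean(expm1
x_out)+1)) — the mean-of-unlogged-with-pseudocount convention. DA peaks use
a likelihood-ratio test between logistic cluster-membership models (null:
intercept + ln(1 + total fragments); full: + the peak, binarized by default
— binarization stabilizes the test at snATAC sparsity; raw counts are an
option), p from χ²₁, detection filter min.pct = 0.02. The test is
direction-agnostic, so positive-direction markers are selected by log2FC
sign. Perfect separation falls back to a small-ridge penalized fit and is
flagged. BH adjustment is applied within each (assay, cluster); ranks break
ties by |log2FC| then feature id so top-N lists are deterministic.

DA peaks map to their closest gene by gene-body distance (0 when
overlapping; ties to the nearest TSS, then lexicographic gene id), dropping
peaks farther than 10⁵ bp. The gene filter is applied before truncating the
top-100 mapped list. The multiomic signature is the union of the top-100
GEX/GA/DA features with its 7-region Venn decomposition.

## Peak-to-gene links

Candidate pairs are all (gene, peak) with peak-interval-to-TSS distance
≤ 10⁶ bp. Within a cell subset (normalization recomputed inside the
subset), pairs whose gene or peak is detected in fewer than 2 cells, or has
zero variance, are skipped. The score is the Pearson correlation between
normalized expression and TF-IDF accessibility (a raw-count option exists).
The null draws 200 background peaks from the focal peak's GC-content ×
mean-accessibility quantile bin (20 × 20; shallow bins widen to the nearest
peaks in covariate space and fall back to with-replacement sampling,
flagged); z = (r − μ₀)/σ₀ with σ₀ the ddof-1 standard deviation, p =
1 − Φ(z). Links are retained when p < 0.05 and r > 0.05 (positive scores
only — links are read as activating elements; a two-sided flag exists). No
multiple-testing correction is applied across pairs; retention is
cutoff-based by design. Background draws are seeded per (gene, peak) by
hashing the ids with the global seed, so per-group runs are reproducible
and order-independent.

Under the permutation null E[r²] = 1/(n − 1), so at n = 1,500 cells the
null-pair retention rate is ≈ P(r > 0.05) ≈ 2.6%. The realized false
discovery proportion of a run therefore depends on the ratio of true links
to candidate pairs; with 200 true links among ~2,000 candidates it sits
near 0.19 at the default cutoffs. Tightening `score_cutoff` or `p_cutoff`
trades sensitivity for FDR in the usual way.

Group runs: `fatemap` yields naive/exp tables; `fatemap_disease` yields the
four-way split, where each group's links are matched back to (intersected
with) the all-cells table before any set analysis — this regularizes
group-specific noise.

## Regulome comparison

Per gene: link counts in the naive and exp tables, diff = naive − exp,
sorted descending with ties by symbol. For set analysis, GPLs with
redundant peaks collapse to the distinct peak set per group. Intersections
use **exclusive** (UpSet) semantics — each peak in the union belongs to
exactly one membership combination, so combination sizes always partition
the union (an inclusive mode is available for sensitivity analysis).
Induced peaks are those whose exclusive combination is exactly {naiveSS,
naiveAD, expAD}. Induced-gene ranking counts links whose peak is induced,
deduplicated by (gene, peak) across the group tables (a link found in two
groups counts once — the union reading of "identified in corresponding
GPLs"). The Th2-locus report restricts the same machinery to Il4, Il13,
Rad50, Il5 and additionally reports crosstalk peaks (linked to ≥ 2 locus
genes).

## Motif enrichment

PWMs (JASPAR text via Biopython, or planted toy motifs) are scanned in
log-odds form against a uniform background; a peak is a hit when any window
on either strand reaches 80% of the motif's maximum score; windows with
ambiguous bases are skipped. Enrichment in a target peak set samples 40
background peaks per target from the target's GC quantile bin (20 bins) of
the non-target pool and tests hit counts with a hypergeometric tail,
BH-corrected across motifs (default significance cutoff p_adj < 0.05,
configurable). Enriched motifs are joined to per-fate-map TF expression
summaries (mean normalized expression and detection fraction); TFs detected
in < 1% of cells are flagged undetected. Per-cell motif deviation scoring
is out of scope; the set-level enrichment plus expression cross-reference
is the supported readout.

## Synthetic generator

`make_genome` tiles genes (default 200, including the barcode gene, 7
lineage genes, 10 `mt-` and 40 `Rps/Rpl` pseudo-genes, and a 4-gene Th2
locus analog on consecutive slots) along chromosomes and places 3 peaks
within 10⁵ bp and 2 within (10⁵, 10⁶] bp of each TSS. Peaks are kept
mutually disjoint and ≥ 2.5 kb clear of every TSS so fragments land in at
most one peak and never inside a TSS QC window; each peak gets a random
sequence with Beta(2,2)-distributed GC in [0.25, 0.75].

`simulate_counts` draws gene counts negative-binomially (dispersion θ = 10)
around per-gene log-normal means scaled to ~3,000 RNA counts/cell, with
per-cell-type marker genes (8 per type, 8-fold) and marker peaks (8-fold);
peak counts are Poisson with baseline mean 0.5 per peak per cell (~40%
detection, a realistic snATAC sparsity at this peak count). For each
planted link active in group G, cells of G share a standard-normal latent u
entering both means as exp(a·u − a²/2); a is solved by bisection against a
10,000-draw Monte-Carlo estimate of the realized count correlation
(including the independent per-cell library-size spread, lognormal
σ = 0.2), cached on rounded inputs. The barcode transcript is planted with
detection probability 0.9 in RAGexp cells and false-positive rate 0;
lineage-positive cells receive ≥ 1 count of 1–3 lineage genes; planted QC
failures violate exactly one bound each, drawn with wide margins past the
bound (e.g. RNA-high cells at 20,000–30,000 counts). Fragments are emitted
per nonzero (peak, cell) entry (count-weighted, placed inside the peak)
plus background records: 40% at TSS windows (flank windows instead for
planted TSS failures; all-TSS for ATAC-low cells so only the depth bound
fails) and 60% uniform outside peaks, with lengths from the
nucleosome-free/mono-nucleosome mixture whose per-cell weight (0.35 normal,
0.75 for planted nucleosome-signal failures) defines the true nucleosome
signal. All randomness flows from one integer seed through spawned
`numpy` generators; fixtures record the seed in a manifest.

What the generator does **not** emulate: batch effects (a toggle exists but
defaults off), doublets and ambient RNA beyond truth flags (corrected
counts are assumed), chromatin co-accessibility structure between
neighboring peaks, distance-dependent link strength, and read-level
artifacts. Passing tests therefore demonstrate correctness of the
statistics and recovery under the declared noise model, not robustness to
those real-data pathologies.

## Numerical choices and edge cases

Zero-total cells produce zero normalized columns (flagged for TF-IDF);
zero-variance features are skipped in linking; a zero background σ₀ maps to
z = ±∞ and p ∈ {0, 1}; clusters with < 3 cells are skipped with a warning;
rank-deficient matrices reduce the component count with a warning;
`k_neighbors ≥ n_cells` is an error. Problem sizes in the test-suite
recovery checks (e.g. 1,500–2,000 cells, ~2,000 candidate pairs, 20 seeds)
were chosen as the smallest designs at which the planted effects are
comfortably identifiable on a single CPU.
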