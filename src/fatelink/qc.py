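"""Per-cell quality control, lineage filtering, and fate-map assignment.

QC metrics follow the standard snMultiome definitions: total RNA counts,
count-weighted total ATAC fragments, percent mitochondrial reads (gene
symbols prefixed ``mt-``), percent ribosomal genes detected (symbols
prefixed ``Rps``/``Rpl``), nucleosome signal (mono-nucleosome to
nucleosome-free fragment-length ratio), and TSS enrichment (TSS-proximal
over distal-flank per-bp coverage). Cells are retained only when every
bound holds with strict inequality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._coverage import FragmentIndex
from .types import GenomeModel, PairedCounts

MITO_PREFIX = "mt-"
RIBO_PREFIXES = ("Rps", "Rpl")
LINEAGE_MARKERS = ("Cd3d", "Cd3e", "Cd3g", "Cd4", "Cd19", "Cd8a", "Itgam")

TSS_HALF_WINDOW = 100          # TSS +/- 100 bp
FLANK_OFFSETS = (1901, 2000)   # +/- 1901..2000 bp flank windows


@dataclass
class QCThresholds:
    """Retention bounds; all strict (exclusive) inequalities."""

    ns_max: float = 1.5
    tss_min: float = 1.0
    rna_max: float = 15_000
    rna_min: float = 1_000
    atac_max: float = 75_000
    atac_min: float = 100
    mito_max: float = 5.0   # percent
    ribo_max: float = 10.0  # percent

    def __post_init__(self):
        if self.rna_min >= self.rna_max or self.atac_min >= self.atac_max:
            raise ValueError("min bound must be below max bound")


def compute_qc(paired: PairedCounts, genome: GenomeModel,
               ribo_mode: str = "genes") -> pd.DataFrame:
    """Per-cell QC metrics.

    ``ribo_mode='genes'`` computes percent of *detected genes* that are
    ribosomal (the default reading of the retention rule);
    ``ribo_mode='counts'`` computes percent of counts instead.
    """
    rna = sp.csc_matrix(paired.rna)
    feats = np.array(paired.rna_features)
    rna_total = np.asarray(rna.sum(axis=0)).ravel().astype(float)

    mito = np.char.startswith(feats.astype(str), MITO_PREFIX)
    ribo = np.zeros(len(feats), dtype=bool)
    for pre in RIBO_PREFIXES:
        ribo |= np.char.startswith(feats.astype(str), pre)

    mito_counts = np.asarray(rna[mito].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(rna_total > 0, 100.0 * mito_counts / rna_total, 0.0)

    detected = rna.copy()
    detected.data = (detected.data >= 1).astype(np.int8)
    n_detected = np.asarray(detected.sum(axis=0)).ravel().astype(float)
    n_ribo_det = np.asarray(detected[ribo].sum(axis=0)).ravel().astype(float)
    if ribo_mode == "genes":
        with np.errstate(invalid="ignore", divide="ignore"):
            pct_ribo = np.where(n_detected > 0, 100.0 * n_ribo_det / n_detected, 0.0)
    elif ribo_mode == "counts":
        ribo_counts = np.asarray(rna[ribo].sum(axis=0)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct_ribo = np.where(rna_total > 0, 100.0 * ribo_counts / rna_total, 0.0)
    else:
        raise ValueError("ribo_mode must be 'genes' or 'counts'")

    index = FragmentIndex(paired.fragments, paired.barcodes)
    atac_total = index.totals()
    mono, short = index.length_tallies()
    nucleosome_signal = mono / (short + 1.0)

    center_bp = np.zeros(len(paired.barcodes))
    flank_bp = np.zeros(len(paired.barcodes))
    n_genes = len(genome.genes)
    for _, g in genome.genes.iterrows():
        tss = int(g["tss"])
        chrom = g["chrom"]
        center_bp += index.window_overlap_bp(chrom, tss - TSS_HALF_WINDOW,
                                             tss + TSS_HALF_WINDOW + 1)
        lo, hi = FLANK_OFFSETS
        flank_bp += index.window_overlap_bp(chrom, tss - hi, tss - lo + 1)
        flank_bp += index.window_overlap_bp(chrom, tss + lo, tss + hi + 1)
    center_width = 2 * TSS_HALF_WINDOW + 1
    flank_width = 2 * (FLANK_OFFSETS[1] - FLANK_OFFSETS[0] + 1)
    center_cov = center_bp / (n_genes * center_width)
    flank_cov = flank_bp / (n_genes * flank_width)
    tss_enrichment = center_cov / (flank_cov + 0.1)

    qc = pd.DataFrame({
        "rna_total": rna_total,
        "atac_total": atac_total,
        "pct_mito": pct_mito,
        "pct_ribo": pct_ribo,
        "nucleosome_signal": nucleosome_signal,
        "tss_enrichment": tss_enrichment,
        "no_fragments": (atac_total == 0) & (rna_total > 0),
    }, index=pd.Index(paired.barcodes, name="barcode"))
    return qc


def apply_thresholds(qc: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.Series:
    """Boolean kept flag per barcode: all eight bounds strict."""
    t = thresholds or QCThresholds()
    keep = (
        (qc["nucleosome_signal"] < t.ns_max)
        & (qc["tss_enrichment"] > t.tss_min)
        & (qc["rna_total"] < t.rna_max)
        & (qc["rna_total"] > t.rna_min)
        & (qc["atac_total"] < t.atac_max)
        & (qc["atac_total"] > t.atac_min)
        & (qc["pct_mito"] < t.mito_max)
        & (qc["pct_ribo"] < t.ribo_max)
    )
    keep.name = "qc_pass"
    return keep


def lineage_filter(rna, features: list[str], barcodes: list[str],
                   marker_genes=LINEAGE_MARKERS) -> pd.Series:
    """Keep cells with zero counts for every lineage-defining marker.

    A cell is removed iff any listed gene has a raw count >= 1 ("detectable
    transcript"). Missing symbols warn rather than fail.
    """
    rna = sp.csr_matrix(rna)
    feat_idx = {f: i for i, f in enumerate(features)}
    rows = []
    for g in marker_genes:
        if g in feat_idx:
            rows.append(feat_idx[g])
        else:
            warnings.warn(f"lineage marker {g!r} not in feature list")
    if rows:
        positive = np.asarray((rna[rows] >= 1).sum(axis=0)).ravel() > 0
    else:
        positive = np.zeros(len(barcodes), dtype=bool)
    return pd.Series(~positive, index=pd.Index(barcodes, name="barcode"),
                     name="lineage_pass")


def drop_doublets(cell_table: pd.DataFrame) -> pd.Series:
    """Keep flag from the synthetic truth doublet column (upstream doublet
    detection is out of scope; this filter consumes the generator's flags)."""
    if "doublet" not in cell_table:
        return pd.Series(True, index=cell_table.index, name="doublet_pass")
    return (~cell_table["doublet"].astype(bool)).rename("doublet_pass")


def assign_fatemap(rna, features: list[str], barcodes: list[str],
                   barcode_gene: str = "tdRFP", min_count: int = 1) -> pd.Series:
    """RAGexp iff the barcode transcript count >= min_count, else RAGnaive."""
    if barcode_gene not in features:
        raise ValueError(f"barcode gene {barcode_gene!r} absent from feature list")
    rna = sp.csr_matrix(rna)
    row = features.index(barcode_gene)
    counts = np.asarray(rna[row].todense()).ravel()
    labels = np.where(counts >= min_count, "RAGexp", "RAGnaive")
    return pd.Series(labels, index=pd.Index(barcodes, name="barcode"), name="fatemap")
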