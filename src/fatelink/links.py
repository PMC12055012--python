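"""Peak-to-gene links (GPLs) with a background-matched correlation null.

For every (gene, peak) pair within 1e6 bp of the gene's TSS, the link score
is the Pearson correlation across cells between normalized expression and
TF-IDF-normalized accessibility. Significance comes from a matched
background null: n_background peaks drawn from the focal peak's GC-content
x mean-accessibility bin are correlated with the same gene, giving
z = (score - mean_null) / sd_null and p = 1 - Phi(z). Links with
p < p_cutoff and score > score_cutoff are retained.

Background draws are seeded per (gene, peak) by hashing the ids with the
global seed, so results are reproducible and independent of pair order and
of the cell grouping.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from . import reduce as flreduce
from .types import GenomeModel, PairedCounts, PeakSet

LINK_COLUMNS = ["group", "gene", "peak", "score", "z", "p"]


@dataclass
class LinkParams:
    window: int = 1_000_000
    min_cells: int = 2
    n_background: int = 200
    p_cutoff: float = 0.05
    score_cutoff: float = 0.05
    gc_bins: int = 20
    accessibility_bins: int = 20
    two_sided: bool = False  # retain strong negative scores as well
    seed: int = 0

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.n_background < 50:
            raise ValueError("n_background must be at least 50")


def candidate_pairs(genome: GenomeModel, peaks: PeakSet,
                    window: int = 1_000_000) -> pd.DataFrame:
    """All (gene, peak) pairs with peak-interval-to-TSS distance <= window."""
    rows = []
    pk = peaks.peaks
    for chrom, genes_sub in genome.genes.groupby("chrom"):
        sub = pk[pk["chrom"] == chrom]
        if sub.empty:
            continue
        ps = sub["start"].to_numpy()
        pe = sub["end"].to_numpy()
        ids = sub.index.to_numpy()
        for _, g in genes_sub.iterrows():
            tss = g["tss"]
            dist = np.maximum(0, np.maximum(ps - tss, tss - (pe - 1)))
            for pid in ids[dist <= window]:
                rows.append((g["symbol"], pid))
    return pd.DataFrame(rows, columns=["gene", "peak"])


def pair_seed(gene: str, peak: str, global_seed: int) -> int:
    """Stable per-pair RNG seed (below 2^31)."""
    return zlib.crc32(f"{gene}|{peak}|{global_seed}".encode()) & 0x7FFFFFFF


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(edges)
    return np.searchsorted(edges, values, side="right")


def assign_background_bins(gc: np.ndarray, mean_acc: np.ndarray,
                           params: LinkParams) -> np.ndarray:
    """2-D quantile bin id per peak from GC content and mean accessibility."""
    g = _quantile_bins(np.asarray(gc, float), params.gc_bins)
    a = _quantile_bins(np.asarray(mean_acc, float), params.accessibility_bins)
    return g * (params.accessibility_bins + 1) + a


def sample_background(focal_idx: int, bins: np.ndarray, gc: np.ndarray,
                      mean_acc: np.ndarray, n: int, rng) -> tuple[np.ndarray, bool]:
    """Indices of n background peaks matched to the focal peak's bin.

    If the bin holds fewer than n peaks it is widened to the nearest peaks in
    (gc, accessibility) space and sampling falls back to with-replacement;
    the second return value flags that fallback.
    """
    pool = np.nonzero(bins == bins[focal_idx])[0]
    pool = pool[pool != focal_idx]
    if len(pool) >= n:
        return rng.choice(pool, size=n, replace=False), False
    # widen: rank all other peaks by standardized distance in covariate space
    others = np.arange(len(bins))
    others = others[others != focal_idx]
    gz = (gc - gc.mean()) / (gc.std() or 1.0)
    az = (mean_acc - mean_acc.mean()) / (mean_acc.std() or 1.0)
    d = np.abs(gz[others] - gz[focal_idx]) + np.abs(az[others] - az[focal_idx])
    widened = others[np.argsort(d, kind="stable")[:max(n, 2 * len(pool) + 50)]]
    return rng.choice(widened, size=n, replace=True), True


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    out = x - mean
    good = sd > 0
    out[good] /= sd[good][:, None]
    return out, good


def link_peaks(paired: PairedCounts, genome: GenomeModel, peaks: PeakSet,
               pairs: pd.DataFrame | None = None,
               cell_mask: np.ndarray | None = None,
               params: LinkParams | None = None,
               group: str = "all") -> pd.DataFrame:
    """Compute and filter gene-to-peak links on a cell subset.

    Normalization (log for RNA, TF-IDF for ATAC) is computed within the
    subset. Pairs whose gene or peak is detected in fewer than
    ``min_cells`` cells, or has zero variance, are skipped.
    """
    params = params or LinkParams()
    if pairs is None:
        pairs = candidate_pairs(genome, peaks, params.window)
    if cell_mask is None:
        cell_mask = np.ones(paired.n_cells, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    n_cells = int(cell_mask.sum())
    if n_cells < 3 or pairs.empty:
        return pd.DataFrame(columns=LINK_COLUMNS)

    rna = sp.csc_matrix(paired.rna)[:, cell_mask]
    atac = sp.csc_matrix(paired.atac)[:, cell_mask]
    norm_rna = flreduce.lognormalize(rna)
    norm_atac = flreduce.tfidf(atac)

    sym_idx = {s: i for i, s in enumerate(paired.rna_features)}
    pid_idx = {p: i for i, p in enumerate(paired.atac_features)}

    gene_det = np.asarray((rna > 0).sum(axis=1)).ravel()
    peak_det = np.asarray((atac > 0).sum(axis=1)).ravel()

    genes_used = sorted({g for g in pairs["gene"] if g in sym_idx})
    grows = np.array([sym_idx[g] for g in genes_used], dtype=int)
    G = np.asarray(sp.csr_matrix(norm_rna)[grows].todense())
    Gs, g_ok = _standardize_rows(G)
    P = np.asarray(norm_atac.todense())
    Ps, p_ok = _standardize_rows(P)

    # full correlation matrix genes_used x peaks; background lookups are rows
    C = (Gs @ Ps.T) / n_cells

    gc = peaks.peaks["gc"].to_numpy() if "gc" in peaks.peaks else _gc_from_sequences(
        peaks, genome)
    mean_acc = np.asarray(atac.mean(axis=1)).ravel()
    bins = assign_background_bins(gc, mean_acc, params)

    g_pos = {g: i for i, g in enumerate(genes_used)}
    records = []
    for gene, peak in pairs.itertuples(index=False):
        if gene not in g_pos or peak not in pid_idx:
            continue
        gi = g_pos[gene]
        pi = pid_idx[peak]
        if gene_det[grows[gi]] < params.min_cells or peak_det[pi] < params.min_cells:
            continue
        if not (g_ok[gi] and p_ok[pi]):
            continue
        score = float(C[gi, pi])
        rng = np.random.default_rng(pair_seed(gene, peak, params.seed))
        bg, _flag = sample_background(pi, bins, gc, mean_acc,
                                      params.n_background, rng)
        null = C[gi, bg]
        mu = float(null.mean())
        sd = float(null.std(ddof=1))
        if sd == 0:
            z = np.inf if score > mu else (-np.inf if score < mu else 0.0)
        else:
            z = (score - mu) / sd
        p = float(stats.norm.sf(z))
        records.append((group, gene, peak, score, z, p))

    table = pd.DataFrame(records, columns=LINK_COLUMNS)
    keep = table["p"] < params.p_cutoff
    if params.two_sided:
        keep &= table["score"].abs() > params.score_cutoff
    else:
        keep &= table["score"] > params.score_cutoff
    return table[keep].reset_index(drop=True)


def _gc_from_sequences(peaks: PeakSet, genome: GenomeModel) -> np.ndarray:
    if not genome.peak_sequences:
        raise ValueError("no GC content: peaks lack a 'gc' column and the "
                         "genome has no peak sequences")
    out = np.empty(len(peaks))
    for i, pid in enumerate(peaks.ids):
        seq = genome.peak_sequences[pid]
        out[i] = (seq.count("G") + seq.count("C")) / max(1, len(seq))
    return out


FOUR_WAY = ("naiveSS", "naiveAD", "expSS", "expAD")


def links_per_group(paired: PairedCounts, genome: GenomeModel, peaks: PeakSet,
                    cell_table: pd.DataFrame, grouping: str = "fatemap",
                    params: LinkParams | None = None,
                    pairs: pd.DataFrame | None = None,
                    min_group_cells: int = 50) -> dict[str, pd.DataFrame]:
    """Run link_peaks independently per cell group.

    ``grouping='fatemap'`` yields RAGnaive/RAGexp tables; ``'fatemap_disease'``
    yields the four-way split, where each group's links are additionally
    matched back to (intersected with) the all-cells link table.
    """
    params = params or LinkParams()
    if pairs is None:
        pairs = candidate_pairs(genome, peaks, params.window)
    bc_index = pd.Index(paired.barcodes)
    meta = cell_table.reindex(bc_index)
    if grouping == "fatemap":
        labels = meta["fatemap"].map({"RAGexp": "exp", "RAGnaive": "naive"})
        groups = ["naive", "exp"]
        match_back = False
    elif grouping == "fatemap_disease":
        fm = meta["fatemap"].map({"RAGexp": "exp", "RAGnaive": "naive"})
        labels = fm + meta["disease"].astype(str)
        groups = list(FOUR_WAY)
        match_back = True
    else:
        raise ValueError("grouping must be 'fatemap' or 'fatemap_disease'")

    out = {}
    total = None
    if match_back:
        total = link_peaks(paired, genome, peaks, pairs=pairs, params=params,
                           group="all")
        out["all"] = total
    for grp in groups:
        mask = (labels == grp).to_numpy()
        if mask.sum() == 0:
            warnings.warn(f"group {grp!r} is empty")
            out[grp] = pd.DataFrame(columns=LINK_COLUMNS)
            continue
        if mask.sum() < min_group_cells:
            warnings.warn(f"group {grp!r} has only {int(mask.sum())} cells")
        table = link_peaks(paired, genome, peaks, pairs=pairs, cell_mask=mask,
                           params=params, group=grp)
        if match_back and total is not None:
            total_pairs = set(zip(total["gene"], total["peak"]))
            in_total = [(g, p) in total_pairs
                        for g, p in zip(table["gene"], table["peak"])]
            table = table[np.array(in_total, dtype=bool)] if len(table) else table
        out[grp] = table.reset_index(drop=True)
    return out
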