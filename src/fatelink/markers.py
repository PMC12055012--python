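"""Gene-activity assay, per-cluster markers (GEX/GA/DA) and the multiomic signature.

Three assays feed the signature: normalized gene expression (GEX), gene
activity inferred from ATAC fragments over gene-body + upstream windows
(GA), and differentially accessible peaks mapped to their closest gene (DA).
Markers come from one-vs-rest Wilcoxon rank-sum tests (GEX/GA) and a
likelihood-ratio test between logistic cluster-membership models with total
fragment depth as a latent covariate (DA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._coverage import FragmentIndex
from .types import GenomeModel, PeakSet

MARKER_COLUMNS = ["assay", "cluster", "feature", "log2fc", "pct_in", "pct_out",
                  "p", "p_adj", "rank"]


def gene_activity(fragments: pd.DataFrame, genome: GenomeModel,
                  barcodes: list[str], upstream: int = 2000) -> sp.csr_matrix:
    """Raw gene-activity matrix: fragments overlapping gene body + upstream.

    The window is strand-aware (upstream of the TSS) and clipped at
    chromosome bounds. Counts are fragment-count weighted.
    """
    index = FragmentIndex(fragments, barcodes)
    chrom_len = dict(genome.chromosomes)
    rows, cols, vals = [], [], []
    for gi, g in genome.genes.reset_index(drop=True).iterrows():
        if g["strand"] == "+":
            ws, we = g["start"] - upstream, g["end"]
        else:
            ws, we = g["start"], g["end"] + upstream
        ws = max(0, ws)
        we = min(we, chrom_len.get(g["chrom"], we))
        counts = index.window_counts(g["chrom"], int(ws), int(we))
        nz = np.nonzero(counts)[0]
        rows.extend([gi] * len(nz))
        cols.extend(nz.tolist())
        vals.extend(counts[nz].tolist())
    return sp.csr_matrix((vals, (rows, cols)),
                         shape=(len(genome.genes), len(barcodes)), dtype=np.int64)


def _rank_markers(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(["p", "log2fc", "feature"],
                        ascending=[True, False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def find_markers_ranksum(norm_matrix, features: list[str], clusters,
                         assay: str = "GEX", min_pct: float = 0.20,
                         logfc_min: float = 0.25) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    log2fc = log2((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1)).
    Only features with max(pct_in, pct_out) >= min_pct and
    log2fc >= logfc_min are tested and reported; BH adjustment within
    each cluster.
    """
    x = sp.csr_matrix(norm_matrix)
    clusters = np.asarray(clusters)
    out = []
    for cl in pd.unique(clusters):
        in_mask = clusters == cl
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < 3 or n_out < 1:
            warnings.warn(f"cluster {cl!r} has fewer than 3 cells; skipped")
            continue
        xin = x[:, in_mask]
        xout = x[:, ~in_mask]
        pct_in = np.asarray((xin > 0).sum(axis=1)).ravel() / n_in
        pct_out = np.asarray((xout > 0).sum(axis=1)).ravel() / n_out
        mean_in = np.asarray(np.expm1(xin.todense())).mean(axis=1)
        mean_out = np.asarray(np.expm1(xout.todense())).mean(axis=1)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        passing = (np.maximum(pct_in, pct_out) >= min_pct) & (log2fc >= logfc_min)
        idx = np.nonzero(passing)[0]
        if len(idx) == 0:
            continue
        a = np.asarray(xin[idx].todense())
        b = np.asarray(xout[idx].todense())
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="auto")
        p = np.atleast_1d(res.pvalue)
        p_adj = multipletests(p, method="fdr_bh")[1]
        df = pd.DataFrame({
            "assay": assay,
            "cluster": cl,
            "feature": [features[i] for i in idx],
            "log2fc": log2fc[idx],
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
            "p": p,
            "p_adj": p_adj,
        })
        out.append(_rank_markers(df))
    if not out:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    return pd.concat(out, ignore_index=True)[MARKER_COLUMNS]


def _logit_llf(y, X) -> tuple[float, bool]:
    """Log-likelihood of a logistic fit; (llf, penalized_fallback_used)."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200, method="lbfgs")
        if np.isfinite(fit.llf):
            return float(fit.llf), False
    except Exception:
        pass
    # perfect separation or non-convergence: small-ridge penalized fallback
    from sklearn.linear_model import LogisticRegression
    lr = LogisticRegression(C=100.0, max_iter=1000).fit(X[:, 1:], y)
    eta = lr.decision_function(X[:, 1:])
    llf = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return llf, True


def lr_test_peak(y, log_total, peak_values) -> tuple[float, float, bool]:
    """LR test of logistic membership models: null = depth, full = depth + peak."""
    X0 = np.column_stack([np.ones_like(log_total), log_total])
    X1 = np.column_stack([X0, peak_values])
    llf0, flag0 = _logit_llf(y, X0)
    llf1, flag1 = _logit_llf(y, X1)
    lr_stat = max(0.0, 2.0 * (llf1 - llf0))
    p = float(stats.chi2.sf(lr_stat, df=1))
    return lr_stat, p, flag0 or flag1


def find_da_peaks_lr(atac_counts, peak_ids: list[str], clusters,
                     total_fragments, min_pct: float = 0.02,
                     binarize: bool = True) -> pd.DataFrame:
    """Differentially accessible peaks via logistic LR test per cluster.

    The null logistic model predicts cluster membership from ln(1 + total
    ATAC fragments); the full model adds the peak (binarized detection by
    default). p from chi-square with 1 df; min_pct filters on detection
    fraction; BH within cluster.
    """
    x = sp.csr_matrix(atac_counts)
    clusters = np.asarray(clusters)
    log_total = np.log1p(np.asarray(total_fragments, dtype=float))
    det = sp.csr_matrix((x > 0).astype(np.float64))
    out = []
    for cl in pd.unique(clusters):
        in_mask = clusters == cl
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < 3 or n_out < 1:
            warnings.warn(f"cluster {cl!r} has fewer than 3 cells; skipped")
            continue
        y = in_mask.astype(float)
        pct_in = np.asarray(det[:, in_mask].sum(axis=1)).ravel() / n_in
        pct_out = np.asarray(det[:, ~in_mask].sum(axis=1)).ravel() / n_out
        passing = np.maximum(pct_in, pct_out) >= min_pct
        idx = np.nonzero(passing)[0]
        if len(idx) == 0:
            continue
        vals = det if binarize else x
        mean_in = np.asarray(vals[idx][:, in_mask].mean(axis=1)).ravel()
        mean_out = np.asarray(vals[idx][:, ~in_mask].mean(axis=1)).ravel()
        log2fc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
        ps, flags = [], []
        for i in idx:
            v = np.asarray(vals[i].todense()).ravel()
            _, p, flagged = lr_test_peak(y, log_total, v)
            ps.append(p)
            flags.append(flagged)
        p = np.array(ps)
        p_adj = multipletests(p, method="fdr_bh")[1]
        df = pd.DataFrame({
            "assay": "DA",
            "cluster": cl,
            "feature": [peak_ids[i] for i in idx],
            "log2fc": log2fc,
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
            "p": p,
            "p_adj": p_adj,
            "penalized": flags,
        })
        out.append(_rank_markers(df))
    if not out:
        return pd.DataFrame(columns=MARKER_COLUMNS + ["penalized"])
    return pd.concat(out, ignore_index=True)[MARKER_COLUMNS + ["penalized"]]


def closest_gene(peaks: PeakSet, genome: GenomeModel,
                 max_dist: int = 100_000) -> pd.DataFrame:
    """Nearest gene per peak by gene-body distance; peaks farther than
    max_dist from every gene are dropped.

    Distance is 0 when the peak overlaps the gene body, otherwise the bp gap
    to the nearest gene boundary. Ties go to the gene whose TSS is nearest,
    then lexicographic gene_id.
    """
    rows = []
    genes = genome.genes
    for pid, pk in peaks.peaks.iterrows():
        sub = genes[genes["chrom"] == pk["chrom"]]
        if sub.empty:
            continue
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        dist = np.maximum(0, np.maximum(gs - pk["end"], pk["start"] - ge))
        tss = sub["tss"].to_numpy()
        tss_dist = np.maximum(0, np.maximum(tss - pk["end"] + 1, pk["start"] - tss))
        order = np.lexsort((sub["gene_id"].to_numpy(), tss_dist, dist))
        best = order[0]
        if dist[best] > max_dist:
            continue
        rows.append((pid, sub.iloc[best]["symbol"], sub.iloc[best]["gene_id"],
                     int(dist[best])))
    return pd.DataFrame(rows, columns=["peak_id", "gene", "gene_id", "distance"]
                        ).set_index("peak_id")


VENN_REGIONS = ("gex_only", "ga_only", "da_only", "gex_ga", "gex_da", "ga_da",
                "gex_ga_da")


@dataclass
class SignatureSet:
    """Top marker genes per assay, their union, and 7-region Venn counts."""

    gex_top: list[str]
    ga_top: list[str]
    da_top: list[str]
    union: list[str]
    venn: dict

    def __post_init__(self):
        assert sum(self.venn.values()) == len(self.union)


def _top_features(markers: pd.DataFrame, cluster, top_n: int, assay: str) -> list[str]:
    sub = markers[(markers["cluster"] == cluster)]
    if assay:
        sub = sub[sub["assay"] == assay] if "assay" in sub else sub
    sub = sub.sort_values("rank")
    feats = sub["feature"].drop_duplicates().tolist()
    if len(feats) < top_n:
        warnings.warn(f"only {len(feats)} markers available for {assay}/{cluster}")
    return feats[:top_n]


def multiomic_signature(markers_gex: pd.DataFrame, markers_ga: pd.DataFrame,
                        markers_da: pd.DataFrame, cluster,
                        top_n: int = 100) -> SignatureSet:
    """Union + Venn decomposition of the top markers across the three assays.

    DA markers must already be gene-mapped (feature = gene symbol).
    """
    gex = _top_features(markers_gex, cluster, top_n, "GEX")
    ga = _top_features(markers_ga, cluster, top_n, "GA")
    da = _top_features(markers_da, cluster, top_n, "DA")
    sg, sa, sd = set(gex), set(ga), set(da)
    union = sorted(sg | sa | sd)
    venn = {
        "gex_only": len(sg - sa - sd),
        "ga_only": len(sa - sg - sd),
        "da_only": len(sd - sg - sa),
        "gex_ga": len((sg & sa) - sd),
        "gex_da": len((sg & sd) - sa),
        "ga_da": len((sa & sd) - sg),
        "gex_ga_da": len(sg & sa & sd),
    }
    return SignatureSet(gex_top=gex, ga_top=ga, da_top=da, union=union, venn=venn)
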