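"""Independent brute-force reference implementations used by the tests.

Each oracle recomputes a pipeline quantity from its definition with naive
loops and standard-library/numpy primitives, staying independent of the
package code paths it checks (the linking oracle shares only the background
index draws, by design).
"""

import itertools
import math

import numpy as np
import pandas as pd


def exact_wilcoxon_p(x, y) -> float:
    """Two-sided rank-sum p by enumeration over all group assignments."""
    vals = np.concatenate([x, y])
    n, nx = len(vals), len(x)

    def ustat(xi):
        yi = [j for j in range(n) if j not in xi]
        return sum(vals[i] > vals[j] for i in xi for j in yi) + \
            0.5 * sum(vals[i] == vals[j] for i in xi for j in yi)

    obs = ustat(tuple(range(nx)))
    us = np.array([ustat(c) for c in itertools.combinations(range(n), nx)])
    ple = (us <= obs).mean()
    pge = (us >= obs).mean()
    return min(1.0, 2 * min(ple, pge))


def logistic_llf_optimizer(y, X) -> float:
    """Maximum log-likelihood of a logistic model via scipy.optimize."""
    from scipy.optimize import minimize

    y = np.asarray(y, float)
    X = np.asarray(X, float)

    def nll(beta):
        eta = X @ beta
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    res = minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return -res.fun


def brute_force_gene_activity(fragments: pd.DataFrame, genes: pd.DataFrame,
                              barcodes, upstream: int = 2000) -> np.ndarray:
    """O(genes x fragments) overlap count, count-weighted."""
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    out = np.zeros((len(genes), len(barcodes)), dtype=np.int64)
    for gi, g in genes.reset_index(drop=True).iterrows():
        if g["strand"] == "+":
            ws, we = g["start"] - upstream, g["end"]
        else:
            ws, we = g["start"], g["end"] + upstream
        ws = max(0, ws)
        for _, f in fragments.iterrows():
            if f["chrom"] != g["chrom"]:
                continue
            if f["start"] < we and f["end"] > ws:
                out[gi, bc_idx[f["barcode"]]] += f["count"]
    return out


def brute_force_closest_gene(peaks: pd.DataFrame, genes: pd.DataFrame,
                             max_dist: int) -> dict:
    out = {}
    for pid, pk in peaks.iterrows():
        best = None
        for _, g in genes.iterrows():
            if g["chrom"] != pk["chrom"]:
                continue
            if pk["start"] < g["end"] and pk["end"] > g["start"]:
                d = 0
            elif pk["end"] <= g["start"]:
                d = g["start"] - pk["end"]
            else:
                d = pk["start"] - g["end"]
            tss = g["tss"]
            td = max(0, tss - pk["end"] + 1, pk["start"] - tss)
            key = (d, td, g["gene_id"])
            if best is None or key < best[0]:
                best = (key, g["symbol"], d)
        if best is not None and best[2] <= max_dist:
            out[pid] = (best[1], best[2])
    return out


def brute_force_candidate_pairs(genes: pd.DataFrame, peaks: pd.DataFrame,
                                window: int) -> set:
    out = set()
    for _, g in genes.iterrows():
        for pid, pk in peaks.iterrows():
            if pk["chrom"] != g["chrom"]:
                continue
            tss = g["tss"]
            d = max(0, pk["start"] - tss, tss - (pk["end"] - 1))
            if d <= window:
                out.add((g["symbol"], pid))
    return out


def pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm = x - x.mean()
    ym = y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def normal_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def brute_force_links(paired, genome, peaks, pairs, params):
    """Naive reference for link scoring and retention.

    Recomputes log-normalization, TF-IDF, per-pair Pearson scores and the
    background z/p from their definitions with per-pair loops. Background
    peak indices are drawn through the package's seeded sampler (the shared
    RNG), everything else is independent.
    """
    from fatelink.links import (assign_background_bins, pair_seed,
                                sample_background)

    rna = np.asarray(paired.rna.todense(), dtype=float)
    atac = np.asarray(paired.atac.todense(), dtype=float)
    n_cells = rna.shape[1]

    norm_rna = np.zeros_like(rna)
    for c in range(n_cells):
        tot = rna[:, c].sum()
        if tot > 0:
            norm_rna[:, c] = np.log1p(1e4 * rna[:, c] / tot)
    tf = np.zeros_like(atac)
    for c in range(n_cells):
        tot = atac[:, c].sum()
        if tot > 0:
            tf[:, c] = atac[:, c] / tot
    idf = n_cells / (1.0 + (atac > 0).sum(axis=1))
    norm_atac = np.log1p(tf * idf[:, None] * 1e4)

    sym_idx = {s: i for i, s in enumerate(paired.rna_features)}
    pid_idx = {p: i for i, p in enumerate(paired.atac_features)}
    gc = peaks.peaks["gc"].to_numpy()
    mean_acc = atac.mean(axis=1)
    bins = assign_background_bins(gc, mean_acc, params)

    rows = []
    for gene, peak in pairs.itertuples(index=False):
        gi, pi = sym_idx[gene], pid_idx[peak]
        if (rna[gi] > 0).sum() < params.min_cells or (atac[pi] > 0).sum() < params.min_cells:
            continue
        if norm_rna[gi].std() == 0 or norm_atac[pi].std() == 0:
            continue
        score = pearson(norm_rna[gi], norm_atac[pi])
        rng = np.random.default_rng(pair_seed(gene, peak, params.seed))
        bg, _ = sample_background(pi, bins, gc, mean_acc, params.n_background, rng)
        null = np.array([pearson(norm_rna[gi], norm_atac[b]) for b in bg])
        mu = null.mean()
        sd = null.std(ddof=1)
        z = (score - mu) / sd if sd > 0 else math.inf * np.sign(score - mu)
        p = normal_sf(z)
        retained = p < params.p_cutoff and score > params.score_cutoff
        rows.append((gene, peak, score, z, p, retained))
    return pd.DataFrame(rows, columns=["gene", "peak", "score", "z", "p", "retained"])


def hypergeom_tail(k, N, K, n) -> float:
    """P(X >= k) for a hypergeometric(N, K, n) by direct summation."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += (math.comb(K, i) * math.comb(N - K, n - i)) / math.comb(N, n)
    return total
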