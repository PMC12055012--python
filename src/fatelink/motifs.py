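"""TF motif scanning and GC-matched enrichment in link peaks.

Position probability matrices (JASPAR text format, or planted toy motifs in
synthetic mode) are scanned against peak sequences in log-odds form versus
a uniform background; a peak is a hit when any window on either strand
reaches ``score_fraction`` of the motif's maximum score. Enrichment of
motif hits in a target peak set is tested against a GC-quantile-matched
background sample with a hypergeometric tail, BH-corrected across motifs,
and cross-referenced with per-fate-map TF expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class MotifModel:
    """A position probability matrix with its log-odds form.

    ``matrix`` is positions x 4 (A, C, G, T) probabilities summing to 1 per
    row; log-odds are taken against a uniform background with a small
    pseudo-probability to keep scores finite.
    """

    motif_id: str
    name: str
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("motif matrix must be positions x 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("motif position probabilities must sum to 1")
        self.matrix = m

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, pseudo: float = 1e-3) -> np.ndarray:
        p = (self.matrix + pseudo) / (1 + 4 * pseudo)
        return np.log2(p / 0.25)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def reverse_complement(self) -> np.ndarray:
        return self.matrix[::-1, ::-1]


def read_jaspar(path) -> list[MotifModel]:
    """Parse a JASPAR-format PWM collection into probability matrices."""
    from Bio import motifs as bio_motifs
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in BASES]
                           for i in range(m.length)], dtype=float)
        probs = (counts + 0.5) / (counts.sum(axis=1, keepdims=True) + 2.0)
        out.append(MotifModel(motif_id=m.matrix_id or m.name, name=m.name or m.matrix_id,
                              matrix=probs))
    return out


def make_toy_motifs(n: int, length: int = 8, rng=None,
                    concentration: float = 8.0) -> list[MotifModel]:
    """Random sharp planted motifs for synthetic mode."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = []
    for i in range(n):
        consensus = rng.integers(0, 4, size=length)
        mat = np.full((length, 4), 1.0)
        mat[np.arange(length), consensus] = concentration
        mat /= mat.sum(axis=1, keepdims=True)
        out.append(MotifModel(motif_id=f"TOY{i + 1:03d}", name=f"Tf{i + 1}", matrix=mat))
    return out


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; any other base -> -1 (windows containing it are skipped)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _scan_one(code: np.ndarray, lom: np.ndarray) -> float:
    """Best window score of a log-odds matrix along an encoded sequence."""
    L = lom.shape[0]
    n = len(code) - L + 1
    if n <= 0:
        return -np.inf
    windows = np.lib.stride_tricks.sliding_window_view(code, L)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return -np.inf
    w = windows[valid]
    scores = lom[np.arange(L)[None, :], w].sum(axis=1)
    return float(scores.max())


def scan_motifs(peak_sequences: dict[str, str], motifs: list[MotifModel],
                score_fraction: float = 0.8) -> pd.DataFrame:
    """Boolean motif x peak hit matrix; hit = any window on either strand
    scoring >= score_fraction * max possible score."""
    pids = list(peak_sequences)
    codes = {p: encode_sequence(s) for p, s in peak_sequences.items()}
    hits = np.zeros((len(motifs), len(pids)), dtype=bool)
    for mi, motif in enumerate(motifs):
        lom_f = motif.log_odds()
        lom_r = MotifModel(motif.motif_id, motif.name,
                           motif.reverse_complement()).log_odds()
        cutoff = score_fraction * motif.max_score()
        for pj, pid in enumerate(pids):
            code = codes[pid]
            if _scan_one(code, lom_f) >= cutoff or _scan_one(code, lom_r) >= cutoff:
                hits[mi, pj] = True
    return pd.DataFrame(hits, index=[m.motif_id for m in motifs], columns=pids)


def _gc_quantile_bins(gc: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(gc, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, gc, side="right")


def enrich_motifs(target_peaks, all_peaks, hit_matrix: pd.DataFrame,
                  gc_content: pd.Series, n_bg_per_target: int = 40,
                  gc_bins: int = 20, seed: int = 0) -> pd.DataFrame:
    """Hypergeometric motif enrichment in target peaks vs GC-matched background.

    For every target peak, ``n_bg_per_target`` background peaks are sampled
    from its GC quantile bin of the non-target pool (with replacement when a
    bin is shallow). The test compares hit counts in target vs background.
    """
    target = [p for p in target_peaks if p in hit_matrix.columns]
    if not target:
        return pd.DataFrame(columns=["motif_id", "n_target", "n_background",
                                     "fold", "p", "p_adj"])
    pool = [p for p in all_peaks if p in hit_matrix.columns and p not in set(target)]
    gc = gc_content
    rng = np.random.default_rng(seed)
    bins_pool = _gc_quantile_bins(gc[pool].to_numpy(), gc_bins)
    bins_target = np.searchsorted(
        np.unique(np.quantile(gc[pool].to_numpy(),
                              np.linspace(0, 1, gc_bins + 1)[1:-1])),
        gc[target].to_numpy(), side="right")
    pool = np.array(pool, dtype=object)
    bg = []
    for b in bins_target:
        cand = pool[bins_pool == b]
        if len(cand) == 0:
            cand = pool
        replace = len(cand) < n_bg_per_target
        bg.extend(rng.choice(cand, size=n_bg_per_target, replace=replace).tolist())

    n_t, n_b = len(target), len(bg)
    h_t = hit_matrix[target].to_numpy().sum(axis=1)
    # background is a multiset; count hits with multiplicity
    bg_counts = pd.Series(bg).value_counts()
    h_b = (hit_matrix[bg_counts.index].to_numpy() * bg_counts.to_numpy()[None, :]
           ).sum(axis=1)
    N = n_t + n_b
    K = h_t + h_b
    p = stats.hypergeom.sf(h_t - 1, N, K, n_t)
    p_adj = multipletests(p, method="fdr_bh")[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(h_b > 0, (h_t / n_t) / (h_b / n_b),
                        np.where(h_t > 0, np.inf, 0.0))
    out = pd.DataFrame({
        "motif_id": hit_matrix.index,
        "n_target": h_t.astype(int),
        "n_background": h_b.astype(int),
        "fold": fold,
        "p": p,
        "p_adj": p_adj,
    }).sort_values(["p", "motif_id"], kind="stable").reset_index(drop=True)
    return out


def crossref_expression(enrichment: pd.DataFrame, norm_rna, features: list[str],
                        cell_table: pd.DataFrame, motif_to_gene: dict,
                        detection_floor: float = 0.01) -> pd.DataFrame:
    """Join motif enrichment to per-fate-map TF expression summaries.

    Motifs whose TF gene is absent or detected in fewer than
    ``detection_floor`` of cells are flagged undetected; motifs missing from
    the mapping keep null gene fields.
    """
    x = sp.csr_matrix(norm_rna)
    feat_idx = {f: i for i, f in enumerate(features)}
    groups = {g: (cell_table["fatemap"] == g).to_numpy()
              for g in ("RAGnaive", "RAGexp")}
    rows = []
    for _, r in enrichment.iterrows():
        gene = motif_to_gene.get(r["motif_id"])
        rec = {"motif_id": r["motif_id"], "tf_gene": gene, "p_adj": r["p_adj"]}
        if gene is None or gene not in feat_idx:
            rec.update({"undetected": True})
            for g in groups:
                rec[f"mean_{g}"] = np.nan
                rec[f"detect_frac_{g}"] = np.nan
        else:
            vals = np.asarray(x[feat_idx[gene]].todense()).ravel()
            overall_det = float((vals > 0).mean())
            rec["undetected"] = overall_det < detection_floor
            for g, mask in groups.items():
                rec[f"mean_{g}"] = float(vals[mask].mean()) if mask.any() else np.nan
                rec[f"detect_frac_{g}"] = float((vals[mask] > 0).mean()) if mask.any() else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
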