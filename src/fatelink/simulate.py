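"""Synthetic paired RNA+ATAC multiome generator with planted ground truth.

The generator emulates the study design the pipeline targets: four condition
groups (fate map RAGexp/RAGnaive x disease SS/AD), six cell types, a barcode
transcript (default ``tdRFP``) detectable only in RAGexp cells, QC covariates
with planted single-violation failing cells, and latent-factor-coupled
peak-gene pairs planted selectively per condition group at a target Pearson
correlation.

Counts model
------------
Gene counts are negative-binomial around cell-type-specific means; peak
counts are Poisson around peak-specific means. For a planted link (g, p)
active in group G, cells of G share a per-cell standard-normal latent u that
multiplies both the gene mean (``exp(a*u - a^2/2)``) and the peak mean with
the coupling strength ``a`` solved by bisection against a Monte-Carlo
estimate of the realized count correlation. Fragment records are emitted
consistently with the in-peak count matrix, with lengths drawn from a
two-component (nucleosome-free <147 bp / mono-nucleosome 147-294 bp)
mixture whose per-cell weight sets the true nucleosome signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import io as flio
from .types import CellTable, GenomeModel, PairedCounts, PeakSet, peak_id

GROUPS = ("naiveSS", "naiveAD", "expSS", "expAD")
FATEMAPS = ("RAGexp", "RAGnaive")
DISEASES = ("SS", "AD")

QC_FAIL_MODES = (
    "rna_low", "rna_high", "atac_low", "atac_high",
    "mito_high", "ribo_high", "ns_high", "tss_low",
)

LINEAGE_GENES = ("Cd3d", "Cd3e", "Cd3g", "Cd4", "Cd19", "Cd8a", "Itgam")
TH2_GENES = ("Il4", "Il13", "Rad50", "Il5")
N_MITO = 10
N_RIBO = 40


def condition_group(fatemap: str, disease: str) -> str:
    return ("exp" if fatemap == "RAGexp" else "naive") + disease


@dataclass(frozen=True)
class PlantedLink:
    """A peak-gene coupling active in a subset of the four condition groups."""

    gene: str
    peak: str
    groups: frozenset
    target_r: float

    def __post_init__(self):
        if not (0 < self.target_r < 1):
            raise ValueError("target_r must be in (0, 1)")
        if not self.groups or not set(self.groups).issubset(GROUPS):
            raise ValueError(f"groups must be a non-empty subset of {GROUPS}")


@dataclass
class SimDesign:
    """Study-design parameters for the synthetic multiome.

    Defaults emulate the target study: 6 cell types x 2 fate-map states x
    2 disease states, per-cell RNA depth ~3,000 counts and ATAC depth
    ~3,000 fragments (well inside the QC window), tdRFP detection
    probability 0.9 in RAGexp cells with zero false positives.
    """

    celltypes: tuple = ("ILC2", "T", "B", "NK", "DC", "other")
    cells_per_condition: int = 50  # per (celltype x fatemap x disease)
    n_genes: int = 200  # total incl. barcode/lineage/mito/ribo/Th2 blocks
    # genome geometry
    n_chrom: int = 2
    gene_spacing: int = 200_000
    gene_length: int = 2_000
    n_proximal_peaks: int = 3  # within 1e5 bp of TSS
    n_distal_peaks: int = 2  # within (1e5, 1e6] bp of TSS
    peak_width: int = 500
    # expression / accessibility scale
    rna_total_mean: float = 3_000.0
    atac_total_mean: float = 3_000.0
    peak_mean: float = 0.5  # baseline in-peak counts per peak per cell
    nb_theta: float = 10.0
    libsize_sd: float = 0.2
    mito_fraction: float = 0.015
    ribo_base_mean: float = 0.02
    # markers
    markers_per_type: int = 8
    marker_fold: float = 8.0
    marker_peaks_per_type: int = 8
    marker_peak_fold: float = 8.0
    # barcode transcript
    barcode_gene: str = "tdRFP"
    barcode_detect_prob: float = 0.9
    barcode_false_pos: float = 0.0
    # QC planting
    qc_fail_counts: dict = field(default_factory=dict)  # mode -> n cells
    lineage_pos_fraction: float = 0.0
    doublet_fraction: float = 0.0
    ns_weight_pass: float = 0.35
    ns_weight_fail: float = 0.75
    tss_background_fraction: float = 0.4
    # planted links
    planted_links: list = field(default_factory=list)
    # bookkeeping
    emit_fragments: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < self.n_special_genes + 10:
            raise ValueError(
                f"n_genes must be at least {self.n_special_genes + 10} to leave room "
                "for generic genes"
            )
        bad = set(self.qc_fail_counts) - set(QC_FAIL_MODES)
        if bad:
            raise ValueError(f"unknown QC fail modes: {sorted(bad)}")
        for frac in (self.lineage_pos_fraction, self.barcode_detect_prob,
                     self.barcode_false_pos, self.doublet_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions/probabilities must be in [0, 1]")

    @property
    def n_special_genes(self) -> int:
        return 1 + len(LINEAGE_GENES) + N_MITO + N_RIBO + len(TH2_GENES)

    @property
    def gene_symbols(self) -> list[str]:
        mito = [f"mt-G{i + 1}" for i in range(N_MITO)]
        ribo = [f"Rps{i + 1}" for i in range(N_RIBO // 2)] + \
               [f"Rpl{i + 1}" for i in range(N_RIBO // 2)]
        n_generic = self.n_genes - self.n_special_genes
        generic = [f"Gene{i + 1:04d}" for i in range(n_generic)]
        return [self.barcode_gene, *LINEAGE_GENES, *mito, *ribo, *TH2_GENES, *generic]

    @property
    def generic_genes(self) -> list[str]:
        return [s for s in self.gene_symbols if s.startswith("Gene")]

    def marker_plan(self) -> dict:
        """Cell type -> planted up-regulated generic genes (disjoint blocks)."""
        pool = self.generic_genes
        need = self.markers_per_type * len(self.celltypes)
        if need > len(pool):
            raise ValueError("not enough generic genes for the marker plan")
        plan = {}
        for i, ct in enumerate(self.celltypes):
            plan[ct] = pool[i * self.markers_per_type:(i + 1) * self.markers_per_type]
        return plan


def design_from_yaml(path) -> SimDesign:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    links = [
        PlantedLink(d["gene"], d["peak"], frozenset(d["groups"]), float(d["target_r"]))
        for d in cfg.pop("planted_links", [])
    ]
    for key in ("celltypes",):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return SimDesign(planted_links=links, **cfg)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

_PROX_OFFSET = (2_500, 95_000)  # keeps peaks clear of TSS/flank QC windows
_DIST_OFFSET = (150_000, 800_000)


def make_genome(design: SimDesign, seed: int | None = None) -> tuple[GenomeModel, PeakSet]:
    """Tile genes along chromosomes and place candidate peaks near each TSS.

    Each gene receives ``n_proximal_peaks`` peaks within 1e5 bp of its TSS
    and ``n_distal_peaks`` within (1e5, 1e6]. Each peak gets a random
    sequence with beta-distributed GC content.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    symbols = design.gene_symbols
    n = len(symbols)
    per_chrom = int(np.ceil(n / design.n_chrom))
    margin = 1_100_000
    chrom_len = 2 * margin + per_chrom * design.gene_spacing
    chromosomes = [(f"chr{i + 1}", chrom_len) for i in range(design.n_chrom)]

    rows = []
    for i, sym in enumerate(symbols):
        ci, slot = divmod(i, per_chrom)
        start = margin + slot * design.gene_spacing
        end = start + design.gene_length
        if end > chrom_len:
            raise ValueError("genes do not fit chromosome length")
        strand = "+" if (i % 2 == 0) else "-"
        rows.append((f"g{i + 1:04d}", sym, f"chr{ci + 1}", start, end, strand))
    genes = pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"])
    genome = GenomeModel(chromosomes=chromosomes, genes=genes)

    w = design.peak_width
    # peaks are kept mutually disjoint and clear of every TSS +/- 2.5 kb so
    # that fragments land in at most one peak and never in a TSS QC window
    tss_by_chrom = {c: np.sort(sub["tss"].to_numpy())
                    for c, sub in genome.genes.groupby("chrom")}
    placed: dict[str, list] = {c: [] for c, _ in chromosomes}
    peak_rows = []
    for _, g in genome.genes.iterrows():
        tss = g["tss"]
        chrom = g["chrom"]
        tss_arr = tss_by_chrom[chrom]
        for _kind, nk, (lo, hi) in (
            ("prox", design.n_proximal_peaks, _PROX_OFFSET),
            ("dist", design.n_distal_peaks, _DIST_OFFSET),
        ):
            for _ in range(nk):
                for _attempt in range(200):
                    off = int(rng.integers(lo, hi - w))
                    sign = -1 if rng.random() < 0.5 else 1
                    s = tss + sign * off
                    if sign < 0:
                        s -= w
                    if s < 0 or s + w > chrom_len:
                        continue
                    j = np.searchsorted(tss_arr, s - 2_500)
                    if j < len(tss_arr) and tss_arr[j] < s + w + 2_500:
                        continue
                    if any(s < pe and s + w > ps for ps, pe in placed[chrom]):
                        continue
                    break
                else:
                    raise ValueError("could not place a disjoint peak; "
                                     "reduce peak count or widen spacing")
                placed[chrom].append((s, s + w))
                peak_rows.append((chrom, s, s + w, g["symbol"]))
    pk = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "gene"])
    peaks = PeakSet(pk)

    gc = 0.25 + 0.5 * rng.beta(2.0, 2.0, size=len(peaks))
    peaks.peaks["gc"] = gc
    seqs = {}
    bases = np.array(list("ACGT"))
    for pid, g in zip(peaks.ids, gc):
        probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
        seqs[pid] = "".join(bases[rng.choice(4, size=peaks.peaks.loc[pid, "end"] -
                                             peaks.peaks.loc[pid, "start"], p=probs)])
    genome.peak_sequences = seqs
    return genome, peaks


def plant_links(
    genome: GenomeModel,
    peaks: PeakSet,
    n_genes: int,
    groups,
    target_r: float = 0.4,
    rng=None,
    genes: list[str] | None = None,
    exclude_peaks: set | None = None,
    links_per_gene: int = 1,
) -> list[PlantedLink]:
    """Couple random (gene, own candidate peak) pairs.

    Chooses ``n_genes`` distinct genes (generic genes by default) and for
    each one ``links_per_gene`` distinct peaks placed near its TSS.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if genes is None:
        genes = [s for s in genome.genes["symbol"] if s.startswith("Gene")]
    by_gene = peaks.peaks.groupby("gene")
    exclude_peaks = set(exclude_peaks or set())
    chosen_genes = rng.choice(np.array(genes), size=min(n_genes, len(genes)),
                              replace=False)
    links = []
    for g in chosen_genes:
        cand = [p for p in by_gene.get_group(g).index if p not in exclude_peaks]
        if not cand:
            continue
        k = min(links_per_gene, len(cand))
        for p in rng.choice(np.array(cand, dtype=object), size=k, replace=False):
            links.append(PlantedLink(str(g), str(p), frozenset(groups), target_r))
            exclude_peaks.add(p)
    return links


# ---------------------------------------------------------------------------
# latent-factor coupling calibration
# ---------------------------------------------------------------------------

_CALIB_CACHE: dict = {}


def _realized_corr(a: float, mu_g: float, mu_p: float, theta: float,
                   scale_sd: float, rng) -> float:
    u = rng.standard_normal(10_000)
    m = np.exp(a * u - a * a / 2)
    # independent per-cell library-size spread attenuates the correlation
    s1 = rng.lognormal(0.0, scale_sd, size=u.shape)
    s2 = rng.lognormal(0.0, scale_sd, size=u.shape)
    lam_g = mu_g * m * s1
    x = rng.negative_binomial(theta, theta / (theta + lam_g))
    y = rng.poisson(mu_p * m * s2)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def calibrate_coupling(target_r: float, mu_g: float, mu_p: float, theta: float,
                       scale_sd: float = 0.0, link_name: str = "") -> float:
    """Bisection for the shared coupling strength ``a`` reaching target_r.

    Monte-Carlo estimate at 10,000 draws with an internal fixed-seed RNG;
    cached on rounded inputs so repeated links calibrate once.
    """
    key = (round(target_r, 3), round(mu_g, 2), round(mu_p, 3), round(theta, 2),
           round(scale_sd, 3))
    if key in _CALIB_CACHE:
        return _CALIB_CACHE[key]
    rng = np.random.default_rng(12345)
    lo, hi = 0.0, 3.0
    if _realized_corr(hi, mu_g, mu_p, theta, scale_sd, rng) < target_r:
        raise ValueError(
            f"cannot reach target_r={target_r} for link {link_name or key} "
            f"(means {mu_g:.2f}/{mu_p:.2f}, theta {theta})"
        )
    for _ in range(25):
        mid = (lo + hi) / 2
        if _realized_corr(mid, mu_g, mu_p, theta, scale_sd, rng) < target_r:
            lo = mid
        else:
            hi = mid
    a = (lo + hi) / 2
    _CALIB_CACHE[key] = a
    return a


# ---------------------------------------------------------------------------
# count + fragment simulation
# ---------------------------------------------------------------------------

def simulate_counts(
    genome: GenomeModel,
    peaks: PeakSet,
    design: SimDesign,
    seed: int | None = None,
) -> tuple[PairedCounts, CellTable]:
    """Draw the paired count matrices, truth table and fragment records."""
    seed = design.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_cells, rng_rna, rng_atac, rng_frag = [np.random.default_rng(s) for s in ss.spawn(4)]

    symbols = list(genome.genes["symbol"])
    sym_idx = {s: i for i, s in enumerate(symbols)}
    pids = peaks.ids
    pid_idx = {p: i for i, p in enumerate(pids)}
    n_genes, n_peaks = len(symbols), len(pids)

    # --- cell grid -------------------------------------------------------
    ct_list, fm_list, ds_list = [], [], []
    for ct in design.celltypes:
        for fm in FATEMAPS:
            for dsx in DISEASES:
                ct_list += [ct] * design.cells_per_condition
                fm_list += [fm] * design.cells_per_condition
                ds_list += [dsx] * design.cells_per_condition
    n_cells = len(ct_list)
    order = rng_cells.permutation(n_cells)
    celltype = np.array(ct_list)[order]
    fatemap = np.array(fm_list)[order]
    disease = np.array(ds_list)[order]
    group = np.array([condition_group(f, d) for f, d in zip(fatemap, disease)])
    barcodes = [f"C{i + 1:05d}" for i in range(n_cells)]

    planted_fail = np.array([""] * n_cells, dtype=object)
    n_fail = sum(design.qc_fail_counts.values())
    if n_fail > n_cells:
        raise ValueError("more planted QC failures than cells")
    fail_cells = rng_cells.choice(n_cells, size=n_fail, replace=False)
    pos = 0
    for mode in QC_FAIL_MODES:
        k = design.qc_fail_counts.get(mode, 0)
        planted_fail[fail_cells[pos:pos + k]] = mode
        pos += k

    lineage_pos = rng_cells.random(n_cells) < design.lineage_pos_fraction
    doublet = rng_cells.random(n_cells) < design.doublet_fraction

    # --- RNA means -------------------------------------------------------
    mito_syms = [s for s in symbols if s.startswith("mt-")]
    ribo_syms = [s for s in symbols if s.startswith(("Rps", "Rpl"))]
    silent = {design.barcode_gene, *LINEAGE_GENES}
    expressed = [s for s in symbols
                 if s not in silent and s not in mito_syms and s not in ribo_syms]

    gene_mu = np.zeros(n_genes)
    u = rng_rna.lognormal(0.0, 0.4, size=len(expressed))
    u /= u.mean()
    base_share = design.rna_total_mean * (1 - design.mito_fraction) / len(expressed)
    for s, w in zip(expressed, u):
        gene_mu[sym_idx[s]] = base_share * w
    for s in mito_syms:
        gene_mu[sym_idx[s]] = design.rna_total_mean * design.mito_fraction / len(mito_syms)
    for s in ribo_syms:
        gene_mu[sym_idx[s]] = design.ribo_base_mean

    M = np.tile(gene_mu[:, None], (1, n_cells))

    plan = design.marker_plan()
    for ct, marker_genes in plan.items():
        cells_ct = celltype == ct
        for s in marker_genes:
            M[sym_idx[s], cells_ct] *= design.marker_fold

    # per-cell RNA scale with planted violations; fail scales are drawn with
    # wide margins past the bound so exactly that bound is violated
    rna_scale = rng_rna.lognormal(0.0, design.libsize_sd, size=n_cells)
    n_rlo = int((planted_fail == "rna_low").sum())
    n_rhi = int((planted_fail == "rna_high").sum())
    rna_scale[planted_fail == "rna_low"] = \
        rng_rna.uniform(200, 500, size=n_rlo) / design.rna_total_mean
    rna_scale[planted_fail == "rna_high"] = \
        rng_rna.uniform(20_000, 30_000, size=n_rhi) / design.rna_total_mean
    M *= rna_scale[None, :]
    mito_rows = [sym_idx[s] for s in mito_syms]
    ribo_rows = [sym_idx[s] for s in ribo_syms]
    mito_hi = planted_fail == "mito_high"
    if mito_hi.any():
        M[np.ix_(mito_rows, np.where(mito_hi)[0])] *= 12.0
    ribo_hi = planted_fail == "ribo_high"
    if ribo_hi.any():
        M[np.ix_(ribo_rows, np.where(ribo_hi)[0])] = 8.0 * rna_scale[ribo_hi][None, :]

    # --- ATAC means ------------------------------------------------------
    w = rng_atac.lognormal(0.0, 0.3, size=n_peaks)
    w /= w.mean()
    peak_mu = design.peak_mean * w
    P = np.tile(peak_mu[:, None], (1, n_cells))
    for i, ct in enumerate(design.celltypes):
        marker_genes = plan[ct]
        mp = []
        for s in marker_genes[:design.marker_peaks_per_type]:
            own = peaks.peaks.index[peaks.peaks["gene"] == s]
            if len(own):
                mp.append(pid_idx[own[0]])
        if mp:
            P[np.ix_(mp, np.where(celltype == ct)[0])] *= design.marker_peak_fold

    atac_scale = rng_atac.lognormal(0.0, design.libsize_sd, size=n_cells)
    n_alo = int((planted_fail == "atac_low").sum())
    n_ahi = int((planted_fail == "atac_high").sum())
    atac_scale[planted_fail == "atac_low"] = \
        rng_atac.uniform(30, 60, size=n_alo) / design.atac_total_mean
    atac_scale[planted_fail == "atac_high"] = \
        rng_atac.uniform(85_000, 110_000, size=n_ahi) / design.atac_total_mean
    P *= atac_scale[None, :]
    # atac_low cells keep most fragments at TSSs (see _emit_fragments) so the
    # TSS-enrichment bound still passes; shrink their in-peak share to match
    P[:, planted_fail == "atac_low"] *= 0.2

    # --- planted link couplings -----------------------------------------
    for link in design.planted_links:
        gi = sym_idx.get(link.gene)
        pi = pid_idx.get(link.peak)
        if gi is None or pi is None:
            raise ValueError(f"planted link references unknown feature: {link}")
        active = np.isin(group, list(link.groups))
        if not active.any():
            continue
        mu_g = float(np.median(M[gi, active]))
        mu_p = float(np.median(P[pi, active]))
        a = calibrate_coupling(link.target_r, mu_g, mu_p, design.nb_theta,
                               scale_sd=design.libsize_sd,
                               link_name=f"{link.gene}~{link.peak}")
        uvec = rng_rna.standard_normal(int(active.sum()))
        m = np.exp(a * uvec - a * a / 2)
        M[gi, active] *= m
        P[pi, active] *= m

    # --- draws -----------------------------------------------------------
    theta = design.nb_theta
    with np.errstate(divide="ignore", invalid="ignore"):
        pnb = theta / (theta + M)
    rna = rng_rna.negative_binomial(theta, pnb).astype(np.int64)
    atac = rng_atac.poisson(P).astype(np.int64)

    # lineage-positive planting: positives get >=1 count of >=1 lineage gene
    lin_rows = [sym_idx[s] for s in LINEAGE_GENES]
    for c in np.where(lineage_pos)[0]:
        k = 1 + rng_rna.integers(0, 3)
        rows = rng_rna.choice(lin_rows, size=k, replace=False)
        rna[rows, c] = 1 + rng_rna.poisson(2.0, size=k)

    # barcode transcript
    bc_row = sym_idx[design.barcode_gene]
    is_exp = fatemap == "RAGexp"
    det = rng_rna.random(n_cells) < np.where(is_exp, design.barcode_detect_prob,
                                             design.barcode_false_pos)
    rna[bc_row, det] = 1 + rng_rna.poisson(1.0, size=int(det.sum()))

    # --- fragments -------------------------------------------------------
    ns_weight = np.where(planted_fail == "ns_high", design.ns_weight_fail,
                         design.ns_weight_pass)
    fragments = None
    if design.emit_fragments:
        # TSS-background fragments favor the cell type's marker genes so the
        # gene-activity assay carries the same planted cell-type signal as
        # expression does
        tss_weights = {}
        for ct, marker_genes in plan.items():
            wvec = np.ones(n_genes)
            for s in marker_genes:
                wvec[sym_idx[s]] = design.marker_fold
            tss_weights[ct] = wvec / wvec.sum()
        fragments = _emit_fragments(
            genome, peaks, atac, barcodes, ns_weight, atac_scale,
            planted_fail, celltype, tss_weights, design, rng_frag,
        )

    paired = PairedCounts(
        rna=sp.csr_matrix(rna),
        rna_features=symbols,
        atac=sp.csr_matrix(atac),
        atac_features=pids,
        barcodes=barcodes,
        fragments=fragments,
    )
    cells = CellTable(pd.DataFrame({
        "celltype": celltype,
        "fatemap": fatemap,
        "disease": disease,
        "group": group,
        "planted_fail": planted_fail,
        "lineage_pos": lineage_pos,
        "doublet": doublet,
        "true_ns_weight": ns_weight,
        "rna_scale": rna_scale,
        "atac_scale": atac_scale,
    }, index=pd.Index(barcodes, name="barcode")))
    return paired, cells


def _mixture_lengths(n: int, w, rng) -> np.ndarray:
    """Fragment lengths: mono-nucleosome (147-294) w.p. w, else short (30-146)."""
    mono = rng.random(n) < w
    out = np.empty(n, dtype=np.int64)
    out[mono] = rng.integers(147, 295, size=int(mono.sum()))
    out[~mono] = rng.integers(30, 147, size=int((~mono).sum()))
    return out


def _emit_fragments(genome, peaks, atac, barcodes, ns_weight, atac_scale,
                    planted_fail, celltype, tss_weights, design,
                    rng) -> pd.DataFrame:
    pk = peaks.peaks
    p_start = pk["start"].to_numpy()
    p_end = pk["end"].to_numpy()
    p_chrom = pk["chrom"].to_numpy()
    chrom_names = [c for c, _ in genome.chromosomes]
    chrom_len = {c: l for c, l in genome.chromosomes}

    coo = sp.coo_matrix(atac)
    rows, cols, vals = coo.row, coo.col, coo.data
    n_rec = len(rows)
    lens = _mixture_lengths(n_rec, ns_weight[cols], rng)
    span = p_end[rows] - p_start[rows] - lens
    span = np.maximum(span, 1)
    starts = p_start[rows] + (rng.random(n_rec) * span).astype(np.int64)
    in_peak = {
        "chrom": p_chrom[rows],
        "start": starts,
        "end": starts + lens,
        "barcode": np.array(barcodes, dtype=object)[cols],
        "count": vals.astype(np.int64),
    }

    # background fragments: a TSS-window component plus a uniform component
    # placed outside peaks (keeps in-peak tallies equal to the count matrix)
    tss = genome.genes["tss"].to_numpy()
    g_chrom = genome.genes["chrom"].to_numpy()
    bg_parts = []
    n_cells = len(barcodes)
    bg_base = max(0.0, design.atac_total_mean - design.peak_mean * len(pk))
    bg_total = np.round(bg_base * atac_scale).astype(np.int64)
    rec_count = np.maximum(1, np.round(atac_scale).astype(np.int64))
    for c in range(n_cells):
        total = int(bg_total[c])
        if planted_fail[c] == "atac_low":
            # all background at TSSs so the enrichment bound is the only
            # one this cell can still pass; 70 singleton records suffice
            total, tss_frac = 70, 1.0
        else:
            tss_frac = design.tss_background_fraction
        if total <= 0:
            continue
        cval = int(rec_count[c])
        n_records = max(1, total // cval)
        n_tss = int(round(n_records * tss_frac))
        n_unif = n_records - n_tss
        parts = []
        if n_tss:
            gi = rng.choice(len(tss), size=n_tss, p=tss_weights[celltype[c]])
            ls = _mixture_lengths(n_tss, ns_weight[c], rng)
            if planted_fail[c] == "tss_low":
                # place in the distal flank windows instead of at the TSS
                sign = np.where(rng.random(n_tss) < 0.5, -1, 1)
                center = tss[gi] + sign * 1950
            else:
                center = tss[gi] + rng.integers(-80, 81, size=n_tss)
            s = np.maximum(0, center - ls // 2)
            parts.append((g_chrom[gi], s, s + ls))
        if n_unif:
            chrom_choice = rng.integers(0, len(chrom_names), size=n_unif)
            ls = _mixture_lengths(n_unif, ns_weight[c], rng)
            s = np.empty(n_unif, dtype=np.int64)
            for ci, cname in enumerate(chrom_names):
                mask = chrom_choice == ci
                if not mask.any():
                    continue
                cand = rng.integers(0, chrom_len[cname] - 300, size=int(mask.sum()))
                # reject draws overlapping a peak on this chromosome: a
                # candidate [c, c+300) overlaps a peak iff the running max
                # peak end among peaks starting before c+300 exceeds c
                on = p_chrom == cname
                ps = p_start[on]
                pe_cummax = np.maximum.accumulate(p_end[on]) if on.any() else np.array([])

                def _overlaps(c):
                    if len(ps) == 0:
                        return np.zeros(len(c), dtype=bool)
                    j = np.searchsorted(ps, c + 300, side="left")
                    out = j > 0
                    out[j > 0] &= pe_cummax[j[j > 0] - 1] > c[j > 0]
                    return out

                bad = _overlaps(cand)
                for _ in range(20):
                    if not bad.any():
                        break
                    cand[bad] = rng.integers(0, chrom_len[cname] - 300, size=int(bad.sum()))
                    bad = _overlaps(cand)
                s[mask] = cand
            chroms = np.array(chrom_names, dtype=object)[chrom_choice]
            parts.append((chroms, s, s + ls))
        for chroms, s, e in parts:
            k = len(s)
            bg_parts.append(pd.DataFrame({
                "chrom": chroms,
                "start": s,
                "end": e,
                "barcode": barcodes[c],
                "count": cval,
            }))
    frames = [pd.DataFrame(in_peak)] + bg_parts
    frags = pd.concat(frames, ignore_index=True)
    frags = frags.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return frags


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fixture(paired: PairedCounts, cells: CellTable, genome: GenomeModel,
                  peaks: PeakSet, out_dir, seed: int | None = None,
                  overwrite: bool = False) -> None:
    """Write the full file set: MTX trios, fragments, gene table, peak BED, truth CSV."""
    out = flio.ensure_outdir(out_dir, overwrite=overwrite)
    flio.write_mtx_triplet(paired.rna, paired.rna_features, paired.barcodes,
                           out / "rna.mtx", out / "rna_features.tsv", out / "barcodes.tsv")
    flio.write_mtx_triplet(paired.atac, paired.atac_features, paired.barcodes,
                           out / "atac.mtx", out / "atac_features.tsv", out / "barcodes.tsv")
    if paired.fragments is not None:
        flio.write_fragments(paired.fragments, out / "fragments.tsv.gz")
    flio.write_gene_table(genome.genes, out / "genes.tsv")
    flio.write_peaks_bed(peaks, out / "peaks.bed")
    if "gc" in peaks.peaks:
        peaks.peaks["gc"].to_csv(out / "peaks_gc.tsv", sep="\t", header=False)
    if genome.peak_sequences:
        with open(out / "peak_sequences.fasta", "w") as fh:
            for pid, seq in genome.peak_sequences.items():
                fh.write(f">{pid}\n{seq}\n")
    cells.df.to_csv(out / "cells_truth.csv")
    manifest = {"seed": seed, "n_cells": paired.n_cells,
                "n_genes": len(paired.rna_features), "n_peaks": len(paired.atac_features)}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def read_fixture(out_dir):
    """Read back a written fixture as (PairedCounts, CellTable)."""
    from pathlib import Path
    out = Path(out_dir)
    rna, rf, bc = flio.read_mtx_triplet(out / "rna.mtx", out / "rna_features.tsv",
                                        out / "barcodes.tsv")
    atac, af, _ = flio.read_mtx_triplet(out / "atac.mtx", out / "atac_features.tsv",
                                        out / "barcodes.tsv")
    frags = None
    fp = out / "fragments.tsv.gz"
    if fp.exists():
        frags = flio.read_fragments(fp)
    paired = PairedCounts(rna=rna, rna_features=rf, atac=atac, atac_features=af,
                          barcodes=bc, fragments=frags)
    cells = CellTable(pd.read_csv(out / "cells_truth.csv", index_col=0))
    return paired, cells


def default_design(**overrides) -> SimDesign:
    return SimDesign(**overrides)
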