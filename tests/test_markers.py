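import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from fatelink import markers as flm
from fatelink import reduce as flr
from fatelink import simulate as sim
from fatelink.types import GenomeModel, PeakSet
from oracles import (brute_force_closest_gene, brute_force_gene_activity,
                     exact_wilcoxon_p, logistic_llf_optimizer)


def _toy_genome(n_genes=20, spacing=12_000, length=400_000):
    rng = np.random.default_rng(1)
    genes = pd.DataFrame({
        "gene_id": [f"g{i:02d}" for i in range(n_genes)],
        "symbol": [f"G{i:02d}" for i in range(n_genes)],
        "chrom": "chr1",
        "start": [5_000 + i * spacing for i in range(n_genes)],
        "end": [5_000 + i * spacing + int(rng.integers(1_000, 4_000))
                for i in range(n_genes)],
        "strand": [("+" if i % 2 else "-") for i in range(n_genes)],
    })
    return GenomeModel(chromosomes=[("chr1", length)], genes=genes)


def test_gene_activity_edge_cases():
    genome = _toy_genome(3)
    empty = pd.DataFrame(columns=["chrom", "start", "end", "barcode", "count"])
    assert flm.gene_activity(empty, genome, ["A"]).nnz == 0

    g = genome.genes.iloc[0]
    frag = pd.DataFrame([{"chrom": "chr1", "start": g["start"] + 10,
                          "end": g["start"] + 110, "barcode": "A", "count": 1}])
    ga = np.asarray(flm.gene_activity(frag, genome, ["A", "B"]).todense())
    assert ga[0, 0] == 1 and ga.sum() == 1


def test_gene_activity_equals_brute_force_overlap_count():
    genome = _toy_genome(20)
    rng = np.random.default_rng(2)
    n = 5_000
    starts = rng.integers(0, 395_000, n)
    frags = pd.DataFrame({
        "chrom": "chr1",
        "start": starts,
        "end": starts + rng.integers(30, 300, n),
        "barcode": rng.choice([f"c{i}" for i in range(8)], n),
        "count": rng.integers(1, 3, n),
    })
    barcodes = [f"c{i}" for i in range(8)]
    got = np.asarray(flm.gene_activity(frags, genome, barcodes).todense())
    expected = brute_force_gene_activity(frags, genome.genes, barcodes)
    np.testing.assert_array_equal(got, expected)


def test_wilcoxon_p_matches_exact_enumeration():
    rng = np.random.default_rng(3)
    for _ in range(5):
        x_in = rng.random(4)
        x_out = rng.random(5)
        mat = sp.csr_matrix(np.concatenate([x_in, x_out])[None, :])
        clusters = np.array(["in"] * 4 + ["out"] * 5)
        table = flm.find_markers_ranksum(mat, ["f"], clusters,
                                         min_pct=0.0, logfc_min=-10)
        got = table.loc[table["cluster"] == "in", "p"].iloc[0]
        assert got == pytest.approx(exact_wilcoxon_p(x_in, x_out), abs=1e-12)


def test_identical_distributions_filtered_by_logfc():
    rng = np.random.default_rng(4)
    vals = rng.random(60)
    mat = sp.csr_matrix(vals[None, :])
    clusters = np.array(["a"] * 30 + ["b"] * 30)
    table = flm.find_markers_ranksum(mat, ["f"], clusters)
    assert len(table) == 0  # log2fc ~ 0 < 0.25


def test_planted_markers_recovered_with_low_p():
    hits = 0
    for seed in range(5):
        design = sim.SimDesign(celltypes=("A", "B"), cells_per_condition=75,
                               n_genes=120, emit_fragments=False, seed=seed)
        genome, peaks = sim.make_genome(design, seed=seed)
        paired, cells = sim.simulate_counts(genome, peaks, design, seed=seed)
        table = flm.find_markers_ranksum(flr.lognormalize(paired.rna),
                                         paired.rna_features,
                                         cells.df["celltype"].to_numpy())
        planted = set(design.marker_plan()["A"])
        top = table[(table["cluster"] == "A") & (table["p_adj"] < 0.01)]
        hits += len(planted & set(top["feature"])) / len(planted)
    assert hits / 5 >= 0.9


def test_lr_statistic_matches_independent_optimizer():
    rng = np.random.default_rng(5)
    y = (rng.random(30) < 0.4).astype(float)
    log_total = np.log1p(rng.integers(500, 5_000, 30).astype(float))
    peak = (rng.random(30) < 0.3 + 0.3 * y).astype(float)
    lr_stat, p, flagged = flm.lr_test_peak(y, log_total, peak)
    X0 = np.column_stack([np.ones(30), log_total])
    X1 = np.column_stack([X0, peak])
    expected = 2 * (logistic_llf_optimizer(y, X1) - logistic_llf_optimizer(y, X0))
    assert not flagged
    assert lr_stat == pytest.approx(max(0.0, expected), abs=1e-4)


def test_planted_da_peak_top_ranked():
    design = sim.SimDesign(celltypes=("A", "B"), cells_per_condition=50,
                           n_genes=120, emit_fragments=False,
                           marker_peak_fold=10, seed=6)
    genome, peaks = sim.make_genome(design, seed=6)
    paired, cells = sim.simulate_counts(genome, peaks, design, seed=6)
    totals = np.asarray(paired.atac.sum(axis=0)).ravel()
    table = flm.find_da_peaks_lr(paired.atac, paired.atac_features,
                                 cells.df["celltype"].to_numpy(), totals)
    marker_gene = design.marker_plan()["A"][0]
    planted_peak = peaks.peaks.index[peaks.peaks["gene"] == marker_gene][0]
    # the LR test is direction-agnostic; the planted peak must lead the
    # positive-direction (enriched-in-cluster) ranking
    pos_a = table[(table["cluster"] == "A") & (table["log2fc"] > 0)]
    top_a = pos_a.nsmallest(design.marker_peaks_per_type, "rank")
    assert planted_peak in set(top_a["feature"])


def test_closest_gene_matches_brute_force_and_drops_distant():
    genome = _toy_genome(20)
    rng = np.random.default_rng(7)
    starts = rng.integers(0, 390_000, 50)
    pk = PeakSet.from_arrays(["chr1"] * 50, starts, starts + 400)
    got = flm.closest_gene(pk, genome, max_dist=20_000)
    expected = brute_force_closest_gene(pk.peaks, genome.genes, 20_000)
    assert set(got.index) == set(expected)
    for pid in got.index:
        assert (got.loc[pid, "gene"], got.loc[pid, "distance"]) == expected[pid]

    far_genome = GenomeModel(chromosomes=[("chr1", 1_000_000)],
                             genes=genome.genes.iloc[:1][
                                 ["gene_id", "symbol", "chrom", "start", "end",
                                  "strand"]])
    far_peak = PeakSet.from_arrays(["chr1"], [160_000], [160_400])
    assert len(flm.closest_gene(far_peak, far_genome, max_dist=100_000)) == 0

    inside = PeakSet.from_arrays(["chr1"], [genome.genes.iloc[0]["start"] + 100],
                                 [genome.genes.iloc[0]["start"] + 300])
    res = flm.closest_gene(inside, genome)
    assert res.iloc[0]["distance"] == 0


def test_signature_edge_cases():
    def table(feats, assay):
        return pd.DataFrame({"assay": assay, "cluster": "ILC2", "feature": feats,
                             "rank": np.arange(1, len(feats) + 1)})

    a = [f"a{i}" for i in range(100)]
    b = [f"b{i}" for i in range(100)]
    c = [f"c{i}" for i in range(100)]
    sig = flm.multiomic_signature(table(a, "GEX"), table(b, "GA"), table(c, "DA"),
                                  "ILC2")
    assert len(sig.union) == 300
    assert sig.venn["gex_ga_da"] == 0 and sig.venn["gex_only"] == 100

    sig2 = flm.multiomic_signature(table(a, "GEX"), table(a, "GA"), table(a, "DA"),
                                   "ILC2")
    assert len(sig2.union) == 100
    assert sig2.venn["gex_ga_da"] == 100


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_signature_venn_counts_always_sum_to_union(seed):
    rng = np.random.default_rng(seed)
    pool = [f"g{i}" for i in range(40)]

    def table(assay):
        feats = rng.choice(pool, size=rng.integers(1, 25), replace=False)
        return pd.DataFrame({"assay": assay, "cluster": "x", "feature": feats,
                             "rank": np.arange(1, len(feats) + 1)})

    with pytest.warns(UserWarning):
        sig = flm.multiomic_signature(table("GEX"), table("GA"), table("DA"),
                                      "x", top_n=100)
    assert sum(sig.venn.values()) == len(sig.union)
    assert set(sig.union) == set(sig.gex_top) | set(sig.ga_top) | set(sig.da_top)


def test_ga_assay_recovers_planted_celltype_markers():
    """Gene-activity markers mirror the planted expression markers."""
    design = sim.SimDesign(celltypes=("A", "B"), cells_per_condition=60,
                           n_genes=120, seed=77)
    genome, peaks = sim.make_genome(design, seed=77)
    paired, cells = sim.simulate_counts(genome, peaks, design, seed=77)
    ga = flm.gene_activity(paired.fragments, genome, paired.barcodes)
    table = flm.find_markers_ranksum(flr.lognormalize(ga),
                                     list(genome.genes["symbol"]),
                                     cells.df["celltype"].to_numpy(), assay="GA")
    planted = set(design.marker_plan()["A"])
    sig = table[(table["cluster"] == "A") & (table["p_adj"] < 0.01)]
    assert len(planted & set(sig["feature"])) >= 0.9 * len(planted)


def test_three_assay_signature_converges_on_planted_markers():
    """GEX, GA and gene-mapped DA top lists all contain the planted markers."""
    design = sim.SimDesign(celltypes=("A", "B"), cells_per_condition=60,
                           n_genes=120, seed=78)
    genome, peaks = sim.make_genome(design, seed=78)
    paired, cells = sim.simulate_counts(genome, peaks, design, seed=78)
    labels = cells.df["celltype"].to_numpy()
    gex = flm.find_markers_ranksum(flr.lognormalize(paired.rna),
                                   paired.rna_features, labels, assay="GEX")
    ga = flm.find_markers_ranksum(
        flr.lognormalize(flm.gene_activity(paired.fragments, genome,
                                           paired.barcodes)),
        list(genome.genes["symbol"]), labels, assay="GA")
    totals = np.asarray(paired.atac.sum(axis=0)).ravel()
    da = flm.find_da_peaks_lr(paired.atac, paired.atac_features, labels, totals)
    da = da[da["log2fc"] > 0]
    mapping = flm.closest_gene(peaks, genome)
    da = da[da["feature"].isin(mapping.index)].copy()
    da["feature"] = mapping.loc[da["feature"], "gene"].to_numpy()
    sig = flm.multiomic_signature(gex, ga, da, "A", top_n=10)
    planted = set(design.marker_plan()["A"])
    assert len(planted & set(sig.union)) >= 0.9 * len(planted)
    assert sig.venn["gex_ga_da"] >= 4  # the assays converge on shared genes
    assert sum(sig.venn.values()) == len(sig.union)
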