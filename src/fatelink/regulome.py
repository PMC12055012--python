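"""Regulome comparison: GPL counting, UpSet-style exclusive intersections,
induced-peak discovery and induced-gene ranking.

The per-gene count of retained gene-to-peak links is interpreted as the
regulome activity of that gene in a cell population. Comparing counts
between fate-map populations ranks genes by how much regulatory linkage
they gain or lose with a history of RAG expression; intersecting the four
condition groups' non-redundant link-peak sets isolates peaks "induced" by
inflammation in RAG-experienced cells (present in both RAG-naive groups and
in RAGexp under AD-like disease, absent from RAGexp at steady state).
"""

from __future__ import annotations

import itertools
import warnings

import pandas as pd

FOUR_WAY = ("naiveSS", "naiveAD", "expSS", "expAD")
INDUCED_COMBO = frozenset({"naiveSS", "naiveAD", "expAD"})
TH2_GENES = ("Il4", "Il13", "Rad50", "Il5")


def gpl_count_diff(link_tables: dict[str, pd.DataFrame],
                   gene_set) -> pd.DataFrame:
    """Per-gene link counts for the naive and exp tables, sorted by difference.

    ``diff = n_links_naive - n_links_exp``; descending, ties by gene symbol.
    Genes absent from both tables keep counts (0, 0).
    """
    naive, exp = link_tables["naive"], link_tables["exp"]
    genes = list(gene_set)
    cn = naive["gene"].value_counts() if len(naive) else pd.Series(dtype=int)
    ce = exp["gene"].value_counts() if len(exp) else pd.Series(dtype=int)
    df = pd.DataFrame({
        "gene": genes,
        "n_links_naive": [int(cn.get(g, 0)) for g in genes],
        "n_links_exp": [int(ce.get(g, 0)) for g in genes],
    })
    df["diff"] = df["n_links_naive"] - df["n_links_exp"]
    df = df.sort_values(["diff", "gene"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = df.index + 1
    return df


def unique_link_peaks(link_table: pd.DataFrame) -> set[str]:
    """Non-redundant peak set: distinct peak ids appearing in >= 1 link."""
    if len(link_table) == 0:
        return set()
    return set(link_table["peak"])


def peak_intersections(peak_sets: dict[str, set]) -> tuple[pd.DataFrame, pd.Series]:
    """Exclusive (UpSet) membership of every peak across the four sets.

    Returns the membership table (one row per peak in the union, boolean
    member flags plus the exclusive combination label) and the sizes of all
    15 non-empty combinations. Combination sizes always sum to |union|.
    """
    names = list(peak_sets)
    union = sorted(set().union(*peak_sets.values())) if peak_sets else []
    rows = []
    for pid in union:
        member = {n: pid in peak_sets[n] for n in names}
        combo = "&".join(n for n in names if member[n])
        rows.append({"peak_id": pid, **member, "exclusive_combo": combo})
    membership = pd.DataFrame(rows, columns=["peak_id", *names, "exclusive_combo"])
    membership = membership.set_index("peak_id") if len(rows) else membership

    combos = []
    for r in range(1, len(names) + 1):
        for sub in itertools.combinations(names, r):
            combos.append("&".join(sub))
    if len(rows):
        counts = membership["exclusive_combo"].value_counts()
    else:
        counts = pd.Series(dtype=int)
    sizes = pd.Series({c: int(counts.get(c, 0)) for c in combos}, name="size")
    return membership, sizes


def inclusive_intersection_sizes(peak_sets: dict[str, set]) -> pd.Series:
    """|intersection| per combination without exclusivity (sensitivity mode).

    Unlike the exclusive (UpSet) sizes, these do not partition the union: a
    peak in all four sets contributes to every combination containing it.
    """
    names = list(peak_sets)
    sizes = {}
    for r in range(1, len(names) + 1):
        for sub in itertools.combinations(names, r):
            inter = set.intersection(*[peak_sets[n] for n in sub])
            sizes["&".join(sub)] = len(inter)
    return pd.Series(sizes, name="size")


def induced_peaks(membership: pd.DataFrame,
                  combo: frozenset = INDUCED_COMBO) -> set[str]:
    """Peaks whose exclusive combination is exactly the induced pattern."""
    if len(membership) == 0:
        return set()
    target = set(combo)
    sel = membership["exclusive_combo"].map(
        lambda c: set(c.split("&")) == target if c else False)
    return set(membership.index[sel])


def rank_induced_genes(induced_set: set[str],
                       link_tables: dict[str, pd.DataFrame],
                       gene_set) -> pd.DataFrame:
    """Genes ranked by number of distinct links whose peak is induced.

    Links are deduplicated by (gene, peak) across the group tables, so a
    link found in two groups counts once.
    """
    seen = set()
    for name, table in link_tables.items():
        if name == "all" or len(table) == 0:
            continue
        seen.update(zip(table["gene"], table["peak"]))
    genes = list(gene_set)
    counts = {g: 0 for g in genes}
    for g, p in seen:
        if g in counts and p in induced_set:
            counts[g] += 1
    df = pd.DataFrame({"gene": genes,
                       "n_induced_links": [counts[g] for g in genes]})
    df = df.sort_values(["n_induced_links", "gene"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = df.index + 1
    return df


def crosstalk_peaks(link_tables: dict[str, pd.DataFrame], gene_set) -> dict[str, set]:
    """Peaks linked to >= 2 genes of the set ("crosstalk"), across groups."""
    gene_set = set(gene_set)
    by_peak: dict[str, set] = {}
    for name, table in link_tables.items():
        if name == "all" or len(table) == 0:
            continue
        for g, p in zip(table["gene"], table["peak"]):
            if g in gene_set:
                by_peak.setdefault(p, set()).add(g)
    return {p: gs for p, gs in by_peak.items() if len(gs) >= 2}


def th2_locus_report(fatemap_tables: dict[str, pd.DataFrame],
                     four_way_tables: dict[str, pd.DataFrame] | None = None,
                     th2_genes=TH2_GENES,
                     known_genes=None) -> dict:
    """Full regulome comparison restricted to the Th2 locus genes.

    Returns the per-gene GPL count difference, the exclusive peak
    intersections plus induced set (when four-way tables are given), and
    the crosstalk peaks shared between locus genes.
    """
    genes = list(th2_genes)
    if known_genes is not None:
        missing = [g for g in genes if g not in set(known_genes)]
        if missing:
            warnings.warn(f"Th2 locus genes missing from annotation: {missing}")
            genes = [g for g in genes if g not in missing]
    def restrict(t):
        return t[t["gene"].isin(genes)].reset_index(drop=True) if len(t) else t

    fm = {k: restrict(v) for k, v in fatemap_tables.items()}
    report = {
        "genes": genes,
        "gpl_summary": gpl_count_diff(fm, genes),
        "crosstalk": crosstalk_peaks(fm, genes),
    }
    if four_way_tables is not None:
        fw = {k: restrict(v) for k, v in four_way_tables.items() if k != "all"}
        sets = {k: unique_link_peaks(fw[k]) for k in FOUR_WAY if k in fw}
        membership, sizes = peak_intersections(sets)
        ind = induced_peaks(membership)
        report.update({
            "membership": membership,
            "combo_sizes": sizes,
            "induced_peaks": ind,
            "induced_ranking": rank_induced_genes(ind, fw, genes),
        })
    return report
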