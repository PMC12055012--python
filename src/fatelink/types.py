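"""Shared domain containers.

All genomic coordinates are 0-based half-open (BED convention). GTF input is
converted at the I/O boundary. Peak identifiers are canonical
``"chrom:start-end"`` strings; set operations on peaks compare ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

GENE_TABLE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]


def peak_id(chrom: str, start: int, end: int) -> str:
    """Canonical peak identifier."""
    return f"{chrom}:{start}-{end}"


def parse_peak_id(pid: str) -> tuple[str, int, int]:
    chrom, _, rest = pid.rpartition(":")
    start, _, end = rest.partition("-")
    return chrom, int(start), int(end)


def tss_positions(genes: pd.DataFrame) -> pd.Series:
    """Strand-aware TSS: ``start`` on '+', ``end - 1`` on '-'."""
    plus = genes["strand"] == "+"
    return pd.Series(
        np.where(plus, genes["start"], genes["end"] - 1),
        index=genes.index,
        name="tss",
    )


@dataclass
class GenomeModel:
    """Gene annotation plus (optionally) per-peak nucleotide sequences.

    Parameters
    ----------
    chromosomes
        ``[(name, length_bp), ...]``.
    genes
        DataFrame with columns ``gene_id, symbol, chrom, start, end, strand``
        (0-based half-open). A ``tss`` column is derived on construction.
    peak_sequences
        Optional map ``peak_id -> A/C/G/T string`` for motif work.
    """

    chromosomes: list[tuple[str, int]]
    genes: pd.DataFrame
    peak_sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        g = self.genes.reset_index(drop=True).copy()
        lengths = dict(self.chromosomes)
        if not set(g["strand"]).issubset({"+", "-"}):
            bad = sorted(set(g["strand"]) - {"+", "-"})
            raise ValueError(f"unknown strand symbol(s): {bad}")
        if (g["start"] < 0).any() or (g["start"] >= g["end"]).any():
            raise ValueError("gene intervals must satisfy 0 <= start < end")
        for chrom, sub in g.groupby("chrom"):
            if chrom in lengths and (sub["end"] > lengths[chrom]).any():
                raise ValueError(f"gene extends past end of {chrom}")
        if g["symbol"].duplicated().any():
            dups = g.loc[g["symbol"].duplicated(), "symbol"].tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        g["tss"] = tss_positions(g)
        self.genes = g

    def chrom_length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def genes_by_symbol(self) -> pd.DataFrame:
        return self.genes.set_index("symbol", drop=False)


@dataclass
class PeakSet:
    """Sorted, uniquely-identified genomic intervals.

    ``peaks`` holds columns ``chrom, start, end`` and is indexed by the
    canonical peak id. Construction sorts by (chrom, start) and validates.
    """

    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.peaks.copy()
        if (p["start"] >= p["end"]).any():
            raise ValueError("peak intervals must satisfy start < end")
        p = p.sort_values(["chrom", "start"], kind="stable")
        ids = [peak_id(c, s, e) for c, s, e in zip(p["chrom"], p["start"], p["end"])]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate peak ids")
        p.index = pd.Index(ids, name="peak_id")
        self.peaks = p

    @classmethod
    def from_arrays(cls, chroms, starts, ends) -> "PeakSet":
        return cls(pd.DataFrame({"chrom": chroms, "start": starts, "end": ends}))

    @property
    def ids(self) -> list[str]:
        return list(self.peaks.index)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class PairedCounts:
    """Paired gene x cell and peak x cell count matrices over one barcode axis.

    ``fragments`` is a DataFrame with columns
    ``chrom, start, end, barcode, count`` (0-based half-open).
    """

    rna: sp.csr_matrix
    rna_features: list[str]
    atac: sp.csr_matrix
    atac_features: list[str]
    barcodes: list[str]
    fragments: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.rna = sp.csr_matrix(self.rna)
        self.atac = sp.csr_matrix(self.atac)
        if self.rna.shape != (len(self.rna_features), len(self.barcodes)):
            raise ValueError("rna matrix shape does not match features x barcodes")
        if self.atac.shape != (len(self.atac_features), len(self.barcodes)):
            raise ValueError("atac matrix shape does not match features x barcodes")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")
        if self.rna.nnz and self.rna.data.min() < 0:
            raise ValueError("negative RNA counts")
        if self.atac.nnz and self.atac.data.min() < 0:
            raise ValueError("negative ATAC counts")
        if self.fragments is not None:
            unknown = set(self.fragments["barcode"]) - set(self.barcodes)
            if unknown:
                raise ValueError(f"fragment barcodes not in barcode list: {sorted(unknown)[:3]}")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def rna_row(self, symbol: str) -> np.ndarray:
        i = self.rna_features.index(symbol)
        return np.asarray(self.rna[i].todense()).ravel()


@dataclass
class CellTable:
    """Per-cell metadata: QC metrics, labels, cluster, simulation truth.

    Thin wrapper around a barcode-indexed DataFrame so downstream stages can
    attach columns (``disease``, ``fatemap``, ``cluster``, QC metrics,
    ``planted_fail`` ...) without a schema fight.
    """

    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            raise ValueError("one row per barcode required")

    @property
    def barcodes(self) -> list[str]:
        return list(self.df.index)

    def __len__(self) -> int:
        return len(self.df)
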