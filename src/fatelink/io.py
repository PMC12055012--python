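"""Readers and writers for the standard single-cell multiome file formats.

MatrixMarket triplets (with features/barcodes sidecars), 5-column BED-like
fragments files, GTF or minimal gene tables, and 3-column peak BED. Gzip is
handled transparently for fragments and MTX. All coordinates are normalized
to 0-based half-open on read.
"""

from __future__ import annotations

import gzip
import io as _io
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import GENE_TABLE_COLUMNS, GenomeModel, PeakSet

__all__ = [
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_fragments",
    "write_fragments",
    "read_gene_table",
    "write_gene_table",
    "read_peaks_bed",
    "write_peaks_bed",
]


def _open_text(path, mode="rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_lines(path) -> list[str]:
    with _open_text(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def read_mtx_triplet(matrix_path, features_path, barcodes_path):
    """Read a MatrixMarket coordinate matrix with feature/barcode sidecars.

    Returns ``(csr_matrix, features, barcodes)`` with the matrix shaped
    features x barcodes. Values must be nonnegative integers.
    """
    with _open_text(matrix_path, "rb") as fh:
        mat = scipy.io.mmread(_io.BytesIO(fh.read()))
    mat = sp.csr_matrix(mat)
    features = _read_lines(features_path)
    barcodes = _read_lines(barcodes_path)
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix is {mat.shape} but sidecars declare "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("negative values in count matrix")
    if not np.issubdtype(mat.dtype, np.integer):
        data = mat.data
        if not np.allclose(data, np.round(data)):
            raise ValueError("non-integer values in count matrix")
        mat = mat.astype(np.int64)
    return mat, features, barcodes


def write_mtx_triplet(matrix, features, barcodes, matrix_path, features_path, barcodes_path):
    """Write a sparse integer matrix as MTX plus one-id-per-line sidecars."""
    matrix = sp.coo_matrix(matrix)
    if matrix.shape != (len(features), len(barcodes)):
        raise ValueError("matrix shape does not match features x barcodes")
    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, matrix, field="integer")
    with _open_text(matrix_path, "wb") as fh:
        fh.write(buf.getvalue())
    for path, lines in ((features_path, features), (barcodes_path, barcodes)):
        with _open_text(path, "wt") as fh:
            fh.write("\n".join(str(x) for x in lines) + "\n")


FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


def read_fragments(path) -> pd.DataFrame:
    """Read a 5-column fragments file (plain or gzip).

    Columns: chrom, start, end, barcode, count; 0-based half-open.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=FRAGMENT_COLUMNS,
            comment="#",
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "barcode": str, "count": np.int64},
        )
    except (pd.errors.EmptyDataError, ValueError) as exc:
        if isinstance(exc, pd.errors.EmptyDataError):
            return pd.DataFrame(columns=FRAGMENT_COLUMNS)
        raise ValueError(f"malformed fragments file {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"fragments file {path} has rows with fewer than 5 columns")
    if (df["end"] <= df["start"]).any():
        raise ValueError("fragment with end <= start")
    return df


def write_fragments(fragments: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        fragments[FRAGMENT_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def per_barcode_totals(fragments: pd.DataFrame) -> pd.Series:
    """Count-weighted fragment tally per barcode."""
    return fragments.groupby("barcode")["count"].sum()


def _read_gtf_genes(path) -> pd.DataFrame:
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = parts[:9]
            attr = {}
            for chunk in attrs.strip().strip(";").split(";"):
                chunk = chunk.strip()
                if not chunk:
                    continue
                key, _, val = chunk.partition(" ")
                attr[key] = val.strip().strip('"')
            gene_id = attr.get("gene_id", f"{chrom}:{start}-{end}")
            symbol = attr.get("gene_name", gene_id)
            # GTF is 1-based inclusive; convert to 0-based half-open.
            rows.append((gene_id, symbol, chrom, int(start) - 1, int(end), strand))
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def read_gene_table(path) -> pd.DataFrame:
    """Read gene annotation from GTF or a minimal 6-column tab table.

    The minimal table (gene_id, symbol, chrom, start, end, strand) is already
    0-based half-open; GTF (1-based inclusive) is converted. Returns a
    DataFrame usable as ``GenomeModel.genes``.
    """
    path = os.fspath(path)
    if path.endswith((".gtf", ".gtf.gz", ".gff", ".gff.gz")):
        genes = _read_gtf_genes(path)
    else:
        with _open_text(path) as fh:
            first = fh.readline()
        n_cols = len(first.rstrip("\n").split("\t"))
        if n_cols >= 9:
            genes = _read_gtf_genes(path)
        else:
            genes = pd.read_csv(
                path, sep="\t", header=None, names=GENE_TABLE_COLUMNS, comment="#"
            )
    if not set(genes["strand"]).issubset({"+", "-"}):
        bad = sorted(set(genes["strand"]) - {"+", "-"})
        raise ValueError(f"unknown strand symbol(s): {bad}")
    return genes.reset_index(drop=True)


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes[GENE_TABLE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path) -> PeakSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    return PeakSet(df)


def write_peaks_bed(peaks: PeakSet, path) -> None:
    peaks.peaks[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def build_genome(gene_table_path, chromosomes=None) -> GenomeModel:
    """Convenience: GenomeModel from a gene table, inferring chromosome spans."""
    genes = read_gene_table(gene_table_path)
    if chromosomes is None:
        spans = genes.groupby("chrom")["end"].max()
        chromosomes = [(c, int(e) + 1) for c, e in spans.items()]
    return GenomeModel(chromosomes=chromosomes, genes=genes)


def ensure_outdir(out_dir, overwrite: bool = False) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    return out
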