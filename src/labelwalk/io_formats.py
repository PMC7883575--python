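"""Readers and writers for the external formats the tool touches.

Matrix input is the cellranger-atac-style triplet: MatrixMarket counts plus a
barcodes file and either a BED of peak/bin coordinates or a plain gene list.
Everything downstream consumes only the domain types in :mod:`labelwalk.types`.
"""
from __future__ import annotations

import io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .genome import GenomicIntervalSet
from .types import CellByFeatureMatrix, GeneAnnotation, MarkerSet

__all__ = [
    "read_cell_matrix",
    "write_cell_matrix",
    "read_markers",
    "read_gene_annotation",
    "read_bed",
    "read_gene_list",
    "write_label_scores",
    "write_dendrogram",
]


def read_bed(path) -> GenomicIntervalSet:
    """Read BED3/BED6 (tab-separated, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    name = df[3].to_numpy(dtype=object) if df.shape[1] >= 4 else None
    strand = df[5].to_numpy(dtype=object) if df.shape[1] >= 6 else None
    return GenomicIntervalSet(
        df[0].to_numpy(dtype=object),
        df[1].astype(np.int64).to_numpy(),
        df[2].astype(np.int64).to_numpy(),
        name,
        strand,
    )


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_cell_matrix(
    mtx_path,
    barcodes_path,
    features_path,
    feature_kind: str,
    transpose: bool | None = None,
) -> CellByFeatureMatrix:
    """Read an MTX + barcodes + features triplet into a cell-by-feature matrix.

    The file may store cells on either axis; the orientation is resolved by
    matching the declared MTX dimensions against the barcode and feature
    counts. A square matrix is ambiguous and requires an explicit
    ``transpose`` flag. Values are preserved exactly.
    """
    m = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    barcodes = read_gene_list(barcodes_path)
    if len(set(barcodes)) != len(barcodes):
        raise ValueError(f"{barcodes_path}: duplicate barcodes")
    if feature_kind == "gene":
        features: object = read_gene_list(features_path)
        n_feat = len(features)
    else:
        features = read_bed(features_path)
        n_feat = len(features)
    n_cells = len(barcodes)

    if transpose is None:
        fits = m.shape == (n_cells, n_feat)
        fits_t = m.shape == (n_feat, n_cells)
        if fits and fits_t and n_cells != n_feat:  # unreachable; kept for clarity
            raise AssertionError
        if fits and fits_t:
            raise ValueError(
                f"square matrix {m.shape} is ambiguous: pass transpose=True/False"
            )
        if fits:
            transpose = False
        elif fits_t:
            transpose = True
        else:
            raise ValueError(
                f"matrix shape {m.shape} matches neither (cells={n_cells}, "
                f"features={n_feat}) nor its transpose"
            )
    if transpose:
        m = sp.csr_matrix(m.T)
    if m.shape != (n_cells, n_feat):
        raise ValueError(
            f"matrix shape {m.shape} != (cells={n_cells}, features={n_feat})"
        )
    if m.nnz and m.data.min() < 0:
        raise ValueError(f"{mtx_path}: negative entries")
    return CellByFeatureMatrix(m, barcodes, features, feature_kind)


def write_cell_matrix(matrix: CellByFeatureMatrix, out_dir, prefix: str = "") -> dict:
    """Write the MTX + barcodes + features triplet; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out_dir / f"{prefix}matrix.mtx",
        "barcodes": out_dir / f"{prefix}barcodes.tsv",
    }
    scipy.io.mmwrite(str(paths["mtx"]), sp.coo_matrix(matrix.values))
    paths["barcodes"].write_text("".join(f"{c}\n" for c in matrix.cell_ids))
    if matrix.feature_kind == "gene":
        paths["features"] = out_dir / f"{prefix}genes.txt"
        paths["features"].write_text("".join(f"{g}\n" for g in matrix.features))
    else:
        paths["features"] = out_dir / f"{prefix}features.bed"
        feats = matrix.features
        with open(paths["features"], "w") as fh:
            for i in range(len(feats)):
                name = feats.name[i] if feats.name is not None else f"feat{i}"
                fh.write(f"{feats.chrom[i]}\t{feats.start[i]}\t{feats.end[i]}\t{name}\n")
    return paths


def read_markers(tsv_path) -> MarkerSet:
    """Read a marker table TSV with header ``label  gene  [logFC]``."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"label": str, "gene": str})
    cols = {c.lower(): c for c in df.columns}
    if "label" not in cols or "gene" not in cols:
        raise ValueError(f"{tsv_path}: marker table needs 'label' and 'gene' columns")
    out = pd.DataFrame(
        {
            "label": df[cols["label"]].astype(str),
            "gene": df[cols["gene"]].astype(str),
            "logfc": pd.to_numeric(df[cols["logfc"]], errors="raise")
            if "logfc" in cols
            else np.nan,
        }
    )
    return MarkerSet(out)


_ANNOT_COLS = ["gene", "chrom", "start", "end", "strand"]


def read_gene_annotation(path) -> GeneAnnotation:
    """Read gene coordinates from BED6 (name = gene) or a 5-column TSV.

    The TSV dialect is detected by its header line
    ``gene  chrom  start  end  strand``; anything else is parsed as BED6.
    Strand is mandatory either way.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.rstrip("\n").split("\t")[: len(_ANNOT_COLS)] == _ANNOT_COLS:
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
        table = df[_ANNOT_COLS].copy()
    else:
        bed = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if bed.shape[1] < 6:
            raise ValueError(f"{path}: gene BED must have 6 columns (missing strand)")
        table = pd.DataFrame(
            {
                "gene": bed[3],
                "chrom": bed[0],
                "start": bed[1].astype(np.int64),
                "end": bed[2].astype(np.int64),
                "strand": bed[5],
            }
        )
    table["start"] = table["start"].astype(np.int64)
    table["end"] = table["end"].astype(np.int64)
    return GeneAnnotation(table)


def write_label_scores(scores, path) -> None:
    """Write per-cell label scores: cell_id, one column per label, top_label,
    ambiguous."""
    if scores.n_labels == 0:
        raise ValueError("empty label set")
    df = pd.DataFrame(scores.values, columns=scores.labels)
    df.insert(0, "cell_id", scores.cell_ids)
    df["top_label"] = [scores.labels[i] for i in scores.top_index]
    df["ambiguous"] = scores.ambiguous
    df.to_csv(path, sep="\t", index=False)


def write_dendrogram(newick: str, path) -> None:
    """Write a Newick string (as produced by applications.cluster_labels)."""
    text = newick if newick.endswith("\n") else newick + "\n"
    Path(path).write_text(text)
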