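"""Construction of the combined cell + label network.

Cells are connected by Jaccard similarity of their binarized accessibility
profiles; label nodes attach to cells either through the fraction of a cell's
accessible peaks falling in marker-gene bodies/promoters, or through
normalized gene accessibility scores. A single scalar ``s`` sets the weight
of label-to-cell edges relative to cell-to-cell edges.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .genome import GenomicIntervalSet, overlap_pairs
from .types import CellByFeatureMatrix, GeneAnnotation, MarkerSet

__all__ = [
    "CombinedGraph",
    "jaccard_cell_similarity",
    "promoter_windows",
    "label_edges_from_peaks",
    "label_edges_from_genescores",
    "assemble",
]


@dataclass
class CombinedGraph:
    """Symmetric adjacency over ``n_cells + n_labels`` nodes, cells first.

    Block layout::

        A[cells, cells]  = cell-to-cell weights
        A[cells, labels] = s * label_edges.T
        A[labels, labels] = 0
    """

    adjacency: sp.csr_matrix
    n_cells: int
    labels: list
    s: float
    cell_ids: list | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def jaccard_cell_similarity(matrix: CellByFeatureMatrix) -> np.ndarray:
    """Pairwise Jaccard similarity of binarized (entry > 0) feature profiles.

    Diagonal forced to 0; pairs involving an empty-support cell score 0.
    """
    if matrix.feature_kind not in ("peak", "bin"):
        raise ValueError("Jaccard similarity expects a peak or bin matrix")
    b = matrix.binarized()
    support = np.asarray(b.sum(axis=1)).ravel()
    inter = np.asarray((b @ b.T).todense(), dtype=np.float64)
    union = support[:, None] + support[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    np.fill_diagonal(w, 0.0)
    return w


def promoter_windows(
    annotation: GeneAnnotation, upstream_bp: int = 2000
) -> GenomicIntervalSet:
    """Per gene, the union of the gene body and the strand-aware promoter
    window of ``upstream_bp`` bp ending at the TSS, clipped at coordinate 0."""
    if upstream_bp < 0:
        raise ValueError("upstream_bp must be >= 0")
    t = annotation.table
    start = t["start"].to_numpy(dtype=np.int64)
    end = t["end"].to_numpy(dtype=np.int64)
    plus = (t["strand"] == "+").to_numpy()
    new_start = np.where(plus, np.maximum(start - upstream_bp, 0), start)
    new_end = np.where(plus, end, end + upstream_bp)
    return GenomicIntervalSet(
        t["chrom"].to_numpy(dtype=object),
        new_start,
        new_end,
        t["gene"].to_numpy(dtype=object),
        t["strand"].to_numpy(dtype=object),
    )


def label_edges_from_peaks(
    matrix: CellByFeatureMatrix,
    markers: MarkerSet,
    annotation: GeneAnnotation,
    upstream_bp: int = 2000,
) -> np.ndarray:
    """Label-to-cell weights from a cell-by-peak matrix.

    weight(label, cell) = sum over the label's markers of
    logFC * (# of the cell's accessible peaks overlapping the marker's
    body+promoter window) / (# accessible peaks of the cell).
    Cells with no accessible peaks get weight 0 everywhere.
    """
    if matrix.feature_kind not in ("peak", "bin"):
        raise ValueError("label_edges_from_peaks expects a peak/bin matrix")
    windows = promoter_windows(annotation, upstream_bp)
    gene_index = {g: i for i, g in enumerate(annotation.genes)}

    b = matrix.binarized()
    per_cell_total = np.asarray(b.sum(axis=1)).ravel()

    # peaks overlapping each gene window, as an indicator matrix
    gi, pi = overlap_pairs(windows, matrix.features)
    gene_peak = sp.csr_matrix(
        (np.ones(len(gi)), (gi, pi)), shape=(len(windows), matrix.n_features)
    )
    # accessible-peak count per (cell, gene window)
    counts = np.asarray((b @ gene_peak.T).todense(), dtype=np.float64)

    weights = np.zeros((markers.n_labels, matrix.n_cells))
    n_missing = 0
    for li, label in enumerate(markers.labels):
        used = 0
        for gene, w in markers.entries(label):
            gi_ = gene_index.get(gene)
            if gi_ is None:
                n_missing += 1
                continue
            weights[li] += w * counts[:, gi_]
            used += 1
        if used == 0:
            raise ValueError(
                f"all marker genes of label {label!r} missing from annotation"
            )
    if n_missing:
        warnings.warn(
            f"skipped {n_missing} marker gene(s) missing from annotation",
            stacklevel=2,
        )
    nz = per_cell_total > 0
    weights[:, nz] /= per_cell_total[nz]
    weights[:, ~nz] = 0.0
    return weights


def label_edges_from_genescores(
    matrix: CellByFeatureMatrix, markers: MarkerSet
) -> np.ndarray:
    """Label-to-cell weights from a cell-by-gene score matrix.

    Each cell's gene scores are normalized to sum to 1, then
    weight(label, cell) = sum over markers of logFC * normalized score.
    """
    if matrix.feature_kind != "gene":
        raise ValueError("label_edges_from_genescores expects a gene matrix")
    gene_index = {g: i for i, g in enumerate(matrix.features)}
    totals = np.asarray(matrix.values.sum(axis=1)).ravel()
    dense = np.asarray(matrix.values.todense(), dtype=np.float64)
    nz = totals > 0
    dense[nz] /= totals[nz, None]
    dense[~nz] = 0.0

    weights = np.zeros((markers.n_labels, matrix.n_cells))
    n_missing = 0
    for li, label in enumerate(markers.labels):
        for gene, w in markers.entries(label):
            gi = gene_index.get(gene)
            if gi is None:
                n_missing += 1
                continue
            weights[li] += w * dense[:, gi]
    if n_missing:
        warnings.warn(
            f"skipped {n_missing} marker gene(s) missing from matrix", stacklevel=2
        )
    return weights


def assemble(
    cell_edges: np.ndarray,
    label_edges: np.ndarray,
    s: float,
    labels: list | None = None,
    cell_ids: list | None = None,
) -> CombinedGraph:
    """Assemble the block adjacency; label-to-cell edges are scaled by ``s``."""
    if s <= 0:
        raise ValueError("label edge weight s must be positive")
    cell_edges = np.asarray(cell_edges, dtype=np.float64)
    label_edges = np.asarray(label_edges, dtype=np.float64)
    n = cell_edges.shape[0]
    m = label_edges.shape[0]
    if cell_edges.shape != (n, n):
        raise ValueError("cell_edges must be square")
    if not np.allclose(cell_edges, cell_edges.T):
        raise ValueError("cell_edges must be symmetric")
    if label_edges.shape[1] != n:
        raise ValueError(
            f"label_edges has {label_edges.shape[1]} cells, cell_edges has {n}"
        )
    if np.any(cell_edges < 0) or np.any(label_edges < 0):
        raise ValueError("negative edge weights")
    if labels is None:
        labels = [f"label{i}" for i in range(m)]
    dead = np.flatnonzero(~(label_edges > 0).any(axis=1))
    if dead.size:
        raise ValueError(
            "label(s) with no positive cell edge: "
            + ", ".join(str(labels[i]) for i in dead)
        )
    a = sp.bmat(
        [
            [sp.csr_matrix(cell_edges), sp.csr_matrix(s * label_edges.T)],
            [sp.csr_matrix(s * label_edges), None],
        ],
        format="csr",
    )
    return CombinedGraph(a, n, list(labels), float(s), cell_ids)
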