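"""Domain containers: cell matrices, marker tables, gene annotations."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import GenomicIntervalSet

__all__ = ["CellByFeatureMatrix", "MarkerSet", "GeneAnnotation", "FEATURE_KINDS"]

FEATURE_KINDS = ("peak", "bin", "gene")


@dataclass
class CellByFeatureMatrix:
    """Sparse non-negative counts or scores, rows = cells, columns = features.

    ``features`` is a :class:`GenomicIntervalSet` for peak/bin matrices and a
    list of gene symbols for gene-score matrices.
    """

    values: sp.csr_matrix
    cell_ids: list
    features: object
    feature_kind: str

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}")
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = list(self.cell_ids)
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative entries in cell-by-feature matrix")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError(
                f"matrix has {self.values.shape[0]} rows but "
                f"{len(self.cell_ids)} cell ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if self.feature_kind == "gene":
            self.features = list(self.features)
            n_feat = len(self.features)
        else:
            if not isinstance(self.features, GenomicIntervalSet):
                raise ValueError("peak/bin features must be a GenomicIntervalSet")
            n_feat = len(self.features)
        if self.values.shape[1] != n_feat:
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but {n_feat} features"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def binarized(self) -> sp.csr_matrix:
        """0/1 accessibility indicator (entry > 0)."""
        b = self.values.copy()
        b.data = (b.data > 0).astype(np.int64)
        b.eliminate_zeros()
        return b


@dataclass
class MarkerSet:
    """Marker genes per label with optional log-fold changes.

    ``table`` has columns label, gene, logfc; a missing log-fold change is
    stored as NaN and weighted 1 downstream. ``labels`` preserves
    first-appearance order.
    """

    table: pd.DataFrame
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"label", "gene", "logfc"}
        if not required <= set(self.table.columns):
            raise ValueError(f"marker table must have columns {sorted(required)}")
        if not self.labels:
            self.labels = list(dict.fromkeys(self.table["label"]))
        if not set(self.table["label"]) <= set(self.labels):
            raise ValueError("marker entry with label missing from label list")
        if self.table.duplicated(["label", "gene"]).any():
            raise ValueError("duplicate (label, gene) marker entries")
        present = self.table["logfc"].dropna()
        if (present <= 0).any():
            raise ValueError("non-positive logFC in marker table")

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def entries(self, label) -> list[tuple[str, float]]:
        """(gene, weight) pairs for one label; absent logFC maps to 1.0."""
        sub = self.table[self.table["label"] == label]
        return [
            (g, 1.0 if pd.isna(w) else float(w))
            for g, w in zip(sub["gene"], sub["logfc"])
        ]


@dataclass
class GeneAnnotation:
    """Gene coordinates with mandatory strand; TSS is strand-aware."""

    table: pd.DataFrame  # columns: gene, chrom, start, end, strand

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "start", "end", "strand"}
        if not required <= set(self.table.columns):
            raise ValueError(f"annotation must have columns {sorted(required)}")
        if not set(self.table["strand"]) <= {"+", "-"}:
            raise ValueError("gene strand must be '+' or '-'")
        if self.table.duplicated("gene").any():
            dupes = self.table[self.table.duplicated("gene", keep=False)]
            keep = (
                dupes.assign(_len=dupes["end"] - dupes["start"])
                .sort_values("_len", ascending=False)
                .drop_duplicates("gene")
                .index
            )
            drop = set(dupes.index) - set(keep)
            warnings.warn(
                f"collapsed {len(drop)} duplicate gene record(s), keeping the longest",
                stacklevel=2,
            )
            self.table = self.table.drop(index=list(drop)).reset_index(drop=True)
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list:
        return list(self.table["gene"])

    @property
    def tss(self) -> np.ndarray:
        start = self.table["start"].to_numpy(dtype=np.int64)
        end = self.table["end"].to_numpy(dtype=np.int64)
        plus = (self.table["strand"] == "+").to_numpy()
        return np.where(plus, start, end)

    def intervals(self) -> GenomicIntervalSet:
        return GenomicIntervalSet(
            self.table["chrom"].to_numpy(dtype=object),
            self.table["start"].to_numpy(dtype=np.int64),
            self.table["end"].to_numpy(dtype=np.int64),
            self.table["gene"].to_numpy(dtype=object),
            self.table["strand"].to_numpy(dtype=object),
        )
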