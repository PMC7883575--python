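"""Downstream uses of the influence matrix.

Four families: fuzzy per-cell label scores with an ambiguity call, label
clustering from label-to-label influence, mapping bulk genomic regions to
labels through cell-to-label influence, and the region statistics (score
differences, distal-accessibility correlation, permutation bimodality test,
nearest-gene resampling enrichment).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from statsmodels.stats.multitest import multipletests

from .diffusion import InfluenceMatrix
from .genome import GenomicIntervalSet, nearest_tss_index, overlap_pairs
from .graph_build import promoter_windows
from .types import CellByFeatureMatrix, GeneAnnotation

__all__ = [
    "LabelScoreMatrix",
    "LabelDendrogram",
    "RegionLabelScores",
    "label_scores",
    "flag_ambiguous",
    "cluster_labels",
    "map_regions_to_labels",
    "score_difference",
    "correlate_regions_with_score",
    "bimodality_permutation_test",
    "nearest_gene_enrichment",
]


@dataclass
class LabelScoreMatrix:
    """Normalized per-cell label scores.

    Columns are z-scored across cells and each row rescaled so its maximum is
    one (when positive). ``gap`` is top minus second score.
    """

    values: np.ndarray
    labels: list
    cell_ids: list
    top_index: np.ndarray
    second_index: np.ndarray
    gap: np.ndarray
    ambiguous: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.ambiguous is None:
            self.ambiguous = np.zeros(len(self.cell_ids), dtype=bool)

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def top_labels(self) -> list:
        return [self.labels[i] for i in self.top_index]

    def score_of(self, label) -> np.ndarray:
        return self.values[:, self.labels.index(label)]


def label_scores(f: InfluenceMatrix) -> LabelScoreMatrix:
    """z-score each label column of label-to-cell influence, then rescale each
    cell's row to a maximum of one (when the row maximum is positive)."""
    if f.n_cells < 2:
        raise ValueError("label scores need >= 2 cells (z-score undefined)")
    block = f.label_to_cell.copy()
    mu = block.mean(axis=0)
    sd = block.std(axis=0, ddof=1)
    z = np.zeros_like(block)
    nzc = sd > 0
    z[:, nzc] = (block[:, nzc] - mu[nzc]) / sd[nzc]
    row_max = z.max(axis=1)
    pos = row_max > 0
    z[pos] = z[pos] / row_max[pos, None]

    top = np.argmax(z, axis=1)
    if z.shape[1] >= 2:
        order = np.argsort(z, axis=1)
        second = order[:, -2]
        gap = z[np.arange(len(z)), top] - z[np.arange(len(z)), second]
    else:
        second = np.full(len(z), -1)
        gap = np.full(len(z), np.nan)
    cell_ids = f.cell_ids if f.cell_ids is not None else [str(i) for i in range(f.n_cells)]
    return LabelScoreMatrix(z, list(f.labels), list(cell_ids), top, second, gap)


def flag_ambiguous(scores: LabelScoreMatrix, quantile: float = 0.10) -> np.ndarray:
    """Flag cells whose top-two score gap falls at or below the empirical
    ``quantile`` of gaps across all cells; the result is also stored on
    ``scores.ambiguous``."""
    if scores.n_labels < 2:
        raise ValueError("ambiguity needs >= 2 labels")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    threshold = np.quantile(scores.gap, quantile)
    flags = scores.gap <= threshold
    scores.ambiguous = flags
    return flags


@dataclass
class LabelDendrogram:
    """Agglomerative clustering of labels; serializable to Newick."""

    linkage: np.ndarray
    labels: list

    def newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def fmt(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        body = fmt(tree, tree.dist)
        # strip the root's zero-length branch
        return body.rsplit(":", 1)[0] + ";"


def cluster_labels(f: InfluenceMatrix, method: str = "complete") -> LabelDendrogram:
    """Hierarchical clustering of labels on Euclidean distances between rows
    of the label-to-label influence block."""
    if f.n_labels < 2:
        raise ValueError("label clustering needs >= 2 labels")
    z = sch.linkage(f.label_to_label, method=method, metric="euclidean")
    return LabelDendrogram(z, list(f.labels))


@dataclass
class RegionLabelScores:
    values: np.ndarray  # (n_regions, n_labels)
    labels: list
    regions: GenomicIntervalSet
    mode: str

    def to_frame(self) -> pd.DataFrame:
        coords = [
            f"{c}:{s}-{e}"
            for c, s, e in zip(self.regions.chrom, self.regions.start, self.regions.end)
        ]
        df = pd.DataFrame(self.values, columns=self.labels)
        df.insert(0, "region", coords)
        return df


def map_regions_to_labels(
    f: InfluenceMatrix,
    matrix: CellByFeatureMatrix,
    regions: GenomicIntervalSet,
    mode: str = "binary_peak",
) -> RegionLabelScores:
    """Map bulk regions to labels via cell-to-label influence.

    binary_peak: sum the influence of every cell with at least one accessible
    peak overlapping the region. read_fraction: weight each cell's influence
    by the fraction of its reads falling in overlapping peaks.
    """
    if mode not in ("binary_peak", "read_fraction"):
        raise ValueError(f"unknown mode {mode!r}")
    if matrix.feature_kind not in ("peak", "bin"):
        raise ValueError("region mapping needs a peak/bin matrix")
    ri, pi = overlap_pairs(regions, matrix.features)
    influence = f.cell_to_label  # (labels, cells)
    out = np.zeros((len(regions), f.n_labels))
    if mode == "binary_peak":
        b = matrix.binarized().tocsc()
        for r in range(len(regions)):
            peaks = pi[ri == r]
            if peaks.size == 0:
                continue
            cells = np.unique(b[:, peaks].nonzero()[0])
            out[r] = influence[:, cells].sum(axis=1)
    else:
        v = matrix.values.tocsc()
        totals = np.asarray(matrix.values.sum(axis=1)).ravel()
        nz = totals > 0
        for r in range(len(regions)):
            peaks = pi[ri == r]
            if peaks.size == 0:
                continue
            in_region = np.asarray(v[:, peaks].sum(axis=1)).ravel().astype(float)
            frac = np.zeros_like(in_region)
            frac[nz] = in_region[nz] / totals[nz]
            out[r] = influence @ frac
    return RegionLabelScores(out, list(f.labels), regions, mode)


def score_difference(
    scores: LabelScoreMatrix,
    label_late,
    label_early,
    restrict_to_pair: bool = False,
) -> pd.Series:
    """Per-cell progression score: score(label_late) - score(label_early).

    Higher values mean closer to ``label_late``. With ``restrict_to_pair``,
    only cells whose top label is one of the two are returned.
    """
    for lab in (label_late, label_early):
        if lab not in scores.labels:
            raise ValueError(f"unknown label {lab!r}")
    diff = scores.score_of(label_late) - scores.score_of(label_early)
    out = pd.Series(diff, index=pd.Index(scores.cell_ids, name="cell_id"))
    if restrict_to_pair:
        keep = np.isin(scores.top_labels, [label_late, label_early])
        out = out[keep]
    return out


def _distal_fraction_matrix(
    binarized,
    distal_mask: np.ndarray,
    features: GenomicIntervalSet,
    regions: GenomicIntervalSet,
) -> np.ndarray:
    """x[r, c] = cell c's accessible distal peaks in region r over its
    genome-wide accessible distal peaks (0 when the cell has none)."""
    b_d = binarized[:, distal_mask]
    genome_wide = np.asarray(b_d.sum(axis=1)).ravel().astype(float)
    distal_feats = features.subset(distal_mask)
    ri, pi = overlap_pairs(regions, distal_feats)
    import scipy.sparse as sp

    r_ind = sp.csr_matrix(
        (np.ones(len(ri)), (ri, pi)), shape=(len(regions), len(distal_feats))
    )
    counts = np.asarray((r_ind @ b_d.T).todense(), dtype=float)
    nz = genome_wide > 0
    counts[:, nz] /= genome_wide[nz]
    counts[:, ~nz] = 0.0
    return counts


def correlate_regions_with_score(
    matrix: CellByFeatureMatrix,
    regions: GenomicIntervalSet,
    per_cell_score: np.ndarray,
    annotation: GeneAnnotation,
    cells: np.ndarray | None = None,
    upstream_bp: int = 2000,
) -> np.ndarray:
    """Pearson correlation, per region, between each cell's distal
    accessibility in the region and its score.

    Distal peaks overlap neither gene bodies nor promoter windows. Regions
    whose accessibility does not vary across cells yield NaN.
    """
    score = np.asarray(per_cell_score, dtype=float)
    b = matrix.binarized()
    if cells is not None:
        cells = np.asarray(cells)
        b = b[cells]
    if b.shape[0] < 3:
        raise ValueError("correlation needs >= 3 cells")
    if score.shape[0] != b.shape[0]:
        raise ValueError("per_cell_score length must match analyzed cells")
    windows = promoter_windows(annotation, upstream_bp)
    from .genome import overlap_indicator

    distal = ~overlap_indicator(windows, matrix.features)
    x = _distal_fraction_matrix(b, distal, matrix.features, regions)
    return _rowwise_pearson(x, score)


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    out = np.full(x.shape[0], np.nan)
    ok = (sx > 0) & (sy > 0)
    out[ok] = (xc[ok] @ yc) / (sx[ok] * sy)
    return out


def _relocate_regions(
    regions: GenomicIntervalSet,
    chrom_sizes: dict,
    rng: np.random.Generator,
    excluded: GenomicIntervalSet | None = None,
    max_tries: int = 200,
) -> GenomicIntervalSet:
    """Place each region uniformly at random on its own chromosome, keeping
    lengths, avoiding overlap with already-placed regions and any excluded
    intervals (rejection sampling)."""
    lengths = regions.lengths()
    new_start = np.empty(len(regions), dtype=np.int64)
    placed: dict = {}
    for i in range(len(regions)):
        c = regions.chrom[i]
        size = chrom_sizes[c]
        if lengths[i] > size:
            raise ValueError(f"region {i} longer than chromosome {c}")
        for _ in range(max_tries):
            s = int(rng.integers(0, size - lengths[i] + 1))
            e = s + lengths[i]
            clash = any(s < pe and ps < e for ps, pe in placed.get(c, ()))
            if not clash and excluded is not None:
                mask = excluded.chrom == c
                clash = bool(
                    np.any((s < excluded.end[mask]) & (excluded.start[mask] < e))
                )
            if not clash:
                break
        else:
            warnings.warn(
                f"could not place region {i} without overlap; accepting overlap",
                stacklevel=2,
            )
        placed.setdefault(c, []).append((s, e))
        new_start[i] = s
    return GenomicIntervalSet(regions.chrom, new_start, new_start + lengths)


def bimodality_permutation_test(
    matrix: CellByFeatureMatrix,
    regions: GenomicIntervalSet,
    per_cell_score: np.ndarray,
    annotation: GeneAnnotation,
    chrom_sizes: dict,
    n_perm: int = 1000,
    seed=None,
    cells: np.ndarray | None = None,
    excluded: GenomicIntervalSet | None = None,
) -> tuple[float, float]:
    """Permutation test of whether per-region correlations are more extreme
    than position-shuffled regions.

    Statistic: median absolute correlation over regions (NaNs dropped). Null:
    regions relocated uniformly within their chromosome, lengths preserved.
    Returns (observed statistic, add-one empirical p).
    """
    rng = np.random.default_rng(seed)
    obs_corr = correlate_regions_with_score(
        matrix, regions, per_cell_score, annotation, cells=cells
    )
    observed = float(np.nanmedian(np.abs(obs_corr)))
    n_ge = 0
    for _ in range(n_perm):
        null_regions = _relocate_regions(regions, chrom_sizes, rng, excluded)
        null_corr = correlate_regions_with_score(
            matrix, null_regions, per_cell_score, annotation, cells=cells
        )
        if np.nanmedian(np.abs(null_corr)) >= observed:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return observed, float(p)


def nearest_gene_enrichment(
    regions_by_subset: dict,
    gene_sets: dict,
    background_genes,
    annotation: GeneAnnotation,
    n_resample: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Resampling enrichment of region subsets near gene sets.

    Each region is assigned the gene with the nearest TSS (to the region
    midpoint, same chromosome, ties toward the smaller coordinate). For every
    (subset, gene set) pair: observed = fraction of regions whose nearest
    gene is in the set; the null redraws an equally sized gene set from the
    background ``n_resample`` times. Add-one empirical p-values,
    Benjamini-Hochberg FDR across all pairs.
    """
    rng = np.random.default_rng(seed)
    background = list(dict.fromkeys(background_genes))
    bg_index = {g: i for i, g in enumerate(background)}
    genes = annotation.genes
    tss = annotation.tss
    chrom = annotation.table["chrom"].to_numpy(dtype=object)

    for name, gene_set in gene_sets.items():
        if len(gene_set) > len(background):
            raise ValueError(f"gene set {name!r} larger than background")
        if not set(gene_set) & set(background):
            warnings.warn(
                f"gene set {name!r} disjoint from background", stacklevel=2
            )

    records = []
    for subset_name, regions in regions_by_subset.items():
        nearest = nearest_tss_index(regions, tss, chrom)
        if np.any(nearest < 0):
            warnings.warn(
                f"{int((nearest < 0).sum())} region(s) in {subset_name!r} on "
                "chromosomes with no gene; excluded",
                stacklevel=2,
            )
            nearest = nearest[nearest >= 0]
        if nearest.size == 0:
            raise ValueError(f"subset {subset_name!r} has no regions near genes")
        # nearest gene of each region as a background index (-1 if outside)
        near_bg = np.array(
            [bg_index.get(genes[i], -1) for i in nearest], dtype=np.int64
        )
        for set_name, gene_set in gene_sets.items():
            in_set = np.array([genes[i] in gene_set for i in nearest])
            observed = float(in_set.mean())
            k = len(gene_set)
            n_ge = 0
            member = np.zeros(len(background) + 1, dtype=bool)  # slot -1 unused
            for _ in range(n_resample):
                draw = rng.choice(len(background), size=k, replace=False)
                member[:-1] = False
                member[draw] = True
                frac = member[near_bg].mean() if near_bg.size else 0.0
                if frac >= observed:
                    n_ge += 1
                member[draw] = False
            p = (1 + n_ge) / (n_resample + 1)
            records.append(
                {
                    "subset": subset_name,
                    "gene_set": set_name,
                    "observed_fraction": observed,
                    "empirical_p": p,
                }
            )
    out = pd.DataFrame.from_records(records)
    out["fdr"] = multipletests(out["empirical_p"], method="fdr_bh")[1]
    return out
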