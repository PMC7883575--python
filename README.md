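# labelwalk

Network diffusion for annotating scATAC-seq cells with external cell-type
labels and for mapping bulk genomic regions onto those cell types.

Cells (from a sparse cell-by-peak or cell-by-bin matrix) are connected by the
Jaccard similarity of their binarized accessibility profiles. Label nodes —
one per cell type, anchored by marker genes — attach to cells either through
the fraction of a cell's accessible peaks in marker gene bodies/promoters or
through normalized gene accessibility scores. A random walk with restarts
(restart probability `alpha`, default 0.5) over the combined graph yields a
closed-form influence matrix `F = alpha * (I - (1 - alpha) * W)^-1` with
`W = D^-1 A`. Blocks of `F` drive everything downstream:

- **label-to-cell** — fuzzy per-cell label scores (z-scored per label,
  rescaled to a row maximum of 1) with a bottom-decile ambiguity call;
- **label-to-label** — hierarchical clustering of labels (Newick output);
- **cell-to-label** — mapping bulk regions (e.g. candidate enhancers) to
  labels, plus region statistics: progression-score correlation of distal
  accessibility, a region-relocation permutation test, and nearest-gene
  resampling enrichment with Benjamini–Hochberg FDR.

A single scalar `s` (the label edge weight) trades external label trust
against intrinsic cell similarity; `tune` grid-searches it by maximizing
*cell homogeneity* — the natural log of the ratio of pooled median
within-group to between-group cell-to-cell influence.

The `simulate` module generates synthetic two-type datasets (lognormal read
depths with median 5500, multinomial reads over bins, a configurable percent
of extra type-specific reads, partial/incorrect weight-1 labeling, add/drop
read noise, and an unlabeled mixture population) so the whole pipeline is
testable without external data.

## Command line

All subcommands share the global flags `--alpha`, `--edge-weight/-s`,
`--seed`, `--log-level`, `--out-dir` (placed before the subcommand):

```sh
# full pipeline: scores + ambiguity, label dendrogram, homogeneity
labelwalk --out-dir out run \
    --mtx matrix.mtx --barcodes barcodes.tsv --features peaks.bed \
    --feature-kind peak --markers markers.tsv --annotation genes.bed

# grid-search the label edge weight
labelwalk --out-dir out tune ... --grid 1e-2,1e-1,1,1e1,1e2,1e3,1e4

# per-cell scores only / label dendrogram only
labelwalk --out-dir out label ...
labelwalk --out-dir out cluster-labels ...

# map bulk regions (BED) to labels
labelwalk --out-dir out map-bulk ... --regions enhancers.bed --mode binary_peak

# synthetic data (config JSON -> MTX triplet + truth + label edges)
labelwalk --out-dir sim simulate --config config.json

# nearest-gene resampling enrichment with BH-FDR
labelwalk --seed 1 --out-dir out enrich \
    --regions subset1.bed --regions subset2.bed \
    --gene-set disease.txt --background expressed.txt --annotation genes.bed
```

Formats: MatrixMarket + barcodes + BED/gene-list triplet for matrices (either
orientation; square matrices need an explicit `--transpose/--no-transpose`),
tab-separated BED3/BED6 (0-based half-open) for all genomic intervals, a
`label<TAB>gene<TAB>logFC` marker table, and gene annotation as BED6 or a
`gene chrom start end strand` TSV (strand mandatory — it sets the TSS).

## Library quick start

```python
import labelwalk as lw

matrix = lw.read_cell_matrix("matrix.mtx", "barcodes.tsv", "peaks.bed", "peak")
markers = lw.read_markers("markers.tsv")
genes = lw.read_gene_annotation("genes.bed")

cell_edges = lw.jaccard_cell_similarity(matrix)
label_edges = lw.label_edges_from_peaks(matrix, markers, genes)
graph = lw.assemble(cell_edges, label_edges, s=1.0, labels=markers.labels,
                    cell_ids=matrix.cell_ids)
f = lw.influence_matrix(lw.walk_matrix(graph), alpha=0.5)

scores = lw.label_scores(f)          # fuzzy per-cell labels
lw.flag_ambiguous(scores)            # bottom-decile gap rule
tree = lw.cluster_labels(f)          # label dendrogram -> tree.newick()
```
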