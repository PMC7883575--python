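import numpy as np
import pandas as pd
import pytest

import dendropy

from labelwalk.applications import (
    LabelScoreMatrix,
    bimodality_permutation_test,
    cluster_labels,
    correlate_regions_with_score,
    flag_ambiguous,
    label_scores,
    map_regions_to_labels,
    nearest_gene_enrichment,
    score_difference,
)
from labelwalk.diffusion import InfluenceMatrix
from labelwalk.genome import GenomicIntervalSet
from labelwalk.types import GeneAnnotation

from conftest import make_peak_matrix


def influence_from_label_block(label_to_cell, labels=None, cell_ids=None):
    block = np.asarray(label_to_cell, dtype=float)
    n, m = block.shape
    labels = labels or [f"L{i}" for i in range(m)]
    f = np.zeros((n + m, n + m))
    f[:n, n:] = block
    f[n:, :n] = block.T  # cell-to-label mirror, fine for tests
    return InfluenceMatrix(f, 0.5, n, list(labels), cell_ids)


class TestLabelScores:
    def test_zscore_rescale_hand_example(self):
        f = influence_from_label_block([[0.4, 0.1], [0.2, 0.3]])
        scores = label_scores(f)
        assert np.allclose(scores.values, [[1, -1], [-1, 1]])

    def test_constant_column_maps_to_zeros(self):
        f = influence_from_label_block([[0.5, 0.1], [0.5, 0.3]])
        scores = label_scores(f)
        assert np.allclose(scores.values[:, 0], 0.0)

    def test_single_label_scores_one_when_spread(self):
        f = influence_from_label_block([[0.4], [0.2], [0.6]])
        scores = label_scores(f)
        pos = scores.values[:, 0] > 0
        assert np.all(scores.values[pos, 0] == 1.0)

    def test_single_cell_fatal(self):
        f = influence_from_label_block([[0.4, 0.2]])
        with pytest.raises(ValueError, match="2 cells"):
            label_scores(f)

    def test_row_max_is_one_for_positive_spread_rows(self):
        rng = np.random.default_rng(0)
        f = influence_from_label_block(rng.random((20, 4)))
        scores = label_scores(f)
        row_max = scores.values.max(axis=1)
        assert np.allclose(row_max[row_max > 0], 1.0)


class TestFlagAmbiguous:
    def make_scores(self, gaps):
        gaps = np.asarray(gaps, dtype=float)
        n = len(gaps)
        return LabelScoreMatrix(
            values=np.zeros((n, 2)),
            labels=["A", "B"],
            cell_ids=[f"c{i}" for i in range(n)],
            top_index=np.zeros(n, dtype=int),
            second_index=np.ones(n, dtype=int),
            gap=gaps,
        )

    def test_bottom_decile_flagged(self):
        gaps = [0.01, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        scores = self.make_scores(gaps)
        flags = flag_ambiguous(scores, quantile=0.10)
        assert flags.tolist() == [True] + [False] * 9

    def test_identical_gaps_all_flagged(self):
        flags = flag_ambiguous(self.make_scores([0.3] * 5))
        assert flags.all()

    def test_half_quantile_flags_about_half(self):
        flags = flag_ambiguous(self.make_scores(np.linspace(0, 1, 10)), quantile=0.5)
        assert 4 <= flags.sum() <= 6

    def test_flags_stored_on_scores(self):
        scores = self.make_scores([0.1, 0.9])
        flag_ambiguous(scores)
        assert scores.ambiguous.tolist() == [True, False]

    def test_single_label_fatal(self):
        scores = self.make_scores([0.1, 0.9])
        scores.labels = ["A"]
        with pytest.raises(ValueError, match="2 labels"):
            flag_ambiguous(scores)


def influence_from_ll_block(block, labels):
    block = np.asarray(block, dtype=float)
    m = len(labels)
    q = m + 2  # two dummy cells
    f = np.zeros((q, q))
    f[2:, 2:] = block
    return InfluenceMatrix(f, 0.5, 2, list(labels))


class TestClusterLabels:
    def test_two_labels_merge_at_euclidean_distance(self):
        block = [[1.0, 0.0], [0.0, 1.0]]
        tree = cluster_labels(influence_from_ll_block(block, ["A", "B"]))
        assert tree.linkage[0, 2] == pytest.approx(np.sqrt(2))

    def test_identical_rows_merge_first_at_zero(self):
        block = [[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]]
        tree = cluster_labels(influence_from_ll_block(block, ["A", "B", "C"]))
        assert tree.linkage[0, 2] == pytest.approx(0.0)
        assert set(tree.linkage[0, :2].astype(int).tolist()) == {0, 1}

    def test_newick_reparses_with_all_leaves(self):
        rng = np.random.default_rng(3)
        labels = ["A", "B", "C", "D", "E"]
        tree = cluster_labels(influence_from_ll_block(rng.random((5, 5)), labels))
        t = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == labels
        assert len(t.leaf_nodes()) == 5
        assert sum(1 for n in t if not n.is_leaf()) == 4

    def test_single_label_fatal(self):
        with pytest.raises(ValueError, match="2 labels"):
            cluster_labels(influence_from_ll_block([[1.0]], ["A"]))

    def test_label_order_invariance(self):
        rng = np.random.default_rng(4)
        block = rng.random((4, 4)) + np.eye(4)
        labels = ["A", "B", "C", "D"]
        t1 = cluster_labels(influence_from_ll_block(block, labels))
        perm = [2, 0, 3, 1]
        t2 = cluster_labels(
            influence_from_ll_block(block[np.ix_(perm, perm)], [labels[i] for i in perm])
        )
        assert sorted(t1.linkage[:, 2]) == pytest.approx(sorted(t2.linkage[:, 2]))


PEAKS = [("chr1", 0, 100), ("chr1", 200, 300), ("chr1", 400, 500)]


def full_influence(matrix, label_edges, labels, s=1.0):
    from labelwalk.diffusion import influence_matrix, walk_matrix
    from labelwalk.graph_build import assemble, jaccard_cell_similarity

    ce = jaccard_cell_similarity(matrix)
    g = assemble(ce, label_edges, s, labels=labels, cell_ids=matrix.cell_ids)
    return influence_matrix(walk_matrix(g))


class TestMapRegionsToLabels:
    def setup_method(self):
        self.matrix = make_peak_matrix(
            [[5, 0, 1], [0, 10, 2], [1, 1, 0]], PEAKS
        )
        self.edges = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        self.f = full_influence(self.matrix, self.edges, ["A", "B"])

    def test_binary_single_cell_region(self):
        regions = GenomicIntervalSet.from_records([("chr1", 210, 220)])
        # peak 1 accessible in cells 1 and 2
        out = map_regions_to_labels(self.f, self.matrix, regions, "binary_peak")
        expect = self.f.cell_to_label[:, [1, 2]].sum(axis=1)
        assert np.allclose(out.values[0], expect)

    def test_read_fraction_weighting(self):
        regions = GenomicIntervalSet.from_records([("chr1", 210, 220)])
        out = map_regions_to_labels(self.f, self.matrix, regions, "read_fraction")
        fracs = np.array([0.0, 10 / 12, 0.5])
        assert np.allclose(out.values[0], self.f.cell_to_label @ fracs)

    def test_region_without_peaks_is_zero(self):
        regions = GenomicIntervalSet.from_records([("chr1", 900, 950)])
        out = map_regions_to_labels(self.f, self.matrix, regions, "binary_peak")
        assert np.all(out.values == 0)

    def test_unknown_mode_fatal(self):
        regions = GenomicIntervalSet.from_records([("chr1", 0, 10)])
        with pytest.raises(ValueError, match="unknown mode"):
            map_regions_to_labels(self.f, self.matrix, regions, "nope")

    def test_concatenation_preserves_rows(self):
        r1 = GenomicIntervalSet.from_records([("chr1", 0, 50)])
        r2 = GenomicIntervalSet.from_records([("chr1", 210, 220)])
        both = GenomicIntervalSet.from_records([("chr1", 0, 50), ("chr1", 210, 220)])
        o1 = map_regions_to_labels(self.f, self.matrix, r1, "binary_peak")
        o2 = map_regions_to_labels(self.f, self.matrix, r2, "binary_peak")
        ob = map_regions_to_labels(self.f, self.matrix, both, "binary_peak")
        assert np.array_equal(ob.values, np.vstack([o1.values, o2.values]))

    def test_frame_region_coordinates(self):
        regions = GenomicIntervalSet.from_records([("chr1", 210, 220)])
        df = map_regions_to_labels(self.f, self.matrix, regions, "binary_peak").to_frame()
        assert df.loc[0, "region"] == "chr1:210-220"


class TestScoreDifference:
    def make_scores(self):
        return LabelScoreMatrix(
            values=np.array([[1.0, 0.2], [0.5, 0.5], [0.1, 1.0]]),
            labels=["early", "late"],
            cell_ids=["c0", "c1", "c2"],
            top_index=np.array([0, 0, 1]),
            second_index=np.array([1, 1, 0]),
            gap=np.array([0.8, 0.0, 0.9]),
        )

    def test_late_minus_early(self):
        out = score_difference(self.make_scores(), "late", "early")
        assert out["c0"] == pytest.approx(-0.8)
        assert out["c1"] == 0.0

    def test_restriction_filters_other_top_labels(self):
        scores = self.make_scores()
        scores.labels = ["early", "late"]
        scores.top_index = np.array([0, 1, 1])
        out = score_difference(scores, "late", "early", restrict_to_pair=True)
        assert len(out) == 3
        scores2 = self.make_scores()
        scores2.labels = ["early", "other"]
        with pytest.raises(ValueError, match="unknown label"):
            score_difference(scores2, "late", "early")


DISTAL_ANNOTATION = GeneAnnotation(
    pd.DataFrame(
        {
            "gene": ["FAR"],
            "chrom": ["chrZ"],
            "start": [0],
            "end": [100],
            "strand": ["+"],
        }
    )
)


def bin_matrix(counts, p, width=100):
    peaks = [("chr1", i * width, (i + 1) * width) for i in range(p)]
    return make_peak_matrix(counts, peaks)


class TestCorrelateRegions:
    def test_proportional_gives_plus_one(self):
        # cell c: c accessible bins inside the region, 6 total genome-wide,
        # so the distal fraction is exactly c/6 and tracks the score linearly
        p = 12
        counts = np.zeros((4, p), dtype=int)
        for c in range(4):
            counts[c, :c] = 1  # region bins 0..3
            counts[c, 5 : 5 + 6 - c] = 1
        m = bin_matrix(counts, p)
        regions = GenomicIntervalSet.from_records([("chr1", 0, 400)])
        score = np.array([0.0, 1.0, 2.0, 3.0])
        r = correlate_regions_with_score(m, regions, score, DISTAL_ANNOTATION)
        assert r[0] == pytest.approx(1.0)

    def test_constant_accessibility_is_nan(self):
        counts = np.ones((4, 6), dtype=int)
        m = bin_matrix(counts, 6)
        regions = GenomicIntervalSet.from_records([("chr1", 0, 200)])
        r = correlate_regions_with_score(m, regions, np.arange(4.0), DISTAL_ANNOTATION)
        assert np.isnan(r[0])

    def test_sign_flip_negates(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 2, size=(8, 12))
        m = bin_matrix(counts, 12)
        regions = GenomicIntervalSet.from_records([("chr1", 0, 300), ("chr1", 500, 900)])
        score = rng.random(8)
        r1 = correlate_regions_with_score(m, regions, score, DISTAL_ANNOTATION)
        r2 = correlate_regions_with_score(m, regions, -score, DISTAL_ANNOTATION)
        assert np.allclose(r1, -r2, equal_nan=True)

    def test_promoter_and_body_peaks_excluded(self):
        ann = GeneAnnotation(
            pd.DataFrame(
                {
                    "gene": ["G"],
                    "chrom": ["chr1"],
                    "start": [0],
                    "end": [250],
                    "strand": ["+"],
                }
            )
        )
        counts = np.array([[1, 1, 1, 0], [1, 1, 0, 1], [1, 0, 1, 1]])
        m = bin_matrix(counts, 4)
        regions = GenomicIntervalSet.from_records([("chr1", 0, 400)])
        # bins 0-2 overlap the gene body [0,250): only bin 3 is distal
        r_with = correlate_regions_with_score(m, regions, np.array([1.0, 2.0, 3.0]), ann)
        x = counts[:, 3]  # distal accessibility drives the correlation alone
        expect = np.corrcoef(x, [1.0, 2.0, 3.0])[0, 1]
        assert r_with[0] == pytest.approx(expect)

    def test_too_few_cells_fatal(self):
        m = bin_matrix(np.ones((2, 4), dtype=int), 4)
        regions = GenomicIntervalSet.from_records([("chr1", 0, 100)])
        with pytest.raises(ValueError, match="3 cells"):
            correlate_regions_with_score(m, regions, np.arange(2.0), DISTAL_ANNOTATION)


def build_bimodal_dataset(seed, n_cells=60, p=400, n_sig=4, n_null=4, width=100):
    """Half the regions sit on bins wired to the score, half on random bins."""
    rng = np.random.default_rng(seed)
    score = rng.normal(size=n_cells)
    counts = (rng.random((n_cells, p)) < 0.3).astype(int)
    regions = []
    # signal regions occupy bins [0, n_sig*5): accessibility tracks the score
    for r in range(n_sig):
        bins = slice(r * 5, (r + 1) * 5)
        prob = 1 / (1 + np.exp(-3 * score * (1 if r % 2 == 0 else -1)))
        counts[:, bins] = (rng.random((n_cells, 5)) < prob[:, None]).astype(int)
        regions.append(("chr1", r * 5 * width, (r + 1) * 5 * width))
    for r in range(n_null):
        start = (n_sig * 5 + r * 5) * width
        regions.append(("chr1", start, start + 5 * width))
    m = bin_matrix(counts, p, width=width)
    return m, GenomicIntervalSet.from_records(regions), score


class TestBimodalityPermutation:
    CHROM_SIZES = {"chr1": 40_000}

    def test_zero_permutations_give_p_one(self):
        m, regions, score = build_bimodal_dataset(0)
        _, p = bimodality_permutation_test(
            m, regions, score, DISTAL_ANNOTATION, self.CHROM_SIZES, n_perm=0, seed=1
        )
        assert p == 1.0

    def test_signal_regions_give_small_p(self):
        m, regions, score = build_bimodal_dataset(1)
        sig_only = regions.subset(np.arange(4))
        _, p = bimodality_permutation_test(
            m, sig_only, score, DISTAL_ANNOTATION, self.CHROM_SIZES, n_perm=99, seed=2
        )
        assert p <= 0.05

    def test_null_regions_give_large_p(self):
        m, regions, score = build_bimodal_dataset(2)
        null_only = regions.subset(np.arange(4, 8))
        _, p = bimodality_permutation_test(
            m, null_only, score, DISTAL_ANNOTATION, self.CHROM_SIZES, n_perm=99, seed=3
        )
        assert p > 0.1

    def test_region_longer_than_chromosome_fatal(self):
        m, regions, score = build_bimodal_dataset(3)
        with pytest.raises(ValueError, match="longer than chromosome"):
            bimodality_permutation_test(
                m, regions, score, DISTAL_ANNOTATION, {"chr1": 10}, n_perm=5, seed=1
            )


def enrichment_annotation(n_genes=40, spacing=10_000):
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n_genes)],
                "chrom": ["chr1"] * n_genes,
                "start": np.arange(n_genes) * spacing,
                "end": np.arange(n_genes) * spacing + 1000,
                "strand": ["+"] * n_genes,
            }
        )
    )


class TestNearestGeneEnrichment:
    def test_gene_set_equal_to_background_gives_p_one(self):
        ann = enrichment_annotation()
        background = ann.genes
        regions = GenomicIntervalSet.from_records([("chr1", 100, 200), ("chr1", 20_100, 20_200)])
        out = nearest_gene_enrichment(
            {"sub": regions}, {"all": set(background)}, background, ann, n_resample=50, seed=0
        )
        assert out.loc[0, "empirical_p"] == 1.0

    def test_concentrated_nearest_gene_gives_small_p(self):
        ann = enrichment_annotation()
        background = ann.genes
        regions = GenomicIntervalSet.from_records(
            [("chr1", 50, 150), ("chr1", 120, 220), ("chr1", 10, 110)]
        )  # all nearest to g0
        out = nearest_gene_enrichment(
            {"sub": regions}, {"hit": {"g0"}}, background, ann, n_resample=199, seed=1
        )
        assert out.loc[0, "observed_fraction"] == 1.0
        assert out.loc[0, "empirical_p"] < 0.1

    def test_gene_set_larger_than_background_fatal(self):
        ann = enrichment_annotation(5)
        regions = GenomicIntervalSet.from_records([("chr1", 0, 10)])
        with pytest.raises(ValueError, match="larger than background"):
            nearest_gene_enrichment(
                {"s": regions}, {"big": set("abcdefgh")}, ["g0", "g1"], ann, n_resample=5
            )

    def test_disjoint_gene_set_warns(self):
        ann = enrichment_annotation(5)
        regions = GenomicIntervalSet.from_records([("chr1", 0, 10)])
        with pytest.warns(UserWarning, match="disjoint"):
            nearest_gene_enrichment(
                {"s": regions}, {"d": {"zzz"}}, ann.genes, ann, n_resample=5, seed=0
            )

    def test_pvalues_super_uniform_under_null(self):
        """Gene sets drawn from the background: ECDF of p-values must not
        exceed uniform by more than sampling noise (one-sided KS)."""
        ann = enrichment_annotation()
        background = ann.genes
        rng = np.random.default_rng(42)
        starts = rng.integers(0, 390_000, size=25)
        regions = GenomicIntervalSet.from_records(
            [("chr1", int(s), int(s) + 500) for s in starts]
        )
        pvals = []
        for rep in range(200):
            gene_set = set(rng.choice(background, size=5, replace=False))
            out = nearest_gene_enrichment(
                {"s": regions}, {"x": gene_set}, background, ann, n_resample=99, seed=rep
            )
            pvals.append(out.loc[0, "empirical_p"])
        pvals = np.sort(pvals)
        ecdf_excess = np.max(np.arange(1, 201) / 200 - pvals)
        assert ecdf_excess < 0.12  # 1.63/sqrt(200) ~ 0.115 at alpha=0.01
        assert pvals.min() >= 1 / 100
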