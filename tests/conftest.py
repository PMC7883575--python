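import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from labelwalk.genome import GenomicIntervalSet
from labelwalk.types import CellByFeatureMatrix, GeneAnnotation, MarkerSet


@pytest.fixture
def annotation():
    """Two genes on chr1 (one per strand), one on chr2."""
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene": ["G1", "G2", "G3"],
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [100, 5000, 1000],
                "end": [500, 6000, 2000],
                "strand": ["+", "-", "+"],
            }
        )
    )


@pytest.fixture
def markers():
    return MarkerSet(
        pd.DataFrame(
            {
                "label": ["A", "A", "B"],
                "gene": ["G1", "G2", "G3"],
                "logfc": [2.0, 1.0, 0.5],
            }
        )
    )


def make_peak_matrix(counts, peaks, cell_ids=None):
    counts = np.asarray(counts)
    if cell_ids is None:
        cell_ids = [f"c{i}" for i in range(counts.shape[0])]
    return CellByFeatureMatrix(
        sp.csr_matrix(counts),
        cell_ids,
        GenomicIntervalSet.from_records(peaks),
        "peak",
    )


@pytest.fixture
def peak_matrix(annotation):
    """4 cells x 4 peaks; peaks 0,1 hit G1's window, peak 2 hits G2's, peak 3
    is distal on chr2."""
    peaks = [
        ("chr1", 50, 150, "p0"),
        ("chr1", 400, 450, "p1"),
        ("chr1", 5500, 5600, "p2"),
        ("chr2", 9000, 9100, "p3"),
    ]
    counts = [
        [1, 1, 0, 0],
        [0, 1, 1, 1],
        [0, 0, 0, 2],
        [1, 0, 1, 0],
    ]
    return make_peak_matrix(counts, peaks)
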