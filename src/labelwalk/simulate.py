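"""Synthetic scATAC-like data with known cell types.

Cells draw a total read depth (lognormal, median 5500 by default), spread
reads over p bins by a global propensity vector, and receive a fixed percent
of extra type-specific reads on their type's half of the bins. Labeling is
partial and optionally wrong; read noise adds or drops reads; an unlabeled
mixture population blends the global propensity toward one type.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from .genome import GenomicIntervalSet
from .types import CellByFeatureMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_two_types",
    "make_label_edges",
    "perturb_reads",
    "simulate_mixture_population",
    "simulation_cell_edges",
    "labeling_accuracy",
]

TYPE_LABELS = ("type1", "type2")


@dataclass
class SimulationConfig:
    """Parameters of the two-type synthetic protocol."""

    n_per_type: int = 400
    n_bins: int = 2000
    depth_median: float = 5500.0
    depth_sigma: float = 0.5
    depth_empirical: list | None = None  # overrides the lognormal sampler
    bin_propensity: list | None = None  # default: Dirichlet(0.5) draw per seed
    distinctness_pct: float = 5.0
    frac_labeled: float = 0.15
    frac_mislabeled: float = 0.0
    noise_pct: float = 0.0
    noise_mode: str = "add"
    mixture_n_cells: int = 0
    mixture_proportion: float = 0.3
    shuffle_bin_split: bool = False
    distinct_flatten: float = 0.5  # exponent on propensity for extra reads
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_type < 1:
            raise ValueError("n_per_type must be positive")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        for name in ("frac_labeled", "frac_mislabeled"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.distinctness_pct < 0:
            raise ValueError("distinctness_pct must be >= 0")
        if self.noise_pct < 0:
            raise ValueError("noise_pct must be >= 0")
        if self.noise_mode not in ("add", "drop"):
            raise ValueError("noise_mode must be 'add' or 'drop'")
        if self.bin_propensity is not None:
            p = np.asarray(self.bin_propensity, dtype=float)
            if len(p) != self.n_bins or not np.isclose(p.sum(), 1.0):
                raise ValueError("bin_propensity must sum to 1 over n_bins entries")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls(**json.loads(text))


@dataclass
class SimulatedDataset:
    matrix: CellByFeatureMatrix
    true_type: np.ndarray  # per-cell type id strings
    label_edges: np.ndarray  # (2, n_cells) 0/1
    config: SimulationConfig
    propensity: np.ndarray
    type_bins: dict = field(default_factory=dict)  # label -> bin index array

    @property
    def labels(self) -> list:
        return list(TYPE_LABELS)


def _bin_intervals(p: int) -> GenomicIntervalSet:
    width = 1000
    return GenomicIntervalSet(
        np.array(["chrS"] * p, dtype=object),
        np.arange(p, dtype=np.int64) * width,
        (np.arange(p, dtype=np.int64) + 1) * width,
        np.array([f"bin{i}" for i in range(p)], dtype=object),
    )


def _sample_depths(config: SimulationConfig, n: int, rng) -> np.ndarray:
    if config.depth_empirical is not None:
        depths = rng.choice(np.asarray(config.depth_empirical), size=n)
    else:
        depths = rng.lognormal(np.log(config.depth_median), config.depth_sigma, n)
    return np.maximum(np.rint(depths).astype(np.int64), 1)


def _restricted(
    propensity: np.ndarray, bins: np.ndarray, flatten: float = 1.0
) -> np.ndarray:
    """Propensity restricted to ``bins`` and renormalized; ``flatten`` < 1
    spreads mass toward low-propensity bins (exponent on the propensity)."""
    out = np.zeros_like(propensity)
    out[bins] = propensity[bins] ** flatten
    total = out.sum()
    if total == 0:  # degenerate propensity; fall back to uniform on the half
        out[bins] = 1.0 / len(bins)
        return out
    return out / total


def simulate_two_types(config: SimulationConfig, seed=None) -> SimulatedDataset:
    """Generate two cell types of ``n_per_type`` cells over ``n_bins`` bins.

    Bins are split evenly: the first half is enriched in type1, the second in
    type2. Each cell gets floor-rounded ``distinctness_pct`` percent extra
    reads multinomially over its type's bins. Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = config.n_bins
    if config.bin_propensity is not None:
        propensity = np.asarray(config.bin_propensity, dtype=float)
    else:
        propensity = rng.dirichlet(np.full(p, 0.5))
    order = rng.permutation(p) if config.shuffle_bin_split else np.arange(p)
    half = p // 2
    type_bins = {TYPE_LABELS[0]: np.sort(order[:half]), TYPE_LABELS[1]: np.sort(order[half:])}

    n = 2 * config.n_per_type
    depths = _sample_depths(config, n, rng)
    counts = rng.multinomial(depths, propensity)
    true_type = np.array(
        [TYPE_LABELS[0]] * config.n_per_type + [TYPE_LABELS[1]] * config.n_per_type,
        dtype=object,
    )
    extra = np.rint(config.distinctness_pct / 100.0 * depths).astype(np.int64)
    for label in TYPE_LABELS:
        cells = np.flatnonzero(true_type == label)
        restricted = _restricted(
            propensity, type_bins[label], config.distinct_flatten
        )
        counts[cells] += rng.multinomial(extra[cells], restricted)

    matrix = CellByFeatureMatrix(
        sp.csr_matrix(counts),
        [f"cell{i}" for i in range(n)],
        _bin_intervals(p),
        "bin",
    )
    edges = make_label_edges(
        true_type, config.frac_labeled, config.frac_mislabeled, rng
    )
    return SimulatedDataset(matrix, true_type, edges, config, propensity, type_bins)


def make_label_edges(
    true_type: np.ndarray, frac_labeled: float, frac_mislabeled: float, seed=None
) -> np.ndarray:
    """Weight-1 label edges: an exact ``frac_labeled`` share of each type's
    cells gets its true label, an independently drawn ``frac_mislabeled``
    share gets the wrong one (a cell may receive both).

    Sampling is stratified per type so labeled counts are exact per label;
    unequal per-label edge counts would bias maximum-influence assignment
    toward the larger label. Mixture cells are never labeled.
    """
    for name, v in (("frac_labeled", frac_labeled), ("frac_mislabeled", frac_mislabeled)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    true_type = np.asarray(true_type, dtype=object)
    n = len(true_type)
    edges = np.zeros((2, n))
    for ti, label in enumerate(TYPE_LABELS):
        cells = np.flatnonzero(true_type == label)
        correct = rng.choice(cells, int(round(frac_labeled * len(cells))), replace=False)
        wrong = rng.choice(cells, int(round(frac_mislabeled * len(cells))), replace=False)
        edges[ti, correct] = 1.0
        edges[1 - ti, wrong] = 1.0
    return edges


def perturb_reads(
    matrix: CellByFeatureMatrix,
    noise_pct: float,
    mode: str,
    seed=None,
    propensity: np.ndarray | None = None,
) -> CellByFeatureMatrix:
    """Add or drop floor(noise_pct% of each cell's reads).

    Drops remove reads uniformly over the cell's existing reads (multivariate
    hypergeometric); additions draw new reads multinomially from the global
    propensity vector.
    """
    if noise_pct < 0:
        raise ValueError("noise_pct must be >= 0")
    if mode not in ("add", "drop"):
        raise ValueError("mode must be 'add' or 'drop'")
    if mode == "drop" and noise_pct > 100:
        raise ValueError("cannot drop more than 100% of reads")
    if mode == "add" and propensity is None:
        raise ValueError("add mode needs the global bin propensity")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.asarray(matrix.values.todense(), dtype=np.int64)
    totals = counts.sum(axis=1)
    change = np.floor(noise_pct / 100.0 * totals).astype(np.int64)
    out = counts.copy()
    if mode == "drop":
        for i in range(counts.shape[0]):
            if change[i] == 0:
                continue
            out[i] -= rng.multivariate_hypergeometric(counts[i], int(change[i]))
    else:
        p = np.asarray(propensity, dtype=float)
        for i in range(counts.shape[0]):
            if change[i] == 0:
                continue
            out[i] += rng.multinomial(int(change[i]), p)
    return CellByFeatureMatrix(
        sp.csr_matrix(out), matrix.cell_ids, matrix.features, matrix.feature_kind
    )


def simulate_mixture_population(
    config: SimulationConfig,
    base: SimulatedDataset,
    mix_proportion: float,
    n_cells: int,
    seed=None,
) -> SimulatedDataset:
    """Append unlabeled cells whose read propensity blends the global vector
    with one type's bins at weight ``mix_proportion``.

    Each new cell leans toward a randomly chosen type, recorded as
    ``mixture(<type>, <proportion>)``; mixture cells get no label edges.
    """
    if n_cells == 0:
        return base
    if not 0 < mix_proportion < 1:
        raise ValueError("mix_proportion must be in (0, 1)")
    if set(np.unique(base.true_type)) != set(TYPE_LABELS):
        raise ValueError("base dataset must contain exactly the two base types")
    rng = np.random.default_rng(seed)
    p = base.config.n_bins
    depths = _sample_depths(config, n_cells, rng)
    toward = rng.integers(0, 2, size=n_cells)
    new_counts = np.zeros((n_cells, p), dtype=np.int64)
    for t in (0, 1):
        cells = np.flatnonzero(toward == t)
        if cells.size == 0:
            continue
        restricted = _restricted(base.propensity, base.type_bins[TYPE_LABELS[t]])
        blend = (1.0 - mix_proportion) * base.propensity + mix_proportion * restricted
        new_counts[cells] = rng.multinomial(depths[cells], blend)
    old = np.asarray(base.matrix.values.todense(), dtype=np.int64)
    all_counts = np.vstack([old, new_counts])
    n_old = base.matrix.n_cells
    cell_ids = list(base.matrix.cell_ids) + [f"mix{i}" for i in range(n_cells)]
    matrix = CellByFeatureMatrix(
        sp.csr_matrix(all_counts), cell_ids, base.matrix.features, "bin"
    )
    mix_type = np.array(
        [f"mixture({TYPE_LABELS[t]}, {mix_proportion:g})" for t in toward], dtype=object
    )
    true_type = np.concatenate([base.true_type, mix_type])
    edges = np.hstack([base.label_edges, np.zeros((2, n_cells))])
    return SimulatedDataset(
        matrix, true_type, edges, base.config, base.propensity, base.type_bins
    )


SIM_EDGE_DAMPING = 14.0


def simulation_cell_edges(matrix: CellByFeatureMatrix, damping: float = SIM_EDGE_DAMPING) -> np.ndarray:
    """Jaccard cell edges scaled for the simulation label-weight regime.

    Raw Jaccard similarities on dense synthetic bin profiles give each cell a
    total similarity mass of several hundred, which makes label edge weights
    in the 1e-4..1e-1 range inert. Dividing by ``damping * n_cells`` places
    that weight range across the transition from cell-dominated to
    label-dominated diffusion (only the ratio of label to cell edge mass
    affects the walk, so this is equivalent to rescaling the weight grid).
    """
    from .graph_build import jaccard_cell_similarity

    return jaccard_cell_similarity(matrix) / (damping * matrix.n_cells)


def labeling_accuracy(
    assigned: np.ndarray, true_type: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Fraction of (optionally masked) cells whose assigned label index
    matches their true type."""
    assigned = np.asarray(assigned)
    truth = np.array(
        [TYPE_LABELS.index(t) if t in TYPE_LABELS else -1 for t in np.asarray(true_type, dtype=object)]
    )
    ok = truth >= 0
    if mask is not None:
        ok &= np.asarray(mask, dtype=bool)
    if not ok.any():
        raise ValueError("no cells to score")
    return float(np.mean(assigned[ok] == truth[ok]))
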