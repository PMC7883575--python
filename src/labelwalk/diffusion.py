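"""Random walk with restarts: walk matrix and closed-form influence matrix.

The walk matrix is the row-normalized adjacency, W = D^-1 A. For restart
probability ``alpha`` the walk converges and the influence matrix has the
closed form F = alpha * (I - (1 - alpha) * W)^-1. We fix the reading
convention: F[i, j] is the influence of node j on node i, so the block
F[cells, labels] is label-to-cell influence.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph_build import CombinedGraph

__all__ = [
    "WalkMatrix",
    "InfluenceMatrix",
    "walk_matrix",
    "influence_matrix",
    "influence_series_oracle",
]

DENSE_NODE_CAP = 50_000


@dataclass
class WalkMatrix:
    """Row-stochastic transition matrix with the node index of its graph."""

    w: sp.csr_matrix
    n_cells: int
    labels: list
    cell_ids: list | None = None

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]


@dataclass
class InfluenceMatrix:
    """Dense influence matrix F with named cell/label blocks.

    Node order is inherited from the graph: cells first, labels last.
    """

    f: np.ndarray
    alpha: float
    n_cells: int
    labels: list
    cell_ids: list | None = None

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def cell_to_cell(self) -> np.ndarray:
        return self.f[: self.n_cells, : self.n_cells]

    @property
    def label_to_cell(self) -> np.ndarray:
        """(n_cells, n_labels): influence of each label on each cell."""
        return self.f[: self.n_cells, self.n_cells :]

    @property
    def cell_to_label(self) -> np.ndarray:
        """(n_labels, n_cells): influence of each cell on each label."""
        return self.f[self.n_cells :, : self.n_cells]

    @property
    def label_to_label(self) -> np.ndarray:
        return self.f[self.n_cells :, self.n_cells :]


def walk_matrix(graph: CombinedGraph) -> WalkMatrix:
    """Row-normalize the adjacency; zero-degree nodes become unit self-loops."""
    a = sp.csr_matrix(graph.adjacency, dtype=np.float64, copy=True)
    deg = np.asarray(a.sum(axis=1)).ravel()
    dead = np.flatnonzero(deg == 0)
    if dead.size:
        warnings.warn(
            f"{dead.size} zero-degree node(s) given self-loops: "
            f"{dead[:20].tolist()}",
            stacklevel=2,
        )
        a = a.tolil()
        for i in dead:
            a[i, i] = 1.0
        a = a.tocsr()
        deg = np.asarray(a.sum(axis=1)).ravel()
    w = sp.diags(1.0 / deg) @ a
    return WalkMatrix(sp.csr_matrix(w), graph.n_cells, graph.labels, graph.cell_ids)


def influence_matrix(
    w: WalkMatrix, alpha: float = 0.5, dense_cap: int = DENSE_NODE_CAP
) -> InfluenceMatrix:
    """Solve F = alpha * (I - (1 - alpha) * W)^-1 by direct linear solves."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    q = w.n_nodes
    m = sp.identity(q, format="csc") - (1.0 - alpha) * w.w
    if q <= dense_cap:
        f = alpha * np.linalg.inv(m.toarray())
    else:  # pragma: no cover - large-graph path, same math
        lu = spla.splu(sp.csc_matrix(m))
        f = alpha * lu.solve(np.eye(q))
    return InfluenceMatrix(f, float(alpha), w.n_cells, w.labels, w.cell_ids)


def influence_columns(
    w: WalkMatrix, columns: np.ndarray, alpha: float = 0.5
) -> np.ndarray:
    """Selected columns of F without materializing the full matrix.

    Column j of F is alpha * (I - (1-alpha) W)^-1 e_j.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    q = w.n_nodes
    m = sp.csc_matrix(sp.identity(q) - (1.0 - alpha) * w.w)
    lu = spla.splu(m)
    rhs = np.zeros((q, len(columns)))
    rhs[np.asarray(columns, dtype=np.intp), np.arange(len(columns))] = alpha
    return lu.solve(rhs)


def influence_series_oracle(w, alpha: float, k_max: int) -> np.ndarray:
    """Truncated Neumann expansion alpha * sum_k (1-alpha)^k W^k (tests only)."""
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    wm = w.w if isinstance(w, WalkMatrix) else sp.csr_matrix(w)
    q = wm.shape[0]
    acc = np.eye(q)
    term = np.eye(q)
    wd = wm.toarray()
    for _ in range(k_max):
        term = (1.0 - alpha) * (term @ wd)
        acc += term
    return alpha * acc
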