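"""Mutual KNN cell graph, Gaussian affinities and the graph Laplacian.

The graph regularizer γ·Tr(VᵀLV) encourages cells that are close in the
preprocessed expression space to take similar factor coefficients.  Edges
are kept only when each endpoint is among the other's K nearest neighbors
(mutual rule), weighted with a Gaussian kernel
w = exp(−d² / (2σ²)), and L = D − W is the unnormalized Laplacian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial.distance import squareform, pdist

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


def default_n_neighbors(n_cells: int) -> int:
    """K ≈ one-third of the cells, capped at 1000 to bound graph density."""
    return max(1, min(n_cells // 3, 1000, n_cells - 1))


@dataclass
class CellGraph:
    """Affinity matrix W, degrees D and Laplacian L = D − W over cells."""

    W: sparse.csr_matrix
    degrees: np.ndarray
    K: int
    sigma: float

    @property
    def n_cells(self) -> int:
        return self.W.shape[0]

    @property
    def laplacian(self) -> sparse.csr_matrix:
        return (sparse.diags(self.degrees) - self.W).tocsr()


def mutual_knn_edges(
    x: ExpressionMatrix | np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mutual K-nearest-neighbor edges with Euclidean distances.

    Cells are the columns of ``x``.  Returns arrays (i, j, d) with i < j,
    one entry per undirected edge.  Ties at the K-th neighbor distance are
    all included, which keeps the edge set invariant to cell reordering.
    """
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x)
    n = values.shape[1]
    if not 1 <= K < n:
        raise ValueError(f"K must satisfy 1 <= K < n_cells; got K={K}, n={n}")
    d = squareform(pdist(values.T))
    np.fill_diagonal(d, np.inf)
    # distance to the K-th nearest neighbor of each cell
    kth = np.partition(d, K - 1, axis=1)[:, K - 1]
    near = d <= (kth[:, None] + _TIE_TOL)  # includes ties at the K-th distance
    mutual = near & near.T
    ii, jj = np.nonzero(np.triu(mutual, k=1))
    return ii, jj, d[ii, jj]


def gaussian_weights(
    edges: tuple[np.ndarray, np.ndarray, np.ndarray],
    n_cells: int,
    K: int,
    sigma: float | None = None,
) -> CellGraph:
    """Assemble the weighted graph from an edge list.

    ``sigma`` defaults to the median distance over the retained mutual-KNN
    edges (each undirected edge counted once).  If that median is zero
    because many cells coincide, the median of the positive edge distances
    is used instead; if every edge has zero length the bandwidth is
    undefined and an error is raised.
    """
    ii, jj, dist = edges
    if len(ii) == 0:
        raise ValueError("no mutual-KNN edges; increase K")
    if sigma is None:
        sigma = float(np.median(dist))
        if sigma <= 0:
            pos = dist[dist > 0]
            if pos.size == 0:
                raise ValueError(
                    "all edge distances are zero (duplicate cells only); "
                    "bandwidth sigma is undefined"
                )
            sigma = float(np.median(pos))
            logger.warning(
                "median edge distance is 0; using median positive distance "
                "sigma=%.4g", sigma,
            )
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    w = np.exp(-(dist ** 2) / (2.0 * sigma ** 2))
    rows = np.concatenate([ii, jj])
    cols = np.concatenate([jj, ii])
    data = np.concatenate([w, w])
    W = sparse.csr_matrix((data, (rows, cols)), shape=(n_cells, n_cells))
    degrees = np.asarray(W.sum(axis=1)).ravel()
    isolated = int((degrees == 0).sum())
    if isolated:
        logger.info("%d isolated cell(s) with no mutual neighbors", isolated)
    return CellGraph(W=W, degrees=degrees, K=K, sigma=sigma)


def build_cell_graph(
    x: ExpressionMatrix | np.ndarray,
    K: int | None = None,
    sigma: float | None = None,
) -> CellGraph:
    """Convenience wrapper: mutual KNN edges + Gaussian weights."""
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x)
    if K is None:
        K = default_n_neighbors(values.shape[1])
    edges = mutual_knn_edges(values, K)
    return gaussian_weights(edges, values.shape[1], K, sigma=sigma)


def laplacian_quadratic(V: np.ndarray, g: CellGraph) -> float:
    """Tr(VᵀLV) = ½ Σ_{j1,j2} w_{j1 j2} ||V_{j1} − V_{j2}||²."""
    V = np.asarray(V, dtype=float)
    if V.shape[0] != g.n_cells:
        raise ValueError(
            f"V has {V.shape[0]} rows but the graph has {g.n_cells} cells"
        )
    LV = g.degrees[:, None] * V - g.W @ V
    return float(np.sum(V * LV))
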