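"""Patient similarity network and its graph Laplacian.

Patients are nodes; the edge weight between patients i and j is a Gaussian
kernel of their Euclidean distance in (standardized) clinical-variable
space, w_ij = exp(-dist(v_i, v_j)/sigma^2).  The graph Laplacian
L = D - W (D the diagonal degree matrix) is what the label-propagation
model regularizes against: f^T L f penalizes score differences across
strongly connected patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GraphConfig",
    "PatientGraph",
    "pairwise_distances",
    "build_graph",
]


@dataclass(frozen=True)
class GraphConfig:
    """Kernel and sparsification settings for the patient network.

    Parameters
    ----------
    sigma : float
        Positive kernel width; larger sigma keeps distant patients connected.
    distance_mode : {"linear", "squared"}
        ``linear`` puts the plain Euclidean distance in the exponent,
        w_ij = exp(-d_ij / sigma^2); ``squared`` is the conventional RBF
        kernel exp(-d_ij^2 / sigma^2).  Both are supported because the two
        conventions differ only in how sigma rescales distances.
    sparsify_k : int or None
        If set, keep w_ij only when j is among i's k nearest neighbours or
        vice versa (symmetric union); None keeps the dense graph.
    """

    sigma: float = 1.0
    distance_mode: str = "linear"
    sparsify_k: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.distance_mode not in ("linear", "squared"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")
        if self.sparsify_k is not None and self.sparsify_k <= 0:
            raise ValueError("sparsify_k must be positive when set")


@dataclass
class PatientGraph:
    """Symmetric weighted patient network with cached degree/Laplacian."""

    weights: np.ndarray  # (n, n) symmetric, zero diagonal, entries in [0,1]
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        W = self.weights
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if (W < 0).any() or (W > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0,1]")
        if self.node_ids is None:
            self.node_ids = np.arange(W.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def laplacian(self) -> np.ndarray:
        """L = D - W; rows sum to zero and L is positive semi-definite."""
        L = -self.weights.copy()
        np.fill_diagonal(L, self.degrees)
        return L

    def n_components(self, weight_floor: float = 0.0) -> int:
        adj = self.weights > weight_floor
        return int(connected_components(adj, directed=False)[0])

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle nonzero edges as a (source, target, weight) table."""
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return pd.DataFrame(
            {
                "source": np.asarray(self.node_ids)[i],
                "target": np.asarray(self.node_ids)[j],
                "weight": self.weights[i, j],
            }
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(np.asarray(self.node_ids))
        for _, row in self.edge_list().iterrows():
            g.add_edge(row["source"], row["target"], weight=row["weight"])
        return g


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    """Dense symmetric Euclidean distance matrix with zero diagonal."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    return squareform(pdist(X, metric="euclidean"))


def _kernel(dist: np.ndarray, config: GraphConfig) -> np.ndarray:
    if config.distance_mode == "squared":
        dist = dist**2
    W = np.exp(-dist / config.sigma**2)
    np.fill_diagonal(W, 0.0)
    return W


def _knn_mask(dist: np.ndarray, k: int) -> np.ndarray:
    n = dist.shape[0]
    d = dist + np.diag(np.full(n, np.inf))  # never self-neighbour
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    mask[rows, nn.ravel()] = True
    return mask | mask.T  # symmetric union


def build_graph(
    X: np.ndarray,
    config: GraphConfig,
    node_ids=None,
    dist: np.ndarray | None = None,
) -> PatientGraph:
    """Build the patient network from a (standardized) feature matrix.

    ``dist`` may be passed to reuse a precomputed distance matrix when
    scanning several kernel widths over the same patients.
    """
    if dist is None:
        dist = pairwise_distances(X)
    W = _kernel(dist, config)
    if config.sparsify_k is not None:
        if config.sparsify_k >= W.shape[0]:
            raise ValueError("sparsify_k must be smaller than the number of nodes")
        W = np.where(_knn_mask(dist, config.sparsify_k), W, 0.0)
    return PatientGraph(weights=W, node_ids=node_ids)
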