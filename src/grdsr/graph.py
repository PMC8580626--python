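"""k-nearest-neighbour similarity graphs over samples and their Laplacians.

The model regularizes every layer's code matrix with the quadratic form
``Tr(H L H^T)``, where ``L = D - S`` is the (combinatorial) graph Laplacian
of a kNN similarity graph built once over the columns (samples) of the
input matrix.  Because ``Tr(H L H^T) = (1/2) * sum_ij S_ij * ||h_i - h_j||^2``,
small values mean that samples connected in the input space receive similar
codes — the locality assumption.

Three edge-weighting schemes are supported: binary 0/1 weights, the heat
kernel ``exp(-||x_i - x_j||^2 / sigma)``, and the raw dot product (cosine
similarity when columns are unit-normalized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import NumericalError

__all__ = [
    "SimilarityGraph",
    "build_knn_adjacency",
    "compute_weights",
    "compute_laplacian",
    "graph_smoothness",
    "build_graph",
    "save_graph_tsv",
    "load_graph_tsv",
]

SCHEMES = ("zero_one", "heat_kernel", "dot_product")


@dataclass
class SimilarityGraph:
    """A sample-similarity graph together with its Laplacian.

    Attributes
    ----------
    S : (n, n) ndarray
        Symmetric nonnegative weight matrix with a zero diagonal
        (dot-product weights may be negative for non-normalized data).
    D : (n, n) ndarray
        Diagonal degree matrix, ``D_ii = sum_j S_ij``.
    L : (n, n) ndarray
        Combinatorial Laplacian ``L = D - S``; symmetric PSD, rows sum to 0.
    k : int
        Neighbour count used to build the adjacency.
    scheme : str
        One of ``zero_one``, ``heat_kernel``, ``dot_product``.
    sigma : float or None
        Heat-kernel bandwidth (only meaningful for ``heat_kernel``).
    """

    S: np.ndarray
    D: np.ndarray
    L: np.ndarray
    k: int
    scheme: str
    sigma: float | None = None
    # eigendecomposition of L, computed lazily and reused by the Sylvester
    # solver (L is shared by every layer update)
    _L_eig: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n_samples(self) -> int:
        return self.S.shape[0]

    def laplacian_eig(self):
        """Eigendecomposition ``(eigvals, eigvecs)`` of L, cached."""
        if self._L_eig is None:
            w, V = np.linalg.eigh(self.L)
            self._L_eig = (w, V)
        return self._L_eig


def _pairwise_sq_distances(X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between columns of X."""
    return squareform(pdist(np.asarray(X, dtype=float).T, metric="sqeuclidean"))


def build_knn_adjacency(X: np.ndarray, k: int) -> np.ndarray:
    """Boolean symmetric kNN connectivity over the columns of ``X``.

    Each sample is linked to its ``k`` nearest neighbours under Euclidean
    distance; the directed graph is symmetrized by union, so an edge is
    present if either endpoint lists the other.  Distance ties are broken
    by the smaller sample index for determinism; the diagonal is False.

    Parameters
    ----------
    X : (m, n) ndarray
        Feature-by-sample matrix with finite entries.
    k : int
        Number of neighbours, ``0 < k < n``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D feature-by-sample matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    n = X.shape[1]
    k = int(k)
    if not 0 < k < n:
        raise ValueError(f"k must satisfy 0 < k < n_samples; got k={k}, n={n}")

    d2 = _pairwise_sq_distances(X)
    np.fill_diagonal(d2, np.inf)  # never a self-neighbour
    adj = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        # stable order: primary key distance, secondary key sample index
        order = np.lexsort((idx, d2[i]))
        adj[i, order[:k]] = True
    adj |= adj.T  # union symmetrization
    return adj


def compute_weights(
    X: np.ndarray,
    adjacency: np.ndarray,
    scheme: str = "zero_one",
    sigma: float | None = None,
) -> np.ndarray:
    """Edge weights S for a given connectivity pattern.

    ``zero_one``: ``S_ij = 1`` on edges.  ``heat_kernel``:
    ``S_ij = exp(-||x_i - x_j||^2 / sigma)``.  ``dot_product``:
    ``S_ij = x_i^T x_j`` (cosine similarity for unit-norm columns).
    Non-edges get weight 0.
    """
    X = np.asarray(X, dtype=float)
    adjacency = np.asarray(adjacency)
    if adjacency.dtype != bool:
        raise ValueError("adjacency must be a boolean matrix")
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}; choose from {SCHEMES}")

    if scheme == "zero_one":
        S = adjacency.astype(float)
    elif scheme == "heat_kernel":
        if sigma is None or sigma <= 0:
            raise ValueError("heat_kernel weighting requires sigma > 0")
        d2 = _pairwise_sq_distances(X)
        S = np.where(adjacency, np.exp(-d2 / sigma), 0.0)
    else:  # dot_product
        G = X.T @ X
        S = np.where(adjacency, G, 0.0)
    np.fill_diagonal(S, 0.0)
    if not np.all(np.isfinite(S)):
        raise NumericalError("non-finite edge weight (overflow in weighting)")
    # exact symmetry despite floating-point evaluation order
    S = 0.5 * (S + S.T)
    return S


def compute_laplacian(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree matrix D and Laplacian ``L = D - S`` for a weight matrix."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, rtol=0.0, atol=1e-12 * max(1.0, np.abs(S).max())):
        raise ValueError("S must be symmetric")
    if np.any(np.abs(np.diag(S)) > 1e-12):
        raise ValueError("S must have a zero diagonal")
    degrees = S.sum(axis=1)
    D = np.diag(degrees)
    L = D - S
    return D, L


def graph_smoothness(H: np.ndarray, L: np.ndarray) -> float:
    """Smoothness penalty ``Tr(H L H^T)`` of a code matrix over the graph.

    Identical to ``(1/2) sum_ij S_ij ||h_i - h_j||^2``; zero when all
    columns are equal, and quadratic in the scale of H.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    L = np.asarray(L, dtype=float)
    if H.shape[1] != L.shape[0]:
        raise ValueError(
            f"H has {H.shape[1]} columns but L is {L.shape[0]}x{L.shape[1]}"
        )
    return float(np.sum((H @ L) * H))


def _self_tuning_sigma(X: np.ndarray, adjacency: np.ndarray) -> float:
    """Median squared distance among connected pairs (heat-kernel default)."""
    d2 = _pairwise_sq_distances(X)
    iu = np.triu_indices_from(adjacency, k=1)
    edge_d2 = d2[iu][adjacency[iu]]
    sigma = float(np.median(edge_d2)) if edge_d2.size else 1.0
    if sigma <= 0:  # duplicate-heavy data: all connected pairs coincide
        sigma = 1.0
        warnings.warn(
            "median edge distance is zero; falling back to sigma=1.0", stacklevel=2
        )
    return sigma


def build_graph(
    X: np.ndarray,
    k: int = 5,
    scheme: str = "zero_one",
    sigma: float | None = None,
) -> SimilarityGraph:
    """Build the kNN similarity graph and Laplacian over the samples of X.

    For the heat kernel, ``sigma=None`` self-tunes to the median squared
    distance among connected pairs.
    """
    adjacency = build_knn_adjacency(X, k)
    if scheme == "heat_kernel" and sigma is None:
        sigma = _self_tuning_sigma(X, adjacency)
    S = compute_weights(X, adjacency, scheme=scheme, sigma=sigma)
    D, L = compute_laplacian(S)
    return SimilarityGraph(S=S, D=D, L=L, k=k, scheme=scheme, sigma=sigma)


def save_graph_tsv(graph: SimilarityGraph, path) -> None:
    """Write the dense weight matrix as TSV (debugging aid)."""
    header = f"k={graph.k}\tscheme={graph.scheme}\tsigma={graph.sigma}"
    np.savetxt(path, graph.S, delimiter="\t", header=header)


def load_graph_tsv(path, k: int = 0, scheme: str = "zero_one") -> SimilarityGraph:
    """Rebuild a :class:`SimilarityGraph` from a TSV weight matrix."""
    S = np.loadtxt(path, delimiter="\t")
    D, L = compute_laplacian(S)
    return SimilarityGraph(S=S, D=D, L=L, k=k, scheme=scheme)
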