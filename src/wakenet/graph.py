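"""Weighted graph metrics on connectivity matrices.

Degree, clustering coefficient and characteristic path length on weighted
undirected graphs with weights in [0, 1]:

* degree          K_i = sum_j w_ij
* clustering      geometric-mean triangle intensity around each node
* path length     lambda = mean shortest-path distance over ordered node
                  pairs, with edge length d_ij = 1 - w_ij (strong
                  connectivity means short distance); absent edges (w = 0)
                  are non-traversable.

Two clustering normalizations are provided.  The default, ``bct``, follows
the standard weighted formulation used by the Brain Connectivity Toolbox:

    C_i = sum_{j != k} (w_ij w_jk w_ki)^{1/3} / (k_i (k_i - 1))

with k_i the *count* of nonzero edges at node i, which keeps C_i in [0, 1]
for weights in [0, 1].  The ``literal`` variant instead normalizes by the
weighted degree K_i:

    C_i = 2 sum_{j < k} (w_ij w_jk w_ki)^{1/3} / (K_i (K_i - 1))

This form is retained for transparency but can exceed 1 on dense weak
graphs; ``bct`` is the analysis default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix, validate_weights

CONVENTIONS = ("bct", "literal")


def _as_weights(W: "np.ndarray | ConnectivityMatrix") -> np.ndarray:
    if isinstance(W, ConnectivityMatrix):
        return W.weights
    W = np.asarray(W, dtype=float)
    validate_weights(W)
    return W


def degrees(W) -> np.ndarray:
    """Weighted degree K_i = row sum of the connectivity matrix."""
    return _as_weights(W).sum(axis=1)


def clustering_coefficients(W, convention: str = "bct") -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients C_i and their network mean.

    Nodes with fewer than two incident edges have no possible triangle and
    get C_i = 0 in both conventions; in the literal convention a weighted
    degree K_i <= 1 makes the normalization K_i (K_i - 1) non-positive and
    such nodes are likewise assigned 0.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown clustering convention {convention!r}; choose from {CONVENTIONS}")
    W = _as_weights(W)
    n = W.shape[0]
    cube_root = np.cbrt(W)
    # ordered-pair triangle sum: diag of (W^(1/3))^3
    numerator = np.einsum("ij,jk,ki->i", cube_root, cube_root, cube_root)
    if convention == "bct":
        k = np.count_nonzero(W, axis=1).astype(float)
        denom = k * (k - 1)
    else:
        K = W.sum(axis=1)
        denom = K * (K - 1)
    C = np.zeros(n)
    ok = denom > 0
    C[ok] = numerator[ok] / denom[ok]
    k_bin = np.count_nonzero(W, axis=1)
    C[k_bin < 2] = 0.0
    return C, float(C.mean()) if n else 0.0


def distance_matrix(W) -> np.ndarray:
    """All-pairs shortest-path distances with edge lengths 1 - w.

    Edges with w = 0 are absent (non-traversable); unreachable pairs are
    ``inf``.  d(i, i) = 0.  A masked-array Dijkstra is used so that
    zero-length edges (w = 1) remain traversable.
    """
    W = _as_weights(W)
    lengths = 1.0 - W
    masked = np.ma.masked_array(lengths, mask=(W == 0))
    D = shortest_path(masked, method="D", directed=False)
    np.fill_diagonal(D, 0.0)
    return D


def path_length(W, return_disconnected: bool = False):
    """Characteristic path length: mean d(i, j) over ordered pairs i != j.

    When some pairs are unreachable the mean is taken over the reachable
    pairs only, a warning is emitted, and the disconnected ordered-pair
    count is available via ``return_disconnected=True``.
    """
    W = _as_weights(W)
    n = W.shape[0]
    if n < 2:
        raise ValueError("path length requires at least 2 nodes")
    D = distance_matrix(W)
    off = ~np.eye(n, dtype=bool)
    d = D[off]
    finite = np.isfinite(d)
    n_disconnected = int(np.sum(~finite))
    if n_disconnected:
        warnings.warn(
            f"{n_disconnected} ordered node pair(s) unreachable; "
            "path length averaged over reachable pairs"
        )
        lam = float(d[finite].mean()) if np.any(finite) else float("inf")
    else:
        lam = float(d.mean())
    if return_disconnected:
        return lam, n_disconnected
    return lam


@dataclass
class GraphMetrics:
    """Node-level and network-level small-world metrics for one graph."""

    clustering: np.ndarray  # per-node C_i
    degree: np.ndarray  # per-node K_i
    mean_clustering: float
    path_length: float
    n_nodes: int
    disconnected_pairs: int
    convention: str

    @classmethod
    def from_connectivity(cls, W, convention: str = "bct") -> "GraphMetrics":
        weights = _as_weights(W)
        C, cbar = clustering_coefficients(weights, convention)
        K = degrees(weights)
        lam, ndis = path_length(weights, return_disconnected=True)
        return cls(C, K, cbar, lam, weights.shape[0], ndis, convention)
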