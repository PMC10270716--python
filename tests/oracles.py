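"""Independent brute-force oracles used to validate the graph metrics."""

import numpy as np


def brute_clustering(W: np.ndarray, convention: str) -> np.ndarray:
    """Exhaustive ordered-triple enumeration of the clustering coefficient."""
    n = W.shape[0]
    C = np.zeros(n)
    for i in range(n):
        num = 0.0
        for j in range(n):
            for k in range(n):
                if j != i and k != i and j != k:
                    num += (W[i, j] * W[j, k] * W[k, i]) ** (1 / 3)
        if convention == "bct":
            k_i = np.count_nonzero(W[i])
            denom = k_i * (k_i - 1)
        else:
            K_i = W[i].sum()
            denom = K_i * (K_i - 1)
        if np.count_nonzero(W[i]) < 2 or denom <= 0:
            C[i] = 0.0  # degenerate normalization (fewer than 2 edges or K <= 1)
        else:
            C[i] = num / denom
    return C


def brute_distances(W: np.ndarray) -> np.ndarray:
    """Floyd-Warshall with lengths 1 - w and absent zero-weight edges."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                D[i, j] = 1.0 - W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def brute_path_length(W: np.ndarray) -> float:
    D = brute_distances(W)
    off = ~np.eye(W.shape[0], dtype=bool)
    vals = D[off]
    finite = np.isfinite(vals)
    return float(vals[finite].mean())
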