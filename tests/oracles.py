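"""Independent reference implementations used as test oracles.

Each oracle deliberately takes a different algorithmic route from the
package code it checks: union-find vs. spectral counting, brute-force
loops vs. vectorized linear algebra, ISTA / primal-dual splitting vs.
coordinate descent / ADMM, and a generic bound-constrained quasi-Newton
solver vs. the closed-form W-step.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def union_find_components(W: np.ndarray, edge_tol: float = 1e-10) -> np.ndarray:
    """Connected-component labels by plain union-find over edges."""
    n = W.shape[0]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > edge_tol:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots = [find(i) for i in range(n)]
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        labels[i] = remap.setdefault(r, len(remap))
    return labels


def brute_force_sq_distances(F: np.ndarray) -> np.ndarray:
    """Double-loop squared Euclidean row distances."""
    n = F.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            diff = F[i] - F[j]
            D[i, j] = float(np.dot(diff, diff))
    return D


def pearson_textbook(X_raw: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation via the covariance / sigma-product formula."""
    m, n = X_raw.shape
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            xi = X_raw[:, i] - X_raw[:, i].mean()
            xj = X_raw[:, j] - X_raw[:, j].mean()
            W[i, j] = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
    return W


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def ista_sparse_regression(
    X: np.ndarray,
    lam: float,
    n_iter: int = 200_000,
    zero_diagonal: bool = True,
) -> np.ndarray:
    """ISTA on ``min ||X - XW||_F^2 + lam ||W||_1`` (zero diagonal).

    Plain proximal gradient with a fixed 1/L step; run long so the
    objective is tight for small instances.
    """
    n = X.shape[1]
    G = X.T @ X
    L = 2.0 * np.linalg.eigvalsh(G)[-1]
    W = np.zeros((n, n))
    for _ in range(n_iter):
        grad = 2.0 * (G @ W - G)
        W = _soft(W - grad / L, lam / L)
        if zero_diagonal:
            np.fill_diagonal(W, 0.0)
    return W


def _svt(M: np.ndarray, t: float) -> np.ndarray:
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return (U * np.maximum(s - t, 0.0)) @ Vt


def condat_vu_sparse_lowrank(
    X: np.ndarray,
    lam1: float,
    lam2: float,
    n_iter: int = 50_000,
    zero_diagonal: bool = True,
) -> np.ndarray:
    """Condat-Vu primal-dual splitting for
    ``min ||X - XW||_F^2 + lam1 ||W||_1 + lam2 ||W||_*`` (zero diagonal).

    The smooth quadratic enters by gradient, the l1 term (plus diagonal
    constraint) by its primal prox, and the trace norm through its dual
    prox (residual of singular-value thresholding).
    """
    n = X.shape[1]
    G = X.T @ X
    Lip = 2.0 * np.linalg.eigvalsh(G)[-1]
    sigma = 1.0
    tau = 0.9 / (Lip / 2.0 + sigma)
    W = np.zeros((n, n))
    V = np.zeros((n, n))
    for _ in range(n_iter):
        grad = 2.0 * (G @ W - G)
        W_new = _soft(W - tau * (grad + V), tau * lam1)
        if zero_diagonal:
            np.fill_diagonal(W_new, 0.0)
        P = V + sigma * (2.0 * W_new - W)
        V = P - sigma * _svt(P / sigma, lam2 / sigma)
        W = W_new
    return W


def qp_wstep(A: np.ndarray, Fdist: np.ndarray, alpha: float, lam: float) -> np.ndarray:
    """Generic bound-constrained solve of the separable W-step QP:
    ``min_{W>=0} sum (W_ij - a_ij)^2 + (alpha/2) f_ij W_ij + lam W_ij``
    over the off-diagonal entries, via L-BFGS-B."""
    n = A.shape[0]
    mask = ~np.eye(n, dtype=bool)
    a = A[mask]
    f = Fdist[mask]

    def obj(w: np.ndarray):
        r = w - a
        g = 2.0 * r + alpha * f / 2.0 + lam
        return float(np.sum(r**2) + (alpha / 2.0) * np.sum(f * w) + lam * np.sum(w)), g

    res = minimize(
        obj,
        np.maximum(a, 0.0),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * a.size,
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
    )
    W = np.zeros((n, n))
    W[mask] = res.x
    return W


def random_sparse_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Random symmetric nonnegative sparse adjacency with zero diagonal."""
    mask = rng.random((n, n)) < p
    weights = rng.random((n, n))
    W = np.triu(mask * weights, k=1)
    return W + W.T
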