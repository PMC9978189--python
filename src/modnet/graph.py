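"""Graph Laplacian machinery for module-structured networks.

A functional brain network is a weighted undirected graph on ``n`` regions
of interest, stored as a symmetric nonnegative adjacency matrix ``W`` with a
zero diagonal.  The central spectral fact used throughout this package is
that the multiplicity of the zero eigenvalue of the graph Laplacian equals
the number of connected components (modules) of the graph; the rank
constraint in the AM-PC estimator is enforced through this identity.

Two Laplacians are supported:

* unnormalized:  ``L = D - W`` with ``D = diag(W 1)``;
* symmetric normalized:  ``L_sym = I - D^{-1/2} W D^{-1/2}``, with the
  convention ``d_i^{-1/2} = 0`` for isolated nodes (each isolated node then
  contributes a diagonal 1 and counts as its own component).

Both are symmetric positive semidefinite; the normalized spectrum lies in
``[0, 2]``, which makes an absolute zero-eigenvalue tolerance scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _csgraph_components
from scipy.spatial.distance import pdist, squareform

#: symmetry tolerance for adjacency validation
SYMMETRY_TOL = 1e-10
#: absolute tolerance below which a Laplacian eigenvalue counts as zero
ZERO_EIG_TOL = 1e-8
#: weights at or below this threshold are not edges
EDGE_TOL = 1e-10

__all__ = [
    "LaplacianSpectrum",
    "ModulePartition",
    "validate_adjacency",
    "build_laplacian",
    "spectrum",
    "count_zero_eigenvalues",
    "connected_components",
    "pairwise_rowdistance_matrix",
]


def validate_adjacency(
    W: np.ndarray,
    *,
    require_nonnegative: bool = False,
    sym_tol: float = SYMMETRY_TOL,
) -> np.ndarray:
    """Validate and return an adjacency matrix as a float array.

    Raises ``ValueError`` on non-square, non-symmetric or (when requested)
    negative input.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got shape {W.shape}")
    asym = np.max(np.abs(W - W.T)) if W.size else 0.0
    if asym > sym_tol:
        raise ValueError(f"adjacency matrix is not symmetric (max |W - W^T| = {asym:.3g})")
    if require_nonnegative and W.size and W.min() < 0:
        raise ValueError(f"adjacency matrix has negative entries (min = {W.min():.3g})")
    return W


@dataclass(frozen=True)
class LaplacianSpectrum:
    """Eigendecomposition of a graph Laplacian.

    ``eigenvalues`` are sorted ascending; ``eigenvectors`` holds the matching
    orthonormal columns.  ``normalized`` records which Laplacian was
    decomposed.  Under eigenvalue degeneracy the individual eigenvectors are
    not unique — only the spanned invariant subspaces are — so downstream
    comparisons must be subspace-based.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    normalized: bool = False


@dataclass(frozen=True)
class ModulePartition:
    """Connected-component labelling of a network.

    ``labels`` assigns each node a 0-based contiguous component id, ordered
    by first appearance; ``k_observed`` is the number of components.
    """

    labels: np.ndarray
    k_observed: int = field(default=0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        k = int(labels.max()) + 1 if labels.size else 0
        object.__setattr__(self, "k_observed", k)


def build_laplacian(W: np.ndarray, normalized: bool = False) -> np.ndarray:
    """Graph Laplacian of a symmetric nonnegative adjacency matrix.

    Unnormalized: ``L = D - W``.  Normalized: ``I - D^{-1/2} W D^{-1/2}``
    with a zero diagonal entry for zero-degree nodes (Chung's convention),
    so each isolated node contributes a zero eigenvalue and counts as its
    own connected component — keeping the multiplicity-equals-components
    theorem valid for both variants.  The result is symmetrized to remove
    round-off asymmetry.
    """
    W = validate_adjacency(W, require_nonnegative=True)
    degrees = W.sum(axis=1)
    if not normalized:
        L = np.diag(degrees) - W
    else:
        inv_sqrt = np.zeros_like(degrees)
        nz = degrees > 0
        inv_sqrt[nz] = 1.0 / np.sqrt(degrees[nz])
        L = np.diag(nz.astype(float)) - inv_sqrt[:, None] * W * inv_sqrt[None, :]
    return (L + L.T) / 2.0


def spectrum(L: np.ndarray, k: int | None = None, *, normalized: bool = False) -> LaplacianSpectrum:
    """Eigendecomposition of a symmetric PSD matrix, ascending eigenvalues.

    With ``k`` given, only the ``k`` smallest eigenpairs are returned (any
    orthonormal basis of the invariant subspace is valid under degeneracy).
    """
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        vals, vecs = scipy.linalg.eigh(L, subset_by_index=[0, k - 1])
    else:
        vals, vecs = scipy.linalg.eigh(L)
    return LaplacianSpectrum(eigenvalues=vals, eigenvectors=vecs, normalized=normalized)


def count_zero_eigenvalues(
    s: LaplacianSpectrum | np.ndarray, tol: float = ZERO_EIG_TOL
) -> int:
    """Number of (numerically) zero eigenvalues, i.e. eigenvalues below ``tol``.

    For a graph Laplacian this equals the number of connected components.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    vals = s.eigenvalues if isinstance(s, LaplacianSpectrum) else np.asarray(s, dtype=float)
    return int(np.count_nonzero(vals < tol))


def connected_components(W: np.ndarray, edge_tol: float = EDGE_TOL) -> ModulePartition:
    """Connected components of the graph whose edges have weight > ``edge_tol``.

    Labels are renumbered by order of first appearance so the output is
    deterministic regardless of the backend's internal ordering.
    """
    W = validate_adjacency(W, require_nonnegative=True)
    graph = csr_matrix((W > edge_tol).astype(np.int8))
    _, raw = _csgraph_components(graph, directed=False)
    # relabel by first appearance
    _, first_idx = np.unique(raw, return_index=True)
    order = raw[np.sort(first_idx)]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[r] for r in raw], dtype=int)
    return ModulePartition(labels=labels)


def pairwise_rowdistance_matrix(F: np.ndarray) -> np.ndarray:
    """Matrix of squared Euclidean distances between the rows of ``F``.

    Entry ``(i, j)`` is ``||f_i - f_j||^2``; symmetric with a zero diagonal.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2:
        raise ValueError("F must be a 2-d array")
    D = squareform(pdist(F, metric="sqeuclidean"))
    return D
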