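"""Functional brain network estimators.

All estimators consume a :class:`TimeSeries` — an ``m x n`` matrix of ROI
signals whose columns have been mean-centered and scaled to unit Euclidean
norm, so that ``X^T X`` is exactly the sample Pearson correlation matrix
``A``.  Five estimators are provided:

* ``pearson_network``        — the full correlation network ``W = A``;
* ``remove_negative_edges``  — the "+" variants (negative edges zeroed);
* ``sparse_pc_network``      — l1-regularized estimation,
  ``min ||X - XW||_F^2 + λ||W||_1`` (regression form) or the
  soft-thresholded-correlation form ``min ||W - A||_F^2 + λ||W||_1``;
* ``mpc_network``            — sparse + low-rank (trace-norm) estimation,
  ``min ||X - XW||_F^2 + λ1||W||_1 + λ2||W||_*``, solved by ADMM;
* ``ampc_estimate``          — the accurate-module estimator: a sparse,
  nonnegative network whose graph Laplacian has exactly ``k`` zero
  eigenvalues, so the network has exactly ``k`` connected components.

The AM-PC model is

    min_{W >= 0}  ||W - A||_F^2 + λ Σ_ij W_ij    s.t.  rank(L_W) = n - k,

relaxed via the Ky Fan theorem (the sum of the k smallest eigenvalues of
``L_W`` equals ``min_{F^T F = I} Tr(F^T L_W F)``) to the joint problem

    min_{W >= 0, F^T F = I}  ||W - A||_F^2 + α Tr(F^T L_W F) + λ Σ_ij W_ij,

solved by alternating a spectral F-step with a closed-form W-step, while
the rank-penalty weight α is adapted (doubled / halved) until the Laplacian
has exactly k zero eigenvalues.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .graph import (
    ZERO_EIG_TOL,
    build_laplacian,
    connected_components,
    count_zero_eigenvalues,
    pairwise_rowdistance_matrix,
    spectrum,
    validate_adjacency,
)

__all__ = [
    "TimeSeries",
    "AmpcConfig",
    "AmpcIteration",
    "AmpcResult",
    "pearson_network",
    "remove_negative_edges",
    "sparse_pc_network",
    "sparse_pc_objective",
    "mpc_network",
    "mpc_objective",
    "ampc_update_F",
    "ampc_update_W",
    "ampc_objective",
    "ampc_estimate",
    "estimate_network",
    "ESTIMATOR_NAMES",
]


class ConstantColumnError(ValueError):
    """A zero-variance ROI column was encountered during standardization."""


@dataclass(frozen=True)
class TimeSeries:
    """One scan's ROI signals, column-standardized.

    ``data`` is ``m x n`` (time points x ROIs) with each column mean-centered
    and scaled to unit Euclidean norm, so ``data.T @ data`` has unit diagonal
    and off-diagonal entries equal to pairwise Pearson correlations.
    """

    data: np.ndarray
    roi_names: tuple[str, ...]

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_raw(
        cls,
        raw: np.ndarray,
        roi_names: list[str] | tuple[str, ...] | None = None,
        *,
        on_constant: str = "error",
    ) -> "TimeSeries":
        """Standardize a raw ``m x n`` signal matrix.

        ``on_constant`` controls zero-variance columns: ``"error"`` raises
        :class:`ConstantColumnError` naming the ROI; ``"drop"`` removes the
        column (and its name) with a warning.
        """
        raw = np.asarray(raw, dtype=float)
        if raw.ndim != 2:
            raise ValueError("time-series matrix must be 2-d (time points x ROIs)")
        m, n = raw.shape
        if m < 2 or n < 2:
            raise ValueError(f"need at least 2 time points and 2 ROIs, got {m} x {n}")
        if roi_names is None:
            roi_names = [f"ROI{i + 1}" for i in range(n)]
        if len(roi_names) != n:
            raise ValueError(f"{len(roi_names)} ROI names for {n} columns")
        centered = raw - raw.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(centered, axis=0)
        constant = norms < 1e-12 * math.sqrt(m)
        if constant.any():
            bad = [roi_names[i] for i in np.flatnonzero(constant)]
            if on_constant == "drop":
                warnings.warn(f"dropping constant ROI column(s): {', '.join(bad)}")
                keep = ~constant
                centered = centered[:, keep]
                norms = norms[keep]
                roi_names = [nm for nm, k in zip(roi_names, keep) if k]
                if centered.shape[1] < 2:
                    raise ConstantColumnError("fewer than 2 non-constant ROI columns remain")
            else:
                raise ConstantColumnError(
                    f"constant (zero-variance) ROI column(s): {', '.join(bad)}"
                )
        data = centered / norms
        return cls(data=data, roi_names=tuple(roi_names))

    def correlation(self) -> np.ndarray:
        """Sample Pearson correlation matrix ``A = X^T X`` (unit diagonal)."""
        A = self.data.T @ self.data
        A = np.clip((A + A.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(A, 1.0)
        return A


def _finalize(W: np.ndarray) -> np.ndarray:
    """Symmetrize and zero the diagonal (estimator output convention)."""
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W


def pearson_network(ts: TimeSeries) -> np.ndarray:
    """Full Pearson correlation network: ``W = X^T X`` with zero diagonal."""
    return _finalize(ts.correlation())


def remove_negative_edges(W: np.ndarray) -> np.ndarray:
    """Elementwise ``max(W, 0)`` — the "+" variant of any estimator."""
    W = validate_adjacency(W)
    return _finalize(np.maximum(W, 0.0))


# ---------------------------------------------------------------------------
# l1-regularized estimation (regression form and soft-threshold variant)
# ---------------------------------------------------------------------------


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def sparse_pc_network(
    ts: TimeSeries,
    lam: float,
    *,
    variant: str = "regression",
    max_iter: int = 100_000,
    tol: float = 1e-12,
) -> np.ndarray:
    """l1-regularized network estimation.

    ``variant="regression"`` solves ``min_W ||X - XW||_F^2 + λ||W||_1`` with
    the diagonal constrained to zero, column by column (an l1-penalized
    least-squares problem per ROI), then symmetrizes ``(W + W^T)/2``.

    ``variant="soft-threshold"`` solves ``min_W ||W - X^T X||_F^2 + λ||W||_1``
    whose closed form is elementwise soft-thresholding of the correlation
    matrix at λ/2.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    X = ts.data
    m, n = X.shape
    if variant == "soft-threshold":
        return _finalize(_soft_threshold(ts.correlation(), lam / 2.0))
    if variant != "regression":
        raise ValueError(f"unknown variant {variant!r}")

    W = np.zeros((n, n))
    if lam == 0.0:
        for j in range(n):
            others = np.delete(np.arange(n), j)
            coef, *_ = np.linalg.lstsq(X[:, others], X[:, j], rcond=None)
            W[others, j] = coef
        return _finalize(W)

    from sklearn.linear_model import Lasso

    # sklearn's objective is (1/2m)||y - Xw||^2 + a||w||_1; matching
    # ||y - Xw||^2 + lam ||w||_1 requires a = lam / (2m).
    model = Lasso(
        alpha=lam / (2.0 * m),
        fit_intercept=False,
        max_iter=max_iter,
        tol=tol,
    )
    for j in range(n):
        others = np.delete(np.arange(n), j)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[:, others], X[:, j])
        W[others, j] = model.coef_
    return _finalize(W)


def sparse_pc_objective(ts: TimeSeries, W: np.ndarray, lam: float) -> float:
    """Objective ``||X - XW||_F^2 + λ||W||_1`` at ``W``."""
    X = ts.data
    return float(np.sum((X - X @ W) ** 2) + lam * np.sum(np.abs(W)))


# ---------------------------------------------------------------------------
# Sparse + low-rank (trace-norm) estimation via ADMM
# ---------------------------------------------------------------------------


def _svd_shrink(M: np.ndarray, t: float) -> np.ndarray:
    """Proximal operator of ``t ||.||_*``: singular-value soft-thresholding."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - t, 0.0)
    return (U * s) @ Vt


def mpc_network(
    ts: TimeSeries,
    lam1: float,
    lam2: float,
    *,
    rho: float = 1.0,
    max_iter: int = 5000,
    tol: float = 1e-9,
    constrain_diagonal: bool = True,
) -> np.ndarray:
    """Sparse + low-rank network: ``min ||X - XW||_F^2 + λ1||W||_1 + λ2||W||_*``.

    Solved by consensus ADMM with two splitting variables, one absorbing the
    l1 term (together with the zero-diagonal constraint) and one the
    trace-norm term; each has a closed-form proximal step (soft-threshold,
    singular-value shrinkage).  The quadratic W-update is solved exactly via
    a cached eigendecomposition of the Gram matrix ``X^T X``.

    ``constrain_diagonal=False`` disables the zero-diagonal constraint
    (useful for checking degenerate cases; without it and with no penalties
    the minimizer of a square invertible design is the identity).
    """
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be nonnegative")
    X = ts.data
    n = X.shape[1]
    G = X.T @ X
    # W-update solves (2G + 2 rho I) W = 2G + rho (Z1 - U1 + Z2 - U2)
    gvals, gvecs = scipy.linalg.eigh(G)
    inv = 1.0 / (2.0 * gvals + 2.0 * rho)

    def w_solve(rhs: np.ndarray) -> np.ndarray:
        return gvecs @ (inv[:, None] * (gvecs.T @ rhs))

    W = np.zeros((n, n))
    Z1 = np.zeros_like(W)
    Z2 = np.zeros_like(W)
    U1 = np.zeros_like(W)
    U2 = np.zeros_like(W)
    for _ in range(max_iter):
        W = w_solve(2.0 * G + rho * (Z1 - U1 + Z2 - U2))
        Z1_new = _soft_threshold(W + U1, lam1 / rho)
        if constrain_diagonal:
            np.fill_diagonal(Z1_new, 0.0)
        Z2_new = _svd_shrink(W + U2, lam2 / rho)
        dual = rho * math.sqrt(
            np.sum((Z1_new - Z1) ** 2) + np.sum((Z2_new - Z2) ** 2)
        )
        Z1, Z2 = Z1_new, Z2_new
        U1 += W - Z1
        U2 += W - Z2
        primal = math.sqrt(np.sum((W - Z1) ** 2) + np.sum((W - Z2) ** 2))
        if primal < tol * max(1.0, np.linalg.norm(W)) and dual < tol * max(
            1.0, np.linalg.norm(W)
        ):
            break
    out = (Z1 + Z2) / 2.0
    if constrain_diagonal:
        return _finalize(out)
    return (out + out.T) / 2.0


def mpc_objective(ts: TimeSeries, W: np.ndarray, lam1: float, lam2: float) -> float:
    """Objective ``||X - XW||_F^2 + λ1||W||_1 + λ2||W||_*`` at ``W``."""
    X = ts.data
    nuc = float(np.sum(np.linalg.svd(W, compute_uv=False)))
    return float(np.sum((X - X @ W) ** 2) + lam1 * np.sum(np.abs(W)) + lam2 * nuc)


# ---------------------------------------------------------------------------
# AM-PC: accurate-module estimation by constrained Laplacian rank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmpcConfig:
    """Configuration of the AM-PC solver.

    Parameters
    ----------
    k : target module (connected-component) count; default 8, the usual
        prior for resting-state networks.
    lam : sparsity weight λ >= 0 on the edge-weight sum.
    alpha0 : initial rank-penalty weight α; adapted by the x2 / ÷2 schedule.
    max_outer_iters : cap on alternating iterations.
    obj_rtol : relative objective-change tolerance for convergence (applies
        once the zero-eigenvalue count hits k at an unchanged α).
    normalized_laplacian : use the symmetric normalized Laplacian for the
        F-step and the zero-eigenvalue count (default), which keeps isolated
        low-degree ROIs from being split off spuriously and makes the
        eigenvalue tolerance scale-free.
    zero_eig_tol : absolute eigenvalue threshold for the rank count.
    """

    k: int = 8
    lam: float = 0.0
    alpha0: float = 0.1
    max_outer_iters: int = 50
    obj_rtol: float = 1e-6
    normalized_laplacian: bool = True
    zero_eig_tol: float = ZERO_EIG_TOL

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.max_outer_iters < 1:
            raise ValueError("max_outer_iters must be >= 1")


@dataclass(frozen=True)
class AmpcIteration:
    """Diagnostics for one outer iteration at a fixed α.

    ``obj_before`` is the joint objective at the incoming (W, F) pair,
    ``obj_after_F`` after the spectral F-step, ``obj_after_W`` after the
    closed-form W-step — each evaluated at this iteration's α and (for the
    normalized variant) this iteration's degree scaling, so the chain
    ``obj_before >= obj_after_F >= obj_after_W`` is an exact guarantee of
    the alternating minimization.
    """

    alpha: float
    n_zero_eigenvalues: int
    obj_before: float
    obj_after_F: float
    obj_after_W: float
    n_edges: int


@dataclass(frozen=True)
class AmpcResult:
    """Output of :func:`ampc_estimate`."""

    W: np.ndarray
    F: np.ndarray
    alpha_final: float
    iterations: tuple[AmpcIteration, ...]
    k_observed: int
    converged: bool

    @property
    def objective_trace(self) -> list[float]:
        """Flat per-half-step objective values (after-F, after-W per iteration)."""
        out: list[float] = []
        for it in self.iterations:
            out.extend([it.obj_after_F, it.obj_after_W])
        return out


def ampc_update_F(W: np.ndarray, k: int, normalized: bool = True) -> np.ndarray:
    """F-step: the ``k`` smallest-eigenvalue eigenvectors of the Laplacian.

    By the Ky Fan theorem these minimize ``Tr(F^T L_W F)`` over orthonormal
    ``n x k`` matrices, and the attained value is the sum of the k smallest
    eigenvalues.
    """
    W = validate_adjacency(W, require_nonnegative=True)
    n = W.shape[0]
    if k >= n:
        raise ValueError(f"k must be < n = {n}, got {k}")
    L = build_laplacian(W, normalized=normalized)
    return spectrum(L, k=k, normalized=normalized).eigenvectors


def ampc_update_W(
    A: np.ndarray, Fdist: np.ndarray, alpha: float, lam: float
) -> np.ndarray:
    """W-step: closed-form minimizer of the separable nonnegative QP.

    Minimizes ``Σ_ij [(W_ij - a_ij)^2 + (α/2) f_ij W_ij + λ W_ij]`` over
    ``W >= 0``; stationarity of each scalar quadratic gives
    ``W_ij = max(0, a_ij - α f_ij / 4 - λ / 2)``.  The diagonal is zeroed.
    """
    A = np.asarray(A, dtype=float)
    Fdist = np.asarray(Fdist, dtype=float)
    if A.shape != Fdist.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"shape mismatch: A {A.shape}, Fdist {Fdist.shape}")
    if alpha < 0 or lam < 0:
        raise ValueError("alpha and lam must be nonnegative")
    W = np.maximum(A - alpha * Fdist / 4.0 - lam / 2.0, 0.0)
    return _finalize(W)


def ampc_objective(
    W: np.ndarray, A: np.ndarray, Fdist: np.ndarray, alpha: float, lam: float
) -> float:
    """Joint objective ``||W - A||_F^2 + (α/2) Σ f_ij W_ij + λ Σ W_ij``.

    ``(1/2) Σ_ij f_ij W_ij`` equals ``Tr(F^T L_W F)`` when ``f_ij`` is the
    squared row distance of the (degree-rescaled, for the normalized
    Laplacian) embedding, so this is the Ky Fan relaxation objective.
    """
    return float(
        np.sum((W - A) ** 2) + (alpha / 2.0) * np.sum(Fdist * W) + lam * np.sum(W)
    )


def _embedding_distances(F: np.ndarray, W: np.ndarray, normalized: bool) -> np.ndarray:
    """Squared row distances of the spectral embedding.

    For the normalized Laplacian the rows are rescaled by ``1/sqrt(d_i)``
    with degrees taken from the current ``W``, which makes
    ``(1/2) Σ f_ij W_ij = Tr(F^T L_sym F)`` exact at this ``W``; the same
    (now lagged) distances are kept fixed through the following W-step so
    the subproblem stays separable with a closed form.
    """
    if normalized:
        d = W.sum(axis=1)
        scale = np.zeros_like(d)
        nz = d > 0
        scale[nz] = 1.0 / np.sqrt(d[nz])
        F = F * scale[:, None]
    return pairwise_rowdistance_matrix(F)


def ampc_estimate(ts: TimeSeries, cfg: AmpcConfig | None = None) -> AmpcResult:
    """Estimate a network with exactly ``cfg.k`` modules by alternating
    minimization with α adaptation.

    Starting from the clipped correlation network ``W0 = max(X^T X, 0)``
    (diagonal zeroed), each outer iteration runs the spectral F-step and the
    closed-form W-step, then counts the zero eigenvalues ``z`` of the new
    Laplacian and adapts α: doubled if ``z < k`` (rank penalty too weak),
    halved if ``z > k`` (too many components), held if ``z == k``.  The
    solver stops when ``z == k`` and the objective change at an unchanged α
    falls below ``obj_rtol`` relative, or at ``max_outer_iters``; failure to
    reach ``z == k`` is reported via ``converged=False``, never raised.
    """
    if cfg is None:
        cfg = AmpcConfig()
    A = ts.correlation()
    n = A.shape[0]
    if n < cfg.k + 1:
        raise ValueError(f"need n >= k + 1 ROIs (n = {n}, k = {cfg.k})")

    W = np.maximum(A, 0.0)
    np.fill_diagonal(W, 0.0)
    alpha = float(cfg.alpha0)
    F_prev: np.ndarray | None = None
    iters: list[AmpcIteration] = []
    prev_obj: float | None = None  # objective at previous iteration's alpha
    prev_alpha: float | None = None
    converged = False
    F = np.zeros((n, cfg.k))

    for _ in range(cfg.max_outer_iters):
        L = build_laplacian(W, normalized=cfg.normalized_laplacian)
        spec = spectrum(L, normalized=cfg.normalized_laplacian)
        F = spec.eigenvectors[:, : cfg.k]
        fdist = _embedding_distances(F, W, cfg.normalized_laplacian)
        if F_prev is not None:
            fdist_prev = _embedding_distances(F_prev, W, cfg.normalized_laplacian)
            obj_before = ampc_objective(W, A, fdist_prev, alpha, cfg.lam)
        else:
            obj_before = ampc_objective(W, A, fdist, alpha, cfg.lam)
        obj_after_F = ampc_objective(W, A, fdist, alpha, cfg.lam)
        W = ampc_update_W(A, fdist, alpha, cfg.lam)
        obj_after_W = ampc_objective(W, A, fdist, alpha, cfg.lam)
        F_prev = F

        L_new = build_laplacian(W, normalized=cfg.normalized_laplacian)
        z = count_zero_eigenvalues(
            spectrum(L_new, normalized=cfg.normalized_laplacian), tol=cfg.zero_eig_tol
        )
        iters.append(
            AmpcIteration(
                alpha=alpha,
                n_zero_eigenvalues=z,
                obj_before=obj_before,
                obj_after_F=obj_after_F,
                obj_after_W=obj_after_W,
                n_edges=int(np.count_nonzero(np.triu(W, 1))),
            )
        )
        if z == cfg.k:
            if (
                prev_obj is not None
                and prev_alpha == alpha
                and abs(obj_after_W - prev_obj) <= cfg.obj_rtol * max(abs(prev_obj), 1.0)
            ):
                converged = True
                prev_obj, prev_alpha = obj_after_W, alpha
                break
        # record at the alpha actually used, then adapt
        prev_obj, prev_alpha = obj_after_W, alpha
        if z < cfg.k:
            alpha *= 2.0
        elif z > cfg.k:
            alpha /= 2.0

    part = connected_components(W)
    return AmpcResult(
        W=W,
        F=F,
        alpha_final=alpha,
        iterations=tuple(iters),
        k_observed=part.k_observed,
        converged=converged and part.k_observed == cfg.k,
    )


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

ESTIMATOR_NAMES = ("pc", "pc+", "sparse-pc", "sparse-pc+", "m-pc", "m-pc+", "am-pc")


def estimate_network(ts: TimeSeries, method: str, **params) -> np.ndarray:
    """Estimate a network by name.

    ``method`` is one of ``pc``, ``pc+``, ``sparse-pc``, ``sparse-pc+``,
    ``m-pc``, ``m-pc+``, ``am-pc``; a trailing ``+`` applies
    :func:`remove_negative_edges` to the base estimate.  AM-PC parameters
    are passed through to :class:`AmpcConfig`.
    """
    method = method.lower()
    if method not in ESTIMATOR_NAMES:
        raise ValueError(f"unknown method {method!r}; choose from {ESTIMATOR_NAMES}")
    plus = method.endswith("+")
    base = method.rstrip("+")
    if base == "pc":
        W = pearson_network(ts)
    elif base == "sparse-pc":
        W = sparse_pc_network(ts, lam=params.pop("lam", 0.0), **params)
    elif base == "m-pc":
        W = mpc_network(
            ts, lam1=params.pop("lam1", 0.0), lam2=params.pop("lam2", 0.0), **params
        )
    else:  # am-pc
        return ampc_estimate(ts, AmpcConfig(**params)).W
    return remove_negative_edges(W) if plus else W
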