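"""Nonnegative matrix factorization of connectivity matrices and dual
regression of a group decomposition to subject level.

Conventions
-----------
The connectivity matrix ``V`` is vertices x voxels. Internally we
factorize ``M = V.T`` (voxels x vertices) as ``M ~ W @ H`` with

* ``W`` — white-matter factor, voxels x K,
* ``H`` — gray-matter factor, K x vertices,

both elementwise nonnegative. After fitting, each column of ``W`` is
rescaled to unit L2 norm with the compensating scale absorbed into the
matching row of ``H``; this fixes the scale ambiguity of NMF so that
screening products and reconstructions are reproducible (the OBI itself
is scale-invariant). The permutation ambiguity is left to callers, who
match components by correlation, never by index.

The solver minimizes the squared Frobenius reconstruction error by
hierarchical alternating least squares (HALS): each factor column/row is
updated to its exact nonnegative least-squares minimizer in turn, so the
objective never increases. Initialization is nonnegative double SVD
(NNDSVDa) with a tiny seed-controlled perturbation, making runs
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse.linalg as spla
from scipy.optimize import nnls

from .errors import DomainError, InvalidSpecError, UndefinedStatisticError
from .synthetic import ConnectivityMatrix

_EPS = 1e-12


@dataclass
class Decomposition:
    W: np.ndarray  # (n_voxels, K)
    H: np.ndarray  # (K, n_vertices)
    K: int
    objective_trace: np.ndarray  # Frobenius loss per iteration
    seed: int
    converged: bool


@dataclass
class SubjectDecomposition:
    subject_id: str
    W_s: np.ndarray
    H_s: np.ndarray
    parent_group_seed: int
    degenerate: bool = False


def _as_values(V) -> np.ndarray:
    if isinstance(V, ConnectivityMatrix):
        return V.values
    return np.asarray(V, dtype=float)


def _truncated_svd(M: np.ndarray, K: int, rng: np.random.Generator):
    """Leading K singular triplets, deterministic for a fixed rng."""
    if K >= min(M.shape) - 1:
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        return u[:, :K], s[:K], vt[:K]
    v0 = rng.standard_normal(min(M.shape))
    u, s, vt = spla.svds(M, k=K, v0=v0)
    order = np.argsort(s)[::-1]
    return u[:, order], s[order], vt[order]


def _nndsvd_init(M: np.ndarray, K: int, rng: np.random.Generator):
    """NNDSVDa: nonnegative parts of SVD factors, zeros filled with the
    matrix mean / 100, plus a tiny seeded perturbation for tie-breaking."""
    u, s, vt = _truncated_svd(M, K, rng)
    W = np.zeros((M.shape[0], K))
    H = np.zeros((K, M.shape[1]))
    W[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    H[0] = np.sqrt(s[0]) * np.abs(vt[0])
    for j in range(1, K):
        x, y = u[:, j], vt[j]
        xp, xn = np.clip(x, 0, None), np.clip(-x, 0, None)
        yp, yn = np.clip(y, 0, None), np.clip(-y, 0, None)
        mp, mn = np.linalg.norm(xp) * np.linalg.norm(yp), \
            np.linalg.norm(xn) * np.linalg.norm(yn)
        if mp >= mn:
            xs, ys, m = xp, yp, mp
        else:
            xs, ys, m = xn, yn, mn
        if m > 0:
            scale = np.sqrt(s[j] * m)
            W[:, j] = scale * xs / np.linalg.norm(xs)
            H[j] = scale * ys / np.linalg.norm(ys)
    fill = M.mean() / 100.0 + _EPS
    W[W <= 0] = fill
    H[H <= 0] = fill
    jitter = 1e-6 * fill
    W += rng.uniform(0, jitter, size=W.shape)
    H += rng.uniform(0, jitter, size=H.shape)
    return W, H


def _normalize_unit_w(W: np.ndarray, H: np.ndarray):
    norms = np.linalg.norm(W, axis=0)
    nz = norms > 0
    W = W.copy()
    H = H.copy()
    W[:, nz] /= norms[nz]
    H[nz] *= norms[nz, None]
    return W, H


def fit_group_nmf(V_avg, K: int, seed: int = 0, tol: float = 1e-6,
                  max_iter: int = 500) -> Decomposition:
    """Factorize a (group-averaged) connectivity matrix.

    Parameters
    ----------
    V_avg : array or ConnectivityMatrix, vertices x voxels, nonnegative.
    K : number of components, ``1 <= K <= min(V_avg.shape)``.
    tol : stop when the relative objective change per iteration falls
        below this.
    """
    V = _as_values(V_avg)
    if V.ndim != 2:
        raise InvalidSpecError("V_avg must be a 2-D matrix")
    if V.size and V.min() < 0:
        raise DomainError("NMF input must be elementwise nonnegative")
    if not 1 <= K <= min(V.shape):
        raise InvalidSpecError(
            f"K={K} outside [1, min(shape)={min(V.shape)}]")
    M = V.T  # voxels x vertices
    rng = np.random.default_rng(seed)
    W, H = _nndsvd_init(M, K, rng)

    trace = [float(np.linalg.norm(M - W @ H))]
    converged = False
    for _ in range(max_iter):
        # HALS sweep: exact nonnegative minimizer per factor column/row,
        # so each block update (and hence the sweep) never increases the
        # objective.
        WtW = W.T @ W
        WtM = W.T @ M
        for k in range(K):
            if WtW[k, k] > 0:
                h = H[k] + (WtM[k] - WtW[k] @ H) / WtW[k, k]
                H[k] = np.maximum(h, 0.0)
        HHt = H @ H.T
        MHt = M @ H.T
        for k in range(K):
            if HHt[k, k] > 0:
                w = W[:, k] + (MHt[:, k] - W @ HHt[:, k]) / HHt[k, k]
                W[:, k] = np.maximum(w, 0.0)
        obj = float(np.linalg.norm(M - W @ H))
        trace.append(obj)
        # improvement measured against the initial objective, so the
        # criterion remains meaningful as the loss approaches zero
        ref = trace[0]
        if ref == 0 or abs(trace[-2] - obj) / ref < tol:
            converged = True
            break
    W, H = _normalize_unit_w(W, H)
    return Decomposition(W=W, H=H, K=K, objective_trace=np.array(trace),
                         seed=seed, converged=converged)


def _nnls_fixed_design(D: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve ``min_{X >= 0} ||D @ X - B||_F`` columnwise.

    The design ``D`` (m x K, K small) is shared by every column, so the
    problem is reduced through the Gram matrix to K x K nonnegative least
    squares per column: with ``G = D'D = R'R`` (Cholesky),
    ``||Dx - b||^2 = ||Rx - R^{-T} D'b||^2 + const``.
    """
    m, K = D.shape
    G = D.T @ D
    # ridge keeps the Cholesky defined when a component column is zero
    ridge = 1e-12 * max(float(np.trace(G)) / K, 1.0)
    R = sla.cholesky(G + ridge * np.eye(K), lower=False)
    C = sla.solve_triangular(R, D.T @ B, trans="T", lower=False)
    X = np.empty((K, B.shape[1]))
    for j in range(B.shape[1]):
        X[:, j], _ = nnls(R, C[:, j])
    return X


def dual_regress(V_subject, group: Decomposition) -> SubjectDecomposition:
    """Project a group decomposition onto one subject's matrix.

    Two stages of exact nonnegative least squares: (1) with the group
    gray factor ``H`` fixed, solve for the subject white factor ``W_s``;
    (2) with ``W_s`` fixed, solve for the subject gray factor ``H_s``.
    The result is normalized like the group factors (unit-L2 ``W_s``
    columns, scale absorbed into ``H_s``).

    An all-zero subject matrix yields zero factors flagged ``degenerate``
    rather than an exception.
    """
    V = _as_values(V_subject)
    subject_id = getattr(V_subject, "subject_id", "")
    M = V.T
    n_vox, n_vert = M.shape
    if group.W.shape[0] != n_vox or group.H.shape[1] != n_vert:
        raise InvalidSpecError("subject matrix does not conform to the "
                               "group decomposition's geometry")
    if not M.any():
        z = SubjectDecomposition(subject_id, np.zeros_like(group.W),
                                 np.zeros_like(group.H), group.seed,
                                 degenerate=True)
        return z
    # stage 1: rows of W_s from design H^T
    W_s = _nnls_fixed_design(group.H.T, M.T).T  # (n_vox, K)
    # stage 2: columns of H_s from design W_s
    H_s = _nnls_fixed_design(W_s, M)  # (K, n_vert)
    W_s, H_s = _normalize_unit_w(W_s, H_s)
    return SubjectDecomposition(subject_id, W_s, H_s, group.seed)


def reconstruction_error(V, W: np.ndarray, H: np.ndarray) -> float:
    """Relative Frobenius reconstruction error ``||V.T - W H|| / ||V||``."""
    Vv = _as_values(V)
    denom = np.linalg.norm(Vv)
    if denom == 0:
        raise UndefinedStatisticError(
            "reconstruction error undefined for an all-zero matrix")
    return float(np.linalg.norm(Vv.T - W @ H) / denom)
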