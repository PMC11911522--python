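"""Fast combinatorial non-negative least squares.

Solves ``min_{X >= 0} ||A X - B||_F`` for many right-hand sides at once by
grouping columns that share a passive (unconstrained) variable set and
solving each group with a single normal-equations factorization
(van Benthem & Keenan-style active-set batching).  With the small numbers
of components used in deconvolution (K of order ten) the number of
distinct passive sets is tiny, so thousands of right-hand sides cost
little more than one.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

__all__ = ["fcnnls", "fcnnls_gram"]


def _cssls(AtA: np.ndarray, AtB: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Least squares restricted to the passive sets in boolean matrix P."""
    K, n = AtB.shape
    X = np.zeros((K, n))
    codes = (P.astype(np.uint64) * (1 << np.arange(K, dtype=np.uint64))[:, None]).sum(axis=0)
    for code in np.unique(codes):
        cols = np.nonzero(codes == code)[0]
        mask = P[:, cols[0]]
        if not mask.any():
            continue
        sub = AtA[np.ix_(mask, mask)]
        rhs = AtB[np.ix_(mask, cols)]
        try:
            sol = np.linalg.solve(sub, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(sub, rhs, rcond=None)[0]
        X[np.ix_(mask, cols)] = sol
    return X


def fcnnls_gram(AtA: np.ndarray, AtB: np.ndarray,
                tol: float | None = None) -> np.ndarray:
    """Batched NNLS given the Gram matrix ``A'A`` and products ``A'B``."""
    AtA = np.asarray(AtA, dtype=float)
    AtB = np.asarray(AtB, dtype=float)
    K, n = AtB.shape
    if tol is None:
        tol = 10 * np.finfo(float).eps * max(np.abs(AtA).max(), 1.0) * K

    # unconstrained start, clip to feasibility
    try:
        X = np.linalg.solve(AtA, AtB)
    except np.linalg.LinAlgError:
        X = np.linalg.lstsq(AtA, AtB, rcond=None)[0]
    P = X > 0
    X[~P] = 0.0

    # every column starts unverified; most are settled in one pass
    todo = np.arange(n)
    max_outer = 3 * K + 10
    for _ in range(max_outer):
        if todo.size == 0:
            break
        X[:, todo] = _cssls(AtA, AtB[:, todo], P[:, todo])

        # restore feasibility: drop the most negative passive variable
        for _inner in range(3 * K + 10):
            neg = (X[:, todo] < -tol) & P[:, todo]
            bad = np.nonzero(neg.any(axis=0))[0]
            if bad.size == 0:
                break
            cols = todo[bad]
            vals = np.where(P[:, cols] & (X[:, cols] < -tol),
                            X[:, cols], np.inf)
            drop = np.argmin(vals, axis=0)
            P[drop, cols] = False
            X[:, cols] = _cssls(AtA, AtB[:, cols], P[:, cols])
        X[:, todo] = np.maximum(X[:, todo], 0.0)

        # optimality: bring in active variables with positive gradient
        W = AtB[:, todo] - AtA @ X[:, todo]
        W = np.where(P[:, todo], -np.inf, W)
        improvable = np.nonzero(W.max(axis=0) > tol)[0]
        if improvable.size == 0:
            todo = np.array([], dtype=int)
            break
        cols = todo[improvable]
        add = np.argmax(W[:, improvable], axis=0)
        P[add, cols] = True
        todo = cols
    else:
        # rare cycling: fall back to the reference solver per column
        for j in todo:
            # reconstruct a design from the Gram matrix via Cholesky-like
            # symmetric square root; AtA is PSD
            w, V = np.linalg.eigh(AtA)
            w = np.clip(w, 0, None)
            Ahalf = V @ np.diag(np.sqrt(w)) @ V.T
            b = np.linalg.pinv(Ahalf) @ AtB[:, j]
            X[:, j], _ = _scipy_nnls(Ahalf, b)
    return X


def fcnnls(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve ``min_{X>=0} ||A X - B||_F`` columnwise for all columns of B.

    Parameters
    ----------
    A : (m, K) design matrix
    B : (m, n) right-hand sides

    Returns
    -------
    X : (K, n) non-negative coefficient matrix
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    return fcnnls_gram(A.T @ A, A.T @ B)
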