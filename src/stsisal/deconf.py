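"""Alternating constrained least-squares factorization ("deconf").

Factors a genes x spots matrix as ``Y ~ M @ H`` with non-negative
per-type profiles ``M`` (L x K) and a non-negative, column-stochastic
proportion matrix ``H`` (K x S): every spot's proportions sum to one.

The solver alternates two exact non-negative least-squares updates:

* ``H`` columns are fit by NNLS with a heavily weighted sum-to-one row
  appended to the design, then projected onto the simplex by clipping at
  zero and renormalizing;
* ``M`` rows are fit by plain NNLS given ``H``.

Iterations stop when the Frobenius residual drops below ``tol_a``, when
the iteration cap is reached, or when the residual stalls (an iteration
that would increase the residual is discarded, so the recorded error
trace is non-increasing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nnls import fcnnls

logger = logging.getLogger(__name__)

__all__ = ["FactorPair", "deconf"]

#: weight multiplier for the soft sum-to-one row in the H update
_SUM_WEIGHT = 100.0


@dataclass
class FactorPair:
    """Result of one deconf run."""

    M: np.ndarray            # (L, K) non-negative profiles
    H: np.ndarray            # (K, S) column-stochastic proportions
    n_iter: int
    frob_err: float          # ||Y - M H||_F at the returned iterate
    converged: bool
    err_trace: list[float] = field(default_factory=list)


def _values(Y) -> np.ndarray:
    return np.asarray(getattr(Y, "values", Y), dtype=float)


def euclidean_simplex_projection(V: np.ndarray) -> np.ndarray:
    """Project every column of V onto the probability simplex
    (Euclidean projection via the sorted-threshold rule)."""
    K, n = V.shape
    U = -np.sort(-V, axis=0)
    css = np.cumsum(U, axis=0) - 1.0
    idx = np.arange(1, K + 1)[:, None]
    cond = U - css / idx > 0
    rho = K - np.argmax(cond[::-1], axis=0) - 1
    theta = css[rho, np.arange(n)] / (rho + 1)
    return np.maximum(V - theta, 0.0)


def _simplex_columns(M: np.ndarray, Yv: np.ndarray,
                     projection: str = "clip") -> np.ndarray:
    """Solve min ||Y - M H|| over H >= 0 with columns (nearly) on the
    simplex: NNLS on an augmented system, then projection onto the
    simplex (clip-and-renormalize by default, exact Euclidean behind the
    ``projection="euclidean"`` flag)."""
    L, K = M.shape
    S = Yv.shape[1]
    w = _SUM_WEIGHT * (np.linalg.norm(M) / max(np.sqrt(K), 1.0) + 1e-12)
    A = np.vstack([M, np.full((1, K), w)])
    B = np.vstack([Yv, np.full((1, S), w)])
    H = fcnnls(A, B)
    if projection == "euclidean":
        return euclidean_simplex_projection(H)
    H = np.maximum(H, 0.0)
    s = H.sum(axis=0)
    dead = s <= 0
    if dead.any():
        H[:, dead] = 1.0 / K
        s = H.sum(axis=0)
    return H / s


def deconf(Y, K: int, max_iter: int = 1000, tol_a: float | None = None,
           seed: int = 0, rel_tol: float = 1e-7, projection: str = "clip",
           rng: np.random.Generator | None = None) -> FactorPair:
    """Factor ``Y ~ M H`` with ``K`` components.

    Parameters
    ----------
    Y
        :class:`~stsisal.data.ExpressionMatrix` or plain ``(L, S)`` array.
    K
        Number of cell types; must satisfy ``1 <= K < S``.
    max_iter
        Iteration cap.
    tol_a
        Absolute Frobenius-residual exit threshold; defaults to
        ``1e-6 * ||Y||_F``.
    seed
        Seeds the Dirichlet initialization of ``H``; runs are bit-identical
        under the same seed.
    rel_tol
        Stall guard: stop once the relative residual improvement per
        iteration falls below this.
    """
    Yv = _values(Y)
    L, S = Yv.shape
    if K < 1:
        raise ValueError("K must be at least 1")
    if K >= S:
        raise ValueError(f"K={K} must be smaller than the number of spots S={S}")
    normY = np.linalg.norm(Yv)
    if tol_a is None:
        tol_a = 1e-6 * normY

    if rng is None:
        rng = np.random.default_rng(seed)
    H = rng.dirichlet(np.ones(K), size=S).T  # (K, S), columns sum to 1
    M = fcnnls(H.T, Yv.T).T                  # one NNLS pass for M

    trace: list[float] = []
    prev_err = None
    M_prev = H_prev = None
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        H_new = _simplex_columns(M, Yv, projection=projection)
        # guard against rank collapse: revive all-zero proportion rows
        dead_rows = np.nonzero(H_new.sum(axis=1) == 0)[0]
        if dead_rows.size:
            logger.info("deconf: reinitializing %d collapsed H row(s)",
                        dead_rows.size)
            for r in dead_rows:
                H_new[r] = rng.dirichlet(np.ones(S)) * 0.05
            H_new = H_new / H_new.sum(axis=0)
        M_new = fcnnls(H_new.T, Yv.T).T
        err = float(np.linalg.norm(Yv - M_new @ H_new))

        if prev_err is not None and err > prev_err:
            # stalled: discard the increasing step and keep the best iterate
            M, H = M_prev, H_prev
            converged = True
            break
        M, H = M_new, H_new
        trace.append(err)
        n_iter = it
        if err <= tol_a:
            converged = True
            break
        if prev_err is not None and (prev_err - err) <= rel_tol * max(prev_err, 1e-300):
            converged = True
            break
        prev_err, M_prev, H_prev = err, M, H

    frob_err = float(np.linalg.norm(Yv - M @ H))
    return FactorPair(M=M, H=H, n_iter=n_iter, frob_err=frob_err,
                      converged=converged, err_trace=trace)
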