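"""Simplex identification via split augmented Lagrangian (SISAL).

Given N points that lie (approximately) in a (K-1)-dimensional simplex,
recover the K vertices by minimum-volume fitting with a soft
non-negativity constraint.  After projecting the data onto the best-fit
(K-1)-dimensional affine subspace and appending a constant-one
coordinate, the problem is posed on the inverse mixing matrix
``Q = M^{-1}``:

    minimize  -log|det Q| + tau * sum(hinge(Q X))

subject to the linear constraint that the barycentric coordinates
``Q X`` of every point sum to one, where ``hinge(z) = max(-z, 0)``
penalizes points that fall outside the candidate simplex.  The hinge
makes the fit robust to noise and outliers: a hard-constraint
minimum-volume fit must enclose every point, while the soft fit may
leave a few slightly outside.

Each outer step linearizes the log-determinant, solves the resulting
non-smooth convex subproblem with an ADMM splitting (the "split augmented
Lagrangian"), and backtracks along the step until the true objective
decreases, so the recorded objective trace is non-increasing.
Initialization is a vertex-component-style greedy: iteratively pick the
point farthest from the affine hull of those already chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = [
    "AffineProjection",
    "SimplexVertices",
    "affine_project",
    "sisal_fit",
    "pseudo_proportions",
]


@dataclass
class AffineProjection:
    """Orthonormal basis of the centered data subspace plus the center."""

    basis: np.ndarray   # (K-1, S), orthonormal rows
    center: np.ndarray  # (S,)

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) @ self.basis.T

    def lift(self, P: np.ndarray) -> np.ndarray:
        return np.asarray(P, dtype=float) @ self.basis + self.center


@dataclass
class SimplexVertices:
    """Fitted simplex corners and solver diagnostics."""

    vertices_projected: np.ndarray      # (K, K-1)
    Q: np.ndarray                       # (K, K) inverse mixing matrix
    tau: float
    n_iter: int
    objective_trace: list[float] = field(default_factory=list)
    vertices: np.ndarray | None = None  # (K, S) lifted to ambient space
    volume_init: float = 0.0

    @property
    def K(self) -> int:
        return self.vertices_projected.shape[0]

    @property
    def volume(self) -> float:
        """|det| of the edge matrix of the fitted simplex (up to K-1!)."""
        V = self.vertices_projected
        E = V[1:] - V[0]
        return float(abs(np.linalg.det(E)))


def affine_project(points: np.ndarray, K: int):
    """Project *points* (N x S) onto the top (K-1)-dimensional affine
    subspace of the centered cloud.

    Returns the :class:`AffineProjection` and the ``N x (K-1)`` projected
    coordinates.  Raises when the centered data have numerical rank below
    ``K - 1``.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2:
        raise ValueError("points must be 2-D (points in rows)")
    N, S = P.shape
    if K < 2:
        raise ValueError("K must be at least 2")
    center = P.mean(axis=0)
    Xc = P - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank_tol = max(N, S) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > rank_tol).sum())
    if rank < K - 1:
        raise ValueError(
            f"data do not span a (K-1)-simplex (numerical rank {rank} < "
            f"{K - 1}); reduce K"
        )
    basis = Vt[: K - 1]
    proj = Xc @ basis.T
    return AffineProjection(basis=basis, center=center), proj


def _greedy_vertex_indices(X: np.ndarray, K: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Vertex-component-style initializer: successively pick the column of
    X (K x N, last row constant one) with the largest residual after
    orthogonal projection onto the span of the picks so far."""
    Kdim, N = X.shape
    idx = np.zeros(K, dtype=int)
    # first pick: farthest from the data mean in the projected coordinates
    d0 = np.linalg.norm(X[:-1] - X[:-1].mean(axis=1, keepdims=True), axis=0)
    idx[0] = _argmax_tiebreak(d0, rng)
    B = X[:, [idx[0]]]
    for k in range(1, K):
        Qb, _ = np.linalg.qr(B)
        R = X - Qb @ (Qb.T @ X)
        d = np.linalg.norm(R, axis=0)
        d[idx[:k]] = -np.inf
        idx[k] = _argmax_tiebreak(d, rng)
        B = X[:, idx[: k + 1]]
    return idx


def _argmax_tiebreak(d: np.ndarray, rng: np.random.Generator) -> int:
    m = d.max()
    ties = np.nonzero(d >= m * (1 - 1e-12) if m > 0 else d == m)[0]
    if ties.size == 1:
        return int(ties[0])
    return int(ties[rng.integers(ties.size)])


def _objective(Q: np.ndarray, X: np.ndarray, tau: float) -> float:
    sign, logdet = np.linalg.slogdet(Q)
    if sign == 0 or not np.isfinite(logdet):
        return np.inf
    Hb = Q @ X
    return float(-logdet + tau * np.clip(-Hb, 0.0, None).sum())


def _admm_subproblem(Q0: np.ndarray, G: np.ndarray, X: np.ndarray,
                     XXt: np.ndarray, c: np.ndarray, lam: float,
                     tau: float, n_iter: int = 40,
                     rho: float = 1.0) -> np.ndarray:
    """Solve the linearized subproblem

        min_Q  <G, Q> + ||Q - Q0||_F^2 / (2 lam) + tau * hinge(Q X)
        s.t.   1' Q = c'

    by ADMM on the splitting Z = Q X."""
    K = Q0.shape[0]
    A = np.eye(K) / lam + rho * XXt
    cf = cho_factor(A)
    Ac = A @ c
    Q = Q0.copy()
    Z = np.clip(Q @ X, 0.0, None)
    U = np.zeros_like(Z)
    for _ in range(n_iter):
        # Q-step: rows decouple apart from the shared equality multiplier
        Bm = Q0 / lam - G + rho * (Z - U) @ X.T      # rows are b_i
        mu = (Bm.sum(axis=0) - Ac) / K
        Q = cho_solve(cf, (Bm - mu[None, :]).T).T
        # Z-step: hinge prox
        V = Q @ X + U
        Z = np.where(V >= 0, V, np.minimum(V + tau / rho, 0.0))
        U += Q @ X - Z
    return Q


def sisal_fit(projected: np.ndarray, K: int, tau: float = 1.0,
              max_iter: int = 100, seed: int = 0,
              admm_iters: int = 40, tol_obj: float = 1e-9,
              projection: AffineProjection | None = None) -> SimplexVertices:
    """Fit a minimum-volume K-vertex simplex to projected points.

    Parameters
    ----------
    projected
        ``(N, K-1)`` coordinates from :func:`affine_project`.
    K
        Number of vertices; requires ``N >= K``.
    tau
        Hinge weight of the soft non-negativity constraint.  Large values
        approach the hard (enclosing) minimum-volume fit; the default 1.0
        tolerates noise and outliers.
    max_iter
        Outer (linearization) iteration cap.
    seed
        Used only to break exact ties in the greedy initializer and to
        perturb restarts after a singular iterate.
    projection
        When given, the fitted vertices are also lifted back to the
        ambient space and stored in ``vertices``.
    """
    P = np.asarray(projected, dtype=float)
    if P.ndim != 2 or P.shape[1] != K - 1:
        raise ValueError(f"projected must be N x (K-1) = N x {K - 1}")
    N = P.shape[0]
    if N < K:
        raise ValueError(f"need at least K={K} points, got {N}")
    rng = np.random.default_rng(seed)

    X = np.vstack([P.T, np.ones((1, N))])  # (K, N) augmented coordinates
    XXt = X @ X.T
    c = np.zeros(K)
    c[-1] = 1.0  # 1' Q = e_K'  <=>  columns of Q X sum to one

    idx = _greedy_vertex_indices(X, K, rng)
    M0 = X[:, idx]

    last_err: Exception | None = None
    for restart in range(3):
        try:
            Q = np.linalg.inv(M0)
            if not np.all(np.isfinite(Q)):
                raise np.linalg.LinAlgError("non-finite inverse")
            result = _sisal_optimize(Q, X, XXt, c, tau, max_iter,
                                     admm_iters, tol_obj)
            Q, trace, n_iter, vol0 = result
            break
        except np.linalg.LinAlgError as exc:
            last_err = exc
            logger.warning("sisal_fit: singular iterate, restarting (%d)",
                           restart + 1)
            scale = np.abs(M0).mean() + 1e-12
            M0 = M0 + rng.normal(scale=1e-3 * scale, size=M0.shape)
    else:
        raise np.linalg.LinAlgError(
            f"sisal_fit failed after 3 restarts: {last_err}"
        )

    M = np.linalg.inv(Q)
    # the equality constraint pins the last row of M to one; renormalize
    # against round-off so each column is a proper augmented vertex
    M = M / M[-1:, :]
    order = np.argsort(-M[0, :], kind="stable")
    M = M[:, order]
    V_proj = M[:-1, :].T                       # (K, K-1)
    Q_final = np.linalg.inv(M)

    vertices = projection.lift(V_proj) if projection is not None else None
    E = V_proj[1:] - V_proj[0]
    logger.info("sisal_fit: K=%d, %d outer iterations, volume %.3e",
                K, n_iter, abs(np.linalg.det(E)))
    return SimplexVertices(
        vertices_projected=V_proj,
        Q=Q_final,
        tau=tau,
        n_iter=n_iter,
        objective_trace=trace,
        vertices=vertices,
        volume_init=vol0,
    )


def _sisal_optimize(Q, X, XXt, c, tau, max_iter, admm_iters, tol_obj):
    K = Q.shape[0]
    M_init = np.linalg.inv(Q)
    E0 = (M_init[:-1, 1:] - M_init[:-1, :1]).T
    vol0 = float(abs(np.linalg.det(E0)))

    f = _objective(Q, X, tau)
    if not np.isfinite(f):
        raise np.linalg.LinAlgError("singular initialization")
    trace = [f]
    lam = None
    n_iter = 0
    for it in range(1, max_iter + 1):
        Qinv = np.linalg.inv(Q)
        G = -Qinv.T
        if lam is None:
            gn = np.linalg.norm(G)
            lam = 0.3 * np.linalg.norm(Q) / gn if gn > 0 else 1.0
        Qc = _admm_subproblem(Q, G, X, XXt, c, lam, tau, n_iter=admm_iters)
        dQ = Qc - Q
        # backtracking line search on the true objective
        step, accepted = 1.0, False
        for _ in range(20):
            f_new = _objective(Q + step * dQ, X, tau)
            if f_new < f - 1e-12 * max(abs(f), 1.0):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            lam *= 0.5
            if lam < 1e-12:
                break
            continue
        Q = Q + step * dQ
        improvement = f - f_new
        f = f_new
        trace.append(f)
        n_iter = it
        if step == 1.0:
            lam *= 1.5
        elif step < 0.25:
            lam *= 0.5
        if improvement <= tol_obj * max(abs(f), 1.0):
            break
    return Q, trace, n_iter, vol0


def pseudo_proportions(vertices: SimplexVertices,
                       projected: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of *projected* points (N x (K-1)) with
    respect to the fitted vertices; returns a ``K x N`` matrix whose
    columns sum to one.  Small negative entries flag points outside the
    soft-constrained simplex."""
    V = vertices.vertices_projected
    K = V.shape[0]
    P = np.asarray(projected, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    if P.shape[1] != K - 1:
        raise ValueError(f"points must have {K - 1} coordinates")
    A = np.vstack([V.T, np.ones((1, K))])          # (K, K)
    if abs(np.linalg.det(A)) < 1e-12 * max(np.abs(A).max(), 1.0) ** K:
        raise ValueError("degenerate simplex: vertices are affinely dependent")
    B = np.vstack([P.T, np.ones((1, P.shape[0]))])  # (K, N)
    return np.linalg.solve(A, B)
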