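"""Proportion-recovery metrics with cell-type alignment.

Reference-free deconvolution returns cell types in arbitrary order, so
estimated and true proportion matrices are first aligned by the optimal
assignment maximizing the summed per-pair Pearson correlation of
proportion rows.  Four metrics are then reported over the aligned
matrices: RMSE, MAE (average absolute elementwise difference), the mean
per-spot Jensen-Shannon divergence (natural log, so the per-spot bound is
ln 2), and the Pearson correlation of the flattened matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import jensenshannon

__all__ = ["EvalReport", "align_types", "proportion_metrics"]


@dataclass
class EvalReport:
    rmse: float
    mae: float
    jsd: float
    pcc: float
    permutation: np.ndarray          # est row i matches true row permutation[i]
    per_spot_jsd: np.ndarray
    per_type_pcc: np.ndarray = field(default_factory=lambda: np.array([]))


def _row_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of A and every row of B."""
    K = A.shape[0]
    C = np.zeros((K, B.shape[0]))
    for i in range(K):
        for j in range(B.shape[0]):
            sa, sb = A[i].std(), B[j].std()
            C[i, j] = np.corrcoef(A[i], B[j])[0, 1] if sa > 0 and sb > 0 else 0.0
    return C


def align_types(P_est: np.ndarray, P_true: np.ndarray) -> np.ndarray:
    """Bijection est->true maximizing the summed per-pair Pearson
    correlation of proportion rows (Hungarian assignment)."""
    P_est = np.asarray(P_est, dtype=float)
    P_true = np.asarray(P_true, dtype=float)
    if P_est.shape != P_true.shape:
        raise ValueError(f"shape mismatch {P_est.shape} vs {P_true.shape}")
    C = _row_corr(P_est, P_true)
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(P_est.shape[0], dtype=int)
    perm[rows] = cols
    return perm


def _check_stochastic(P: np.ndarray, name: str) -> np.ndarray:
    colsum = P.sum(axis=0)
    if np.abs(colsum - 1).max() > 1e-6:
        warnings.warn(f"{name} columns do not sum to one; renormalizing")
        if (colsum <= 0).any():
            raise ValueError(f"{name} has a non-positive column sum")
        P = P / colsum
    return P


def proportion_metrics(P_est: np.ndarray, P_true: np.ndarray,
                       aligned: bool = False, log_base: float | None = None
                       ) -> EvalReport:
    """Compute RMSE, MAE, mean per-spot JSD and flattened PCC.

    When ``aligned`` is false the estimated rows are first matched to the
    true rows by :func:`align_types`.  ``log_base=None`` uses the natural
    log for the JSD (per-spot maximum ln 2); pass ``2`` for bits.
    """
    P_est = np.asarray(P_est, dtype=float)
    P_true = np.asarray(P_true, dtype=float)
    if P_est.shape != P_true.shape:
        raise ValueError(f"shape mismatch {P_est.shape} vs {P_true.shape}")
    K, S = P_est.shape
    P_est = _check_stochastic(P_est, "P_est")
    P_true = _check_stochastic(P_true, "P_true")

    if aligned:
        perm = np.arange(K)
        A = P_est
    else:
        perm = align_types(P_est, P_true)
        A = np.zeros_like(P_est)
        A[perm] = P_est          # row i of P_est placed at matched true row

    diff = A - P_true
    mae = float(np.abs(diff).sum() / (S * K))
    rmse = float(np.sqrt((diff ** 2).sum() / (S * K)))
    per_spot = np.array([
        jensenshannon(A[:, j], P_true[:, j], base=log_base) ** 2
        for j in range(S)
    ])
    per_spot = np.nan_to_num(per_spot, nan=0.0)  # identical columns -> 0
    a, t = A.ravel(), P_true.ravel()
    pcc = float(np.corrcoef(a, t)[0, 1]) if a.std() > 0 and t.std() > 0 else 0.0
    per_type = np.array([
        (np.corrcoef(A[k], P_true[k])[0, 1]
         if A[k].std() > 0 and P_true[k].std() > 0 else 0.0)
        for k in range(K)
    ])
    return EvalReport(rmse=rmse, mae=mae, jsd=float(per_spot.mean()),
                      pcc=pcc, permutation=perm, per_spot_jsd=per_spot,
                      per_type_pcc=per_type)
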