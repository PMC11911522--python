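"""Choosing the number of cell types by corrected AIC.

For each candidate K a deconf fit provides the sum of squared
reconstruction errors ``SSR_K = ||Y - M H||_F^2``, and the score is the
small-sample-corrected Akaike information criterion

    AIC(K) = L*S * ln(SSR_K / (L*S)) + 2 p + 2 p (p + 1) / (L*S - p - 1),

with ``p = K (L + S)`` free parameters and ``L*S`` observations.  The
selected K is the argmin; the full curve is returned so a knee can be
inspected.  To keep the scan affordable the fits run on the top
coefficient-of-variation genes, so ``L`` in the formula is the size of
that working set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .deconf import deconf
from .features import initial_features

logger = logging.getLogger(__name__)

__all__ = ["KSelection", "aic_value", "select_k"]


@dataclass
class KSelection:
    k_grid: list[int]
    aic_values: list[float]
    ssr_values: list[float]
    best_k: int
    errors: dict[int, str] = field(default_factory=dict)

    def to_table(self):
        import pandas as pd

        return pd.DataFrame({"K": self.k_grid, "SSR": self.ssr_values,
                             "AIC": self.aic_values})


def aic_value(ssr: float, K: int, L: int, S: int) -> float:
    """Corrected AIC of a rank-K fit with residual sum of squares *ssr*."""
    if ssr <= 0:
        raise ValueError("ssr must be positive (log of a non-positive "
                         "residual is undefined); the fit is degenerate")
    n = L * S
    p = K * (L + S)
    denom = n - p - 1
    if denom <= 0:
        raise ValueError(
            f"K={K} too large for matrix size: L*S - p - 1 = {denom} <= 0"
        )
    return n * np.log(ssr / n) + 2 * p + 2 * p * (p + 1) / denom


def _k_seed(seed: int, K: int, rep: int) -> int:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, K, rep, 0xA1C])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _stabilize(Yv: np.ndarray) -> np.ndarray:
    """Depth-normalize spots, then divide each gene by its estimated
    count-noise standard deviation (Pearson-residual scaling with a
    robust global quadratic overdispersion).

    The column-stochastic factorization cannot represent per-spot
    sequencing depth, and count noise grows with the mean
    (``var ~ mu + phi mu^2``), so on unscaled data extra components
    absorb depth and high-expression shot noise instead of cell types.
    Both operations are diagonal rescalings and leave the mixing rank
    untouched while flattening the noise profile; ``phi`` is the median
    of ``(var - mu) / mu^2`` over genes, robust to the minority of
    genes whose variance is dominated by signal.
    """
    colsum = Yv.sum(axis=0)
    if (colsum <= 0).any():
        raise ValueError("cannot depth-normalize a spot with zero counts")
    V = Yv / colsum * colsum.mean()
    mu = V.mean(axis=1)
    var = V.var(axis=1, ddof=1) if V.shape[1] > 1 else mu.copy()
    pos = mu > 0
    if pos.any():
        phi = float(np.median(np.clip(var[pos] - mu[pos], 0, None)
                              / mu[pos] ** 2))
    else:
        phi = 0.0
    scale = np.sqrt(mu + phi * mu ** 2)
    scale[scale <= 0] = 1.0
    return V / scale[:, None]


def select_k(Y, k_min: int = 2, k_max: int = 8, reps: int = 1,
             seed: int = 0, n_init: int = 1000,
             deconf_max_iter: int = 400, stabilize: bool = True) -> KSelection:
    """Scan ``k_min..k_max`` and pick the K with the smallest AIC.

    Per K the best (smallest) SSR over ``reps`` seeded deconf restarts is
    used.  Each K draws its restart seeds independently of the grid, so
    extending ``k_max`` leaves earlier entries unchanged.  Ties resolve
    to the smallest K.  With ``stabilize=True`` (default) the fits run on
    a depth-normalized, variance-stabilized copy of the working matrix
    (see :func:`_stabilize`); the candidate curve is returned in full so
    a knee can be inspected alongside the argmin.
    """
    if k_min < 1 or k_max < k_min:
        raise ValueError("require 1 <= k_min <= k_max")
    Yv = np.asarray(getattr(Y, "values", Y), dtype=float)
    L_all, S = Yv.shape
    genes = initial_features(Y, min(n_init, L_all))
    if hasattr(Y, "subset_genes"):
        Yw = Y.subset_genes(genes)
        Yv = Yw.values
    else:
        from .features import _subset_plain

        Yw = _subset_plain(Y, genes)
        Yv = Yw.values
    if stabilize:
        Yw = _stabilize(Yv)
        Yv = Yw
    L = Yv.shape[0]
    logger.info("select_k: scoring K=%d..%d on %d CV-ranked genes x %d spots",
                k_min, k_max, L, S)

    k_grid = list(range(k_min, k_max + 1))
    aics: list[float] = []
    ssrs: list[float] = []
    errors: dict[int, str] = {}
    for K in k_grid:
        try:
            ssr = np.inf
            for rep in range(reps):
                fp = deconf(Yw, K, max_iter=deconf_max_iter,
                            seed=_k_seed(seed, K, rep))
                ssr = min(ssr, fp.frob_err ** 2)
            aic = aic_value(ssr, K, L, S)
        except ValueError as exc:
            errors[K] = str(exc)
            ssr, aic = np.nan, np.nan
        ssrs.append(float(ssr))
        aics.append(float(aic))
    finite = [i for i, a in enumerate(aics) if np.isfinite(a)]
    if not finite:
        raise ValueError(f"no candidate K could be scored: {errors}")
    best = min(finite, key=lambda i: (aics[i], k_grid[i]))
    return KSelection(k_grid=k_grid, aic_values=aics, ssr_values=ssrs,
                      best_k=k_grid[best], errors=errors)
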