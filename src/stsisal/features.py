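"""Iterative cell-type-specific gene selection.

Deconvolution geometry degrades when it is fed thousands of genes that
carry no cell-type signal, so the pipeline works on a reduced gene list.
The list is seeded by the coefficient of variation (sd/mean across spots),
then refined: a deconf fit estimates proportions ``H``, every gene is
projected onto ``H`` by NNLS, and genes are re-ranked by a standardized
one-vs-rest contrast of their estimated per-type expression.  The union of
the per-type lists becomes the next working set, and the loop stops when
the reconstruction RMSE converges.  The final list always stays below
1,000 genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .deconf import FactorPair, deconf
from .nnls import fcnnls

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSelectionResult",
    "initial_features",
    "celltype_specific_features",
    "iterate_selection",
]

_MAX_GENES = 1000  # final list is strictly below this


@dataclass
class FeatureSelectionResult:
    genes: list[str]                      # final selected gene ids (< 1000)
    per_type_genes: list[list[str]]       # K per-type marker candidate lists
    rmse_trace: list[float]
    n_outer_iter: int
    final_factors: FactorPair
    converged: bool = False
    overlapping: bool = field(default=False)  # per-type lists share genes


def _values(Y) -> np.ndarray:
    return np.asarray(getattr(Y, "values", Y), dtype=float)


def _gene_ids(Y) -> list[str]:
    ids = getattr(Y, "gene_ids", None)
    if ids is None:
        ids = [str(i) for i in range(_values(Y).shape[0])]
    return list(ids)


def initial_features(Y, n_init: int = 1000) -> list[str]:
    """The ``n_init`` genes with the largest coefficient of variation.

    CV is the sample standard deviation over the mean across spots,
    computed on the raw (non-log) values.  Genes with zero mean cannot be
    ranked and are excluded.  Ties break by gene id.
    """
    Yv = _values(Y)
    ids = _gene_ids(Y)
    if n_init > Yv.shape[0]:
        raise ValueError(f"n_init={n_init} exceeds the {Yv.shape[0]} genes")
    mean = Yv.mean(axis=1)
    sd = Yv.std(axis=1, ddof=1) if Yv.shape[1] > 1 else np.zeros(len(ids))
    rankable = mean > 0
    if not rankable.all():
        logger.info("initial_features: excluded %d zero-mean gene(s)",
                    int((~rankable).sum()))
    cv = np.zeros(len(ids))
    cv[rankable] = sd[rankable] / mean[rankable]
    order = sorted(np.nonzero(rankable)[0],
                   key=lambda i: (-cv[i], ids[i]))
    return [ids[i] for i in order[:n_init]]


def celltype_specific_features(Y, H: np.ndarray,
                               per_type: int = 100) -> list[list[str]]:
    """Rank genes per cell type by a one-vs-rest contrast of their
    NNLS-estimated per-type expression.

    Each gene's spot vector is regressed on the proportion rows of ``H``
    (non-negative coefficients); type *k*'s score is the estimated
    expression in *k* minus the maximum over the other types, standardized
    by the per-gene residual scale.  Returns the top ``per_type`` gene ids
    for every type, ties broken by gene id.
    """
    Yv = _values(Y)
    ids = _gene_ids(Y)
    H = np.asarray(H, dtype=float)
    K, S = H.shape
    if Yv.shape[1] != S:
        raise ValueError("Y and H disagree on the number of spots")
    if np.linalg.matrix_rank(H) < K:
        raise ValueError(
            "proportion matrix H is numerically rank deficient; the fitted "
            "cell types are not separable (try more spots or a smaller K)"
        )
    coef = fcnnls(H.T, Yv.T)              # (K, L)
    resid = Yv - coef.T @ H
    scale = np.sqrt((resid ** 2).mean(axis=1)) + 1e-12
    lists: list[list[str]] = []
    for k in range(K):
        others = np.delete(coef, k, axis=0)
        contrast = (coef[k] - others.max(axis=0)) / scale
        order = sorted(range(len(ids)), key=lambda i: (-contrast[i], ids[i]))
        lists.append([ids[i] for i in order[:per_type]])
    return lists


def _round_robin_union(per_type: list[list[str]], cap: int) -> list[str]:
    """Interleave the per-type lists rank by rank, deduplicating, until
    every list is exhausted or *cap* genes are collected."""
    out: list[str] = []
    seen: set[str] = set()
    depth = max(len(lst) for lst in per_type)
    for r in range(depth):
        for lst in per_type:
            if r < len(lst) and lst[r] not in seen:
                seen.add(lst[r])
                out.append(lst[r])
                if len(out) >= cap:
                    return out
    return out


def iterate_selection(Y, K: int, n_init: int = 1000, per_type: int = 100,
                      rmse_tol: float = 1e-4, max_outer: int = 20,
                      seed: int = 0, deconf_max_iter: int = 1000,
                      tol_a: float | None = None,
                      augment: bool = False) -> FeatureSelectionResult:
    """Run the outer feature-selection loop.

    Each round restricts ``Y`` to the working gene list, fits deconf with
    ``K`` components, recomputes per-type lists from the fitted
    proportions, and replaces the working list with their (capped) union
    (with ``augment=True`` the previous list is merged in instead of
    replaced, under the same cap).  Convergence is an absolute
    difference of successive RMSE values ``||Y - MH||_F / sqrt(L' S)``
    below ``rmse_tol``.
    """
    Yv = _values(Y)
    S = Yv.shape[1]
    if K >= S:
        raise ValueError(f"K={K} must be smaller than the number of spots S={S}")
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5E1EC7])
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(max_outer)]

    genes = initial_features(Y, min(n_init, Yv.shape[0]))
    has_ids = getattr(Y, "gene_ids", None) is not None

    rmse_trace: list[float] = []
    per_lists: list[list[str]] = []
    fp: FactorPair | None = None
    converged = False
    for t in range(max_outer):
        Yt = Y.subset_genes(genes) if has_ids else _subset_plain(Y, genes)
        fp = deconf(Yt, K, max_iter=deconf_max_iter, tol_a=tol_a,
                    seed=seeds[t])
        Lp = len(genes)
        rmse = fp.frob_err / np.sqrt(Lp * S)
        rmse_trace.append(rmse)
        per_lists = celltype_specific_features(Yt, fp.H, per_type=per_type)
        if any(len(lst) == 0 for lst in per_lists):
            raise ValueError("a cell type produced an empty feature list")
        lists_for_union = per_lists + [genes] if augment else per_lists
        union = _round_robin_union(lists_for_union, _MAX_GENES - 1)
        if t > 0 and abs(rmse_trace[-1] - rmse_trace[-2]) <= rmse_tol:
            converged = True
            genes = union
            break
        genes = union
    assert fp is not None

    flat = [g for lst in per_lists for g in lst]
    overlapping = len(flat) != len(set(flat))
    return FeatureSelectionResult(
        genes=genes,
        per_type_genes=per_lists,
        rmse_trace=rmse_trace,
        n_outer_iter=len(rmse_trace),
        final_factors=fp,
        converged=converged,
        overlapping=overlapping,
    )


class _PlainView:
    """Minimal gene-id view over a bare array (internal)."""

    def __init__(self, values, gene_ids):
        self.values = values
        self.gene_ids = gene_ids


def _subset_plain(Y, genes):
    Yv = _values(Y)
    ids = _gene_ids(Y)
    pos = {g: i for i, g in enumerate(ids)}
    idx = [pos[g] for g in genes]
    return _PlainView(Yv[idx], [ids[i] for i in idx])
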