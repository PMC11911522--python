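"""End-to-end reference-free deconvolution.

After feature selection, every surviving gene is scaled to sum one across
spots.  Under the linear mixing model ``Y = M H`` this makes each gene a
convex combination of the K *row-normalized* proportion rows, so the gene
cloud lives in a (K-1)-simplex whose corners are scaled versions of the
proportion rows.  SISAL recovers those corners as the pseudo-proportion
matrix ``Hp``; a least-squares fit of ``alpha' Hp = 1'`` recovers the
per-type row scales, and ``H = diag(alpha) Hp`` (negatives clipped,
columns renormalized) is the final column-stochastic proportion matrix.
Per-type expression profiles come from rowwise non-negative least
squares, and marker genes are the genes closest to each corner in the
projected space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.naive_bayes import GaussianNB

from .data import ExpressionMatrix, filter_genes, log_normalize, row_normalize
from .features import iterate_selection
from .model_selection import select_k
from .nnls import fcnnls
from .sisal import SimplexVertices, affine_project, pseudo_proportions, sisal_fit

logger = logging.getLogger(__name__)

__all__ = [
    "DeconvResult",
    "LabelAssignment",
    "solve_alpha",
    "rescale_H",
    "estimate_M",
    "rank_markers",
    "stsisal_deconvolve",
    "assign_labels",
]


@dataclass
class DeconvResult:
    """Output of :func:`stsisal_deconvolve`."""

    H: np.ndarray                 # (K, S) column-stochastic proportions
    M: np.ndarray                 # (L', K) non-negative profiles
    alpha: np.ndarray             # (K,) corner rescaling coefficients
    markers: list[list[str]]      # per-type ranked marker gene ids
    selected_genes: list[str]
    K: int
    spot_ids: list[str] = field(default_factory=list)
    type_names: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    vertices: SimplexVertices | None = None


def solve_alpha(Hp: np.ndarray) -> np.ndarray:
    """Least-squares coefficients with ``alpha' Hp`` closest to all-ones.

    ``Hp`` (K x S) holds the simplex corners recovered by SISAL; when the
    true proportion matrix is column-stochastic the solution is the
    inverse of the per-row scale SISAL absorbed into the corners.
    """
    Hp = np.asarray(Hp, dtype=float)
    K, S = Hp.shape
    if np.linalg.matrix_rank(Hp) < K:
        raise ValueError("Hp is rank deficient; corners are not independent")
    alpha, res, _, _ = np.linalg.lstsq(Hp.T, np.ones(S), rcond=None)
    resid = float(np.linalg.norm(Hp.T @ alpha - 1.0))
    logger.info("solve_alpha: residual %.3e", resid)
    return alpha


def rescale_H(Hp: np.ndarray, alpha: np.ndarray):
    """Rescale corners into proportions: ``H[k, j] = alpha[k] Hp[k, j]``,
    clip negatives to zero and renormalize every column to sum one.

    Returns ``(H, clipped_mass)`` where ``clipped_mass`` is the total
    negative mass removed before renormalization.
    """
    Hp = np.asarray(Hp, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if not np.all(np.isfinite(alpha)):
        raise ValueError("alpha contains non-finite entries")
    H = alpha[:, None] * Hp
    clipped = float(-H[H < 0].sum())
    H = np.clip(H, 0.0, None)
    colsum = H.sum(axis=0)
    bad = np.nonzero(colsum <= 0)[0]
    if bad.size:
        raise ValueError(
            f"simplex does not cover spot {bad[0]}: all proportions "
            "non-positive after rescaling"
        )
    return H / colsum, clipped


def estimate_M(Y, H: np.ndarray) -> np.ndarray:
    """Per-type expression profiles by rowwise NNLS of ``Y`` on ``H``."""
    Yv = np.asarray(getattr(Y, "values", Y), dtype=float)
    H = np.asarray(H, dtype=float)
    K = H.shape[0]
    if np.linalg.matrix_rank(H) < K:
        raise ValueError("H is rank deficient; cannot estimate profiles")
    return fcnnls(H.T, Yv.T).T


def rank_markers(projected: np.ndarray, vertices: SimplexVertices,
                 G: int = 50, gene_ids: list[str] | None = None):
    """Top-G genes closest (Euclidean, projected space) to each corner.

    Ties break by gene id; if fewer than G genes exist all are returned
    with a warning.
    """
    P = np.asarray(projected, dtype=float)
    N = P.shape[0]
    ids = gene_ids if gene_ids is not None else [str(i) for i in range(N)]
    if G > N:
        warnings.warn(f"requested G={G} markers but only {N} genes exist")
    D = cdist(P, vertices.vertices_projected)  # (N, K)
    out = []
    for k in range(vertices.K):
        order = sorted(range(N), key=lambda i: (D[i, k], ids[i]))
        out.append([ids[i] for i in order[: min(G, N)]])
    return out


def marker_table(projected: np.ndarray, vertices: SimplexVertices,
                 G: int = 50, gene_ids: list[str] | None = None,
                 type_names: list[str] | None = None) -> pd.DataFrame:
    """Long-form table (type, rank, gene, distance) of ranked markers."""
    P = np.asarray(projected, dtype=float)
    N = P.shape[0]
    ids = gene_ids if gene_ids is not None else [str(i) for i in range(N)]
    names = type_names or [f"V{k + 1}" for k in range(vertices.K)]
    D = cdist(P, vertices.vertices_projected)
    rows = []
    for k in range(vertices.K):
        order = sorted(range(N), key=lambda i: (D[i, k], ids[i]))
        for rank, i in enumerate(order[: min(G, N)], start=1):
            rows.append((names[k], rank, ids[i], D[i, k]))
    return pd.DataFrame(rows, columns=["type", "rank", "gene", "distance"])


def stsisal_deconvolve(Y: ExpressionMatrix, K="auto", *, seed: int = 0,
                       k_min: int = 2, k_max: int = 8, reps: int = 1,
                       n_init: int = 1000, per_type: int = 100,
                       g_markers: int = 50, tau: float = 1.0,
                       tol_a: float | None = None, rmse_tol: float = 1e-4,
                       max_outer: int = 20, min_frac: float = 0.05,
                       max_frac: float = 1.0, use_lognorm: bool = False,
                       sisal_max_iter: int = 100,
                       deconf_max_iter: int = 1000,
                       skip_filter: bool = False) -> DeconvResult:
    """Run the full reference-free deconvolution on an expression matrix.

    Stages: detection filter -> (optional) AIC scan for K -> iterative
    cell-type-specific gene selection -> row normalization -> affine
    projection -> SISAL corner identification -> alpha rescaling ->
    profile recovery -> marker ranking.  All randomness derives from
    *seed*; identical calls return identical results.

    ``K`` may be an integer or ``"auto"`` (AIC argmin over
    ``k_min..k_max``).  By default deconvolution runs on the filtered
    non-log values (the mixing model is linear in expression);
    ``use_lognorm=True`` switches to log-normalized input.
    """
    def stage(name):
        logger.info("stsisal: stage %s", name)
        return name

    current = stage("filter")
    try:
        Yf = Y if skip_filter else filter_genes(Y, min_frac, max_frac)
        if use_lognorm and not Yf.is_lognorm:
            Yf = log_normalize(Yf)

        ksel = None
        if K == "auto":
            current = stage("select_k")
            # the AIC scan runs on the full filtered gene complement: the
            # parameter penalty only dominates noise absorption when the
            # gene/spot ratio is large
            ksel = select_k(Yf, k_min=k_min, k_max=k_max, reps=reps,
                            seed=seed, n_init=Yf.n_genes)
            K = ksel.best_k
        K = int(K)
        if K >= Yf.n_spots:
            raise ValueError(f"K={K} must be below the number of spots "
                             f"{Yf.n_spots}")

        current = stage("feature_selection")
        fsr = iterate_selection(Yf, K, n_init=n_init, per_type=per_type,
                                rmse_tol=rmse_tol, max_outer=max_outer,
                                seed=seed, deconf_max_iter=deconf_max_iter,
                                tol_a=tol_a)
        Ysel = Yf.subset_genes(fsr.genes)
        if Ysel.n_genes <= Ysel.n_spots:
            logger.warning(
                "selected gene count L'=%d is not above the spot count "
                "S=%d; the simplex geometry assumes K < S << L'",
                Ysel.n_genes, Ysel.n_spots)

        current = stage("row_normalize")
        norm = row_normalize(Ysel)

        current = stage("affine_project")
        aff, proj = affine_project(norm.values, K)

        current = stage("sisal")
        sv = sisal_fit(proj, K, tau=tau, max_iter=sisal_max_iter,
                       seed=seed, projection=aff)
        Hp = sv.vertices  # (K, S): corners in the ambient spot space

        current = stage("alpha_rescale")
        alpha = solve_alpha(Hp)
        H, clipped = rescale_H(Hp, alpha)

        current = stage("estimate_M")
        M = estimate_M(Ysel, H)

        current = stage("rank_markers")
        markers = rank_markers(proj, sv, G=g_markers, gene_ids=fsr.genes)
    except Exception as exc:
        raise type(exc)(f"[stage {current}] {exc}") from exc

    rmse = float(np.linalg.norm(Ysel.values - M @ H)
                 / np.sqrt(Ysel.n_genes * Ysel.n_spots))
    diagnostics = {
        "reconstruction_rmse": rmse,
        "clipped_mass": clipped,
        "seed": seed,
        "feature_rmse_trace": fsr.rmse_trace,
        "sisal_objective_trace": sv.objective_trace,
        "k_selection": ksel,
        "gene_projection": proj,
    }
    return DeconvResult(
        H=H, M=M, alpha=alpha, markers=markers, selected_genes=fsr.genes,
        K=K, spot_ids=list(Ysel.spot_ids),
        type_names=[f"V{k + 1}" for k in range(K)],
        diagnostics=diagnostics, vertices=sv,
    )


# ---------------------------------------------------------------------------
# Data-driven cell-type label assignment
# ---------------------------------------------------------------------------

@dataclass
class LabelAssignment:
    mapping: dict            # estimated type name -> reference name or "unassigned"
    scores: pd.DataFrame     # K x R composite similarity matrix
    threshold: float
    pearson: pd.DataFrame | None = None
    posterior: pd.DataFrame | None = None


def _cpm_log(df: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    total = df.sum(axis=0).replace(0, 1.0)
    return np.log1p(df / total * scale)


def assign_labels(M_est: pd.DataFrame, reference: pd.DataFrame,
                  threshold: float = 0.3,
                  ref_labels: list[str] | None = None,
                  n_pseudo: int = 25, noise_sd: float = 0.05,
                  seed: int = 0) -> LabelAssignment:
    """Match anonymous estimated profiles to named reference profiles.

    *M_est* is a genes x K frame of estimated per-type expression;
    *reference* is a genes x R frame of type mean profiles (or a
    genes x cells frame with per-cell *ref_labels*).  Both are depth
    normalized and log1p transformed on the shared genes.  Each
    (estimated, reference) pair is scored by the mean of the Pearson
    correlation and the Gaussian naive-Bayes posterior of the reference
    label given the estimated profile; assignments are made greedily from
    the global maximum, each reference used at most once, and any
    estimated type whose best remaining score falls below *threshold* is
    left "unassigned".
    """
    if ref_labels is None:
        names = list(reference.columns)
        if len(set(names)) != len(names):
            dup = [n for n in names if names.count(n) > 1][0]
            raise ValueError(f"duplicate reference type name {dup!r}")
        labels = np.array(names)
    else:
        if len(ref_labels) != reference.shape[1]:
            raise ValueError("ref_labels length must match reference columns")
        labels = np.array([str(x) for x in ref_labels])

    shared = [g for g in M_est.index if g in set(reference.index)]
    if len(shared) < 20:
        raise ValueError(
            f"only {len(shared)} genes shared with the reference; "
            "at least 20 are required"
        )
    E = _cpm_log(M_est.loc[shared]).to_numpy(dtype=float).T     # (K, n_genes)
    R = _cpm_log(reference.loc[shared]).to_numpy(dtype=float).T  # (cells/types, n_genes)
    types = sorted(set(labels))
    est_names = list(M_est.columns)

    # Pearson between estimated profiles and per-type mean references
    ref_means = np.vstack([R[labels == t].mean(axis=0) for t in types])
    pearson = np.zeros((E.shape[0], len(types)))
    for i, e in enumerate(E):
        for j, r in enumerate(ref_means):
            se, sr = e.std(), r.std()
            pearson[i, j] = (np.corrcoef(e, r)[0, 1]
                             if se > 0 and sr > 0 else 0.0)

    # naive-Bayes posterior of each reference label given the profile
    if ref_labels is None:
        rng = np.random.default_rng(seed)
        sd = noise_sd * (R.std() + 1e-12)
        Xtr = np.repeat(R, n_pseudo, axis=0)
        Xtr = Xtr + rng.normal(scale=sd, size=Xtr.shape)
        ytr = np.repeat(labels, n_pseudo)
    else:
        Xtr, ytr = R, labels
    gnb = GaussianNB()
    gnb.fit(Xtr, ytr)
    post_raw = gnb.predict_proba(E)
    col_of = {t: i for i, t in enumerate(gnb.classes_)}
    posterior = np.column_stack([post_raw[:, col_of[t]] for t in types])

    composite = (pearson + posterior) / 2.0

    # greedy global-max assignment with deletion
    mapping = {name: "unassigned" for name in est_names}
    avail_rows = set(range(len(est_names)))
    avail_cols = set(range(len(types)))
    work = composite.copy()
    while avail_rows and avail_cols:
        sub = [(work[i, j], i, j) for i in avail_rows for j in avail_cols]
        best, i, j = max(sub, key=lambda t: (t[0], -t[1], -t[2]))
        if best < threshold:
            break
        mapping[est_names[i]] = types[j]
        avail_rows.discard(i)
        avail_cols.discard(j)

    idx = pd.Index(est_names, name="estimated")
    cols = pd.Index(types, name="reference")
    return LabelAssignment(
        mapping=mapping,
        scores=pd.DataFrame(composite, index=idx, columns=cols),
        threshold=threshold,
        pearson=pd.DataFrame(pearson, index=idx, columns=cols),
        posterior=pd.DataFrame(posterior, index=idx, columns=cols),
    )
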