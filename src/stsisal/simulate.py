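"""Synthetic spot-mixture generator with known ground truth.

The generator emulates how spot-level spatial data arise from single
cells: a fully synthetic single-cell reference (per-type mean profiles
with exclusive marker blocks, negative-binomial counts) replaces a real
annotated dataset, so no download is needed.  Spots are organized into
anatomical regions, each with a distinct dominant cell type; within a
region every spot mixes a uniformly drawn number of co-occurring types
(2 to 6, capped at K) with flat-Dirichlet proportions, and a configurable
*heterogeneity rate* marks spots whose mixture is drawn without any
dominance constraint.  Spot expression is the sum of the sampled single
cells' counts, and the recorded ground-truth proportions are the realized
cell-count fractions of each spot.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["SyntheticReference", "SyntheticTruth", "make_reference",
           "simulate_spots", "write_truth"]


@dataclass
class SyntheticReference:
    """Per-type mean expression with exclusive marker blocks.

    ``marker_of[g]`` is the owning type of marker gene *g* (-1 for
    background genes).  Marker construction guarantees each type at least
    ``n_markers_per_type`` genes whose mean is >= 3x the mean in every
    other type.
    """

    mean_profiles: np.ndarray     # (L, K) non-negative means
    type_names: list[str]
    dispersion: float             # negative-binomial size parameter theta
    cells_per_type: int
    marker_of: np.ndarray         # (L,) int, -1 = background
    gene_ids: list[str] | None = None

    @property
    def K(self) -> int:
        return self.mean_profiles.shape[1]

    @property
    def L(self) -> int:
        return self.mean_profiles.shape[0]


@dataclass
class SyntheticTruth:
    """Simulated expression plus its generating ground truth."""

    Y: ExpressionMatrix
    P_true: np.ndarray                 # (K, S) column-stochastic
    region_of_spot: np.ndarray         # (S,) int
    dominant_type_of_region: dict      # region index -> type index
    heterogeneity_mask: np.ndarray     # (S,) bool
    seed: int


def make_reference(K: int, L: int, n_markers_per_type: int = 20,
                   seed: int = 0, marker_fold: float = 8.0,
                   dispersion: float = 2.0,
                   cells_per_type: int = 100) -> SyntheticReference:
    """Build a synthetic single-cell reference.

    Baseline per-cell means are log-normal (median ~0.3 counts per cell,
    the sparse regime typical of droplet data); each type receives
    ``n_markers_per_type`` exclusive marker genes whose mean is
    ``marker_fold`` times the baseline in the owning type only.
    Deterministic under *seed*.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    needed = K * n_markers_per_type
    if L < needed:
        raise ValueError(
            f"L={L} too small: need at least K*n_markers_per_type={needed}"
        )
    if marker_fold < 3:
        raise ValueError("marker_fold below 3 breaks the marker guarantee")
    rng = np.random.default_rng(seed)
    baseline = rng.lognormal(mean=np.log(0.3), sigma=1.2, size=L)
    profiles = np.tile(baseline[:, None], (1, K))
    marker_of = np.full(L, -1, dtype=int)
    marker_idx = rng.choice(L, size=needed, replace=False)
    for k in range(K):
        block = marker_idx[k * n_markers_per_type:(k + 1) * n_markers_per_type]
        profiles[block, k] = baseline[block] * marker_fold
        marker_of[block] = k
    return SyntheticReference(
        mean_profiles=profiles,
        type_names=[f"type_{k}" for k in range(K)],
        dispersion=float(dispersion),
        cells_per_type=cells_per_type,
        marker_of=marker_of,
        gene_ids=[f"g{i:05d}" for i in range(L)],
    )


def _allocate_cells(props: np.ndarray, n_cells: int) -> np.ndarray:
    """Largest-remainder rounding of ``props * n_cells`` to integers."""
    raw = props * n_cells
    base = np.floor(raw).astype(int)
    short = n_cells - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _enforce_dominance(counts: np.ndarray, dom: int) -> np.ndarray:
    """Move cells until the dominant type has a strict plurality."""
    counts = counts.copy()
    while True:
        others = np.delete(counts, dom)
        if counts[dom] > others.max():
            return counts
        donor = int(np.argmax(np.where(np.arange(len(counts)) == dom,
                                       -1, counts)))
        counts[donor] -= 1
        counts[dom] += 1


def simulate_spots(ref: SyntheticReference, n_regions: int = 3,
                   spots_per_region: int = 80, het_rate: float = 0.3,
                   cells_per_spot: tuple[int, int] = (5, 15),
                   seed: int = 0) -> SyntheticTruth:
    """Simulate a regional spot-mixture dataset from *ref*.

    Each region gets a distinct dominant type.  Per non-heterogeneous
    spot: the number of co-occurring types is uniform on {2..min(6, K)}
    (always including the dominant), proportions are Dirichlet(1) over
    those types, and the dominant coordinate is forced to be the largest
    by swapping.  Heterogeneous spots (Bernoulli(het_rate)) skip the
    dominance constraint.  Expression is a sum of negative-binomial
    single-cell draws; ``P_true`` records the realized cell-count
    fractions.
    """
    K, L = ref.K, ref.L
    if n_regions > K:
        raise ValueError(f"n_regions={n_regions} exceeds K={K}")
    if n_regions < 1 or spots_per_region < 1:
        raise ValueError("need at least one region and one spot per region")
    if not (0 <= het_rate <= 1):
        raise ValueError("het_rate must lie in [0, 1]")
    lo, hi = cells_per_spot
    if lo < 1 or hi < lo:
        raise ValueError("invalid cells_per_spot range")

    rng = np.random.default_rng(seed)
    S = n_regions * spots_per_region
    dominant = rng.permutation(K)[:n_regions]
    region_of_spot = np.repeat(np.arange(n_regions), spots_per_region)
    het_mask = rng.random(S) < het_rate
    cmax = min(6, K)
    theta = ref.dispersion
    mu = ref.mean_profiles  # (L, K)

    P_true = np.zeros((K, S))
    Yv = np.zeros((L, S))
    for j in range(S):
        dom = int(dominant[region_of_spot[j]])
        c = int(rng.integers(2, cmax + 1))
        if het_mask[j]:
            types = rng.choice(K, size=c, replace=False)
            props = rng.dirichlet(np.ones(c))
        else:
            others = rng.choice(np.delete(np.arange(K), dom), size=c - 1,
                                replace=False)
            types = np.concatenate([[dom], others])
            props = rng.dirichlet(np.ones(c))
            if np.argmax(props) != 0:
                big = int(np.argmax(props))
                props[0], props[big] = props[big], props[0]
        n_cells = int(rng.integers(lo, hi + 1))
        counts_sub = _allocate_cells(props, n_cells)
        counts = np.zeros(K, dtype=int)
        counts[types] = counts_sub
        if not het_mask[j]:
            counts = _enforce_dominance(counts, dom)
        P_true[:, j] = counts / n_cells

        # sum of n_k NB(mu, theta) draws == Poisson(Gamma(n_k*theta, mu/theta))
        active = np.nonzero(counts)[0]
        lam = np.zeros(L)
        for k in active:
            lam += rng.gamma(shape=counts[k] * theta,
                             scale=mu[:, k] / theta)
        Yv[:, j] = rng.poisson(lam)

    coords = _region_grid(n_regions, spots_per_region)
    Y = ExpressionMatrix(
        Yv,
        gene_ids=ref.gene_ids or [f"g{i:05d}" for i in range(L)],
        spot_ids=[f"spot{j:04d}" for j in range(S)],
        coords=coords,
    )
    logger.info("simulated %d spots x %d genes, K=%d, het_rate=%.2f",
                S, L, K, het_rate)
    return SyntheticTruth(
        Y=Y,
        P_true=P_true,
        region_of_spot=region_of_spot,
        dominant_type_of_region={r: int(dominant[r])
                                 for r in range(n_regions)},
        heterogeneity_mask=het_mask,
        seed=seed,
    )


def _region_grid(n_regions: int, spots_per_region: int) -> np.ndarray:
    """Lay regions out side by side on integer grids."""
    w = int(np.ceil(np.sqrt(spots_per_region)))
    coords = []
    for r in range(n_regions):
        for i in range(spots_per_region):
            coords.append((r * (w + 2) + i % w, i // w))
    return np.asarray(coords, dtype=float)


def write_truth(truth: SyntheticTruth, outdir) -> None:
    """Write the simulation to *outdir*: MTX + id files + coords +
    ground-truth proportions TSV + a JSON with the remaining truth."""
    from .data import save_matrix
    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_matrix(truth.Y, out / "matrix.mtx", fmt="mtx",
                genes_path=out / "genes.tsv", spots_path=out / "spots.tsv")
    pd.DataFrame(
        {"spot_id": truth.Y.spot_ids,
         "x": truth.Y.coords[:, 0], "y": truth.Y.coords[:, 1]}
    ).to_csv(out / "coords.tsv", sep="\t", index=False)
    K = truth.P_true.shape[0]
    pd.DataFrame(truth.P_true.T, index=truth.Y.spot_ids,
                 columns=[f"type_{k}" for k in range(K)]).to_csv(
        out / "P_true.tsv", sep="\t", index_label="spot_id")
    meta = {
        "seed": truth.seed,
        "region_of_spot": truth.region_of_spot.tolist(),
        "dominant_type_of_region": {str(k): v for k, v in
                                    truth.dominant_type_of_region.items()},
        "heterogeneity_mask": truth.heterogeneity_mask.astype(int).tolist(),
    }
    (out / "truth.json").write_text(json.dumps(meta, indent=2))
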