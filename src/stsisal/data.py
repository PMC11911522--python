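"""Expression-matrix containers, file I/O and preprocessing.

The central object is :class:`ExpressionMatrix`, a genes x spots
non-negative matrix with gene and spot identifiers and optional spatial
coordinates.  Orientation is genes-in-rows, spots-in-columns everywhere;
loaders that encounter spot-major files must transpose before construction.

Preprocessing follows the usual spot-level workflow: missing values are
filled with zeros at load time, library-size log-normalization is applied
per spot, and genes are kept only when their detection fraction lies
strictly between a lower and an upper bound.  Row normalization (each gene
scaled to sum one across spots) turns genes into points on a simplex and is
the geometric entry point of the deconvolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "load_matrix",
    "save_matrix",
    "load_coords",
    "log_normalize",
    "filter_genes",
    "row_normalize",
]


@dataclass
class ExpressionMatrix:
    """Genes x spots non-negative expression matrix.

    Parameters
    ----------
    values
        ``(L, S)`` array of counts or normalized expression, all entries
        finite and non-negative.
    gene_ids, spot_ids
        Unique row / column identifiers.
    coords
        Optional ``(S, 2)`` array of spatial x/y coordinates.
    is_lognorm
        Whether :func:`log_normalize` has already been applied.
    """

    values: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray | None = None
    is_lognorm: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.spot_ids = [str(s) for s in self.spot_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x spots array")
        L, S = self.values.shape
        if len(self.gene_ids) != L:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {L} rows"
            )
        if len(self.spot_ids) != S:
            raise ValueError(
                f"{len(self.spot_ids)} spot ids for {S} columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.spot_ids, "spot")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"NaN entry at gene {self.gene_ids[i]!r}, spot "
                f"{self.spot_ids[j]!r}; fill missing values with 0 first"
            )
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative entry {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r} (row {i}), spot "
                f"{self.spot_ids[j]!r} (column {j})"
            )
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (S, 2):
                raise ValueError(
                    f"coords must be ({S}, 2), got {self.coords.shape}"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Return a new matrix restricted to *genes* (ids or indices),
        preserving the requested order."""
        if len(genes) == 0:
            raise ValueError("empty gene selection")
        if isinstance(genes[0], (int, np.integer)):
            idx = np.asarray(genes, dtype=int)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            missing = [g for g in genes if g not in pos]
            if missing:
                raise KeyError(f"unknown gene ids: {missing[:5]}")
            idx = np.array([pos[g] for g in genes])
        return ExpressionMatrix(
            self.values[idx],
            [self.gene_ids[i] for i in idx],
            list(self.spot_ids),
            coords=self.coords,
            is_lognorm=self.is_lognorm,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.spot_ids)


@dataclass
class NormalizedMatrix:
    """Row-normalized expression: every gene (row) sums to one.

    ``row_scale`` keeps the original row sums so that
    ``diag(row_scale) @ values`` reconstructs the input exactly.
    """

    values: np.ndarray
    row_scale: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    spot_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_scale = np.asarray(self.row_scale, dtype=float)
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-10):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"row {bad} sums to {sums[bad]}, expected 1")
        if (self.row_scale <= 0).any():
            bad = int(np.argmax(self.row_scale <= 0))
            raise ValueError(f"row_scale[{bad}] is not positive")


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_id_column(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                # tolerate multi-column files (e.g. 10x features.tsv)
                ids.append(line.split("\t")[0])
    return ids


def load_matrix(path, fmt: str | None = None, genes_path=None,
                spots_path=None, coords_path=None) -> ExpressionMatrix:
    """Load a genes x spots expression matrix.

    ``fmt`` is one of ``"mtx"``, ``"csv"``, ``"tsv"``; when omitted it is
    inferred from the file suffix.  MatrixMarket input requires companion
    one-column gene and spot id files.  Dense CSV/TSV input has a header
    row of spot ids and a first column of gene ids; empty cells load as 0.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt == "mtx":
        if genes_path is None or spots_path is None:
            raise ValueError("MTX input requires genes_path and spots_path")
        mat = mmread(str(path))
        if sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        gene_ids = _read_id_column(Path(genes_path))
        spot_ids = _read_id_column(Path(spots_path))
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        values = np.nan_to_num(values, nan=0.0)  # missing -> 0
        gene_ids = [str(g) for g in df.index]
        spot_ids = [str(s) for s in df.columns]
    else:
        raise ValueError(f"unknown format {fmt!r}; expected mtx, csv or tsv")

    coords = None
    if coords_path is not None:
        coords = load_coords(coords_path, spot_ids)
    logger.info("loaded %d genes x %d spots from %s (genes-in-rows)",
                values.shape[0], values.shape[1], path)
    return ExpressionMatrix(values, gene_ids, spot_ids, coords=coords)


def load_coords(path, spot_ids: list[str] | None = None) -> np.ndarray:
    """Read a spot coordinate TSV with columns ``spot_id``, ``x``, ``y``,
    returned in the order of *spot_ids* when given."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = [c.lower() for c in df.columns]
    df = df.set_index(df.columns[0])
    if spot_ids is not None:
        missing = [s for s in spot_ids if s not in df.index]
        if missing:
            raise ValueError(f"coordinates missing for spots {missing[:5]}")
        df = df.loc[spot_ids]
    return df[["x", "y"]].to_numpy(dtype=float)


def save_matrix(Y: ExpressionMatrix, path, fmt: str | None = None,
                genes_path=None, spots_path=None) -> None:
    """Write *Y* so that :func:`load_matrix` round-trips it."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt == "mtx":
        if genes_path is None or spots_path is None:
            raise ValueError("MTX output requires genes_path and spots_path")
        mmwrite(str(path), sparse.coo_matrix(Y.values))
        Path(genes_path).write_text("\n".join(Y.gene_ids) + "\n")
        Path(spots_path).write_text("\n".join(Y.spot_ids) + "\n")
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        Y.to_frame().to_csv(path, sep=sep, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def log_normalize(Y: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Per-spot library-size normalization to *scale* total counts,
    followed by ``log1p``.  Zero entries stay exactly zero."""
    if Y.is_lognorm:
        raise ValueError("matrix is already log-normalized")
    if scale <= 0:
        raise ValueError("scale must be positive")
    colsum = Y.values.sum(axis=0)
    zero = np.nonzero(colsum == 0)[0]
    if zero.size:
        raise ValueError(
            f"spot {Y.spot_ids[zero[0]]!r} has zero total expression and "
            "cannot be normalized"
        )
    vals = np.log1p(Y.values / colsum * scale)
    return ExpressionMatrix(vals, list(Y.gene_ids), list(Y.spot_ids),
                            coords=Y.coords, is_lognorm=True)


def filter_genes(Y: ExpressionMatrix, min_frac: float = 0.05,
                 max_frac: float = 1.0) -> ExpressionMatrix:
    """Keep genes detected (value > 0) in strictly more than ``min_frac``
    and strictly less than ``max_frac`` of spots.

    Both bounds are strict, so with the defaults a gene present in every
    spot is removed along with genes in at most 5% of spots.
    """
    if not (0 <= min_frac < max_frac <= 1):
        raise ValueError("require 0 <= min_frac < max_frac <= 1")
    frac = (Y.values > 0).mean(axis=1)
    keep = np.nonzero((frac > min_frac) & (frac < max_frac))[0]
    if keep.size == 0:
        raise ValueError(
            f"no gene has detection fraction in ({min_frac}, {max_frac}); "
            "loosen the thresholds"
        )
    logger.info("detection filter kept %d/%d genes", keep.size, Y.n_genes)
    return Y.subset_genes(list(keep))


def row_normalize(Y: ExpressionMatrix) -> NormalizedMatrix:
    """Scale every gene to sum one across spots.

    The original row sums are kept in ``row_scale``; the input is exactly
    ``diag(row_scale) @ values``.
    """
    sums = Y.values.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValueError(
            f"gene {Y.gene_ids[zero[0]]!r} has zero total expression; "
            "apply filter_genes first"
        )
    vals = Y.values / sums[:, None]
    return NormalizedMatrix(vals, sums, list(Y.gene_ids), list(Y.spot_ids))
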