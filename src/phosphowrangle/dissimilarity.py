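"""Missing-aware dissimilarities and the Spearman-Euclidean combination.

Correlation distances are computed over pairwise-complete observations:
each gene pair's correlation uses only the samples observed in *both*
genes.  A pair with too little overlap, or zero variance on the overlap,
has no defined statistical relationship; its distance is missing and is
later set far beyond any real distance (the "no statistical interaction"
fill).  Distances from zero-imputed data are kept only as a comparison
mode — shared zeros correlate with each other and collapse the structure.

The Spearman-Euclidean Dissimilarity (SED) rescales the fill-completed
correlation and Euclidean matrices to a common scale (real distances in
[0, 1]) and averages them entrywise, so the two measures contribute
equally and each can resolve pairs the other cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import PhosphoMatrix

__all__ = [
    "DissimilarityMatrix",
    "correlation_distance",
    "euclidean_distance",
    "fill_missing_distances",
    "combine_sed",
    "sed",
    "read_dissimilarity",
    "write_dissimilarity",
]

_CORR_METHODS = {"pearson", "spearman"}
_EXTRA_METRICS = {"manhattan", "canberra"}  # optional, untested vs source data


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric gene x gene dissimilarity with provenance metadata.

    Attributes
    ----------
    data
        Square DataFrame, symmetric, zero diagonal; NaN marks pairs with no
        defined distance (pre-fill only).
    method
        One of ``pearson``, ``spearman``, ``euclidean``, ``manhattan``,
        ``canberra``, ``sed``.
    missing_policy
        ``pairwise`` (pairwise-complete observations) or ``zero_impute``.
    fill_factor
        Multiplier applied to the maximum real distance when filling.
    fill_value
        The resolved fill, set once :func:`fill_missing_distances` ran.
    max_real
        Maximum finite off-diagonal entry before filling (the scaling unit).
    scaled
        True once entries were divided by ``max_real`` (real distances then
        lie in [0, 1] and fills equal ``fill_factor``).
    """

    data: pd.DataFrame = field(repr=False)
    method: str = "spearman"
    missing_policy: str = "pairwise"
    fill_factor: float = 100.0
    fill_value: float | None = None
    max_real: float | None = None
    scaled: bool = False

    def __post_init__(self) -> None:
        df = self.data.astype(float)
        if df.shape[0] != df.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels must match")
        values = df.to_numpy()
        if not np.allclose(np.diag(values), 0.0, equal_nan=False):
            raise ValueError("diagonal must be exactly zero")
        both = ~np.isnan(values)
        if not ((values == values.T) | (np.isnan(values) & np.isnan(values.T))).all():
            raise ValueError("matrix must be symmetric (missing pattern included)")
        if both.any() and np.nanmin(values) < 0:
            raise ValueError("dissimilarities must be nonnegative")
        object.__setattr__(self, "data", df)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def filled(self) -> bool:
        return not bool(np.isnan(self.data.to_numpy()).any())

    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def _prepare_values(matrix: PhosphoMatrix, missing_policy: str) -> pd.DataFrame:
    if missing_policy not in {"pairwise", "zero_impute"}:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    df = matrix.data
    if missing_policy == "zero_impute":
        df = df.fillna(0.0)
    return df


def correlation_distance(
    matrix: PhosphoMatrix,
    method: str = "spearman",
    *,
    min_overlap: int = 2,
    missing_policy: str = "pairwise",
) -> DissimilarityMatrix:
    """Correlation distance 1 - |r| over pairwise-complete observations.

    ``r`` is the Pearson or Spearman correlation computed for each gene
    pair over the samples observed in both genes (Spearman re-ranks within
    each overlap, average ranks for ties).  The absolute value is taken:
    perfect anticorrelation is as strong a statistical relationship as
    perfect correlation.  Pairs with overlap below ``min_overlap`` or zero
    variance on the overlap yield a missing distance.

    With ``missing_policy='zero_impute'`` every missing count is first set
    to 0 and plain full-length correlations are used (comparison mode).
    """
    if method not in _CORR_METHODS:
        raise ValueError(f"method must be one of {sorted(_CORR_METHODS)}")
    if min_overlap < 2:
        raise ValueError("min_overlap must be >= 2")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to correlate genes")
    df = _prepare_values(matrix, missing_policy)
    # genes are rows -> correlate columns of the transpose; pandas computes
    # pairwise-complete correlations (ranks re-derived per pair for spearman)
    corr = df.T.corr(method=method, min_periods=min_overlap)
    dist = 1.0 - corr.abs()
    np.fill_diagonal(dist.values, 0.0)
    # numerical guard: |r| can exceed 1 by epsilon
    dist = dist.clip(lower=0.0)
    return DissimilarityMatrix(
        dist, method=method, missing_policy=missing_policy
    )


def euclidean_distance(
    matrix: PhosphoMatrix,
    *,
    missing_policy: str = "pairwise",
) -> DissimilarityMatrix:
    """Euclidean distance with the co-observation rescaling convention.

    Under the pairwise policy, for genes *x*, *y* co-observed in *m* of *p*
    samples::

        d(x, y) = sqrt( (p / m) * sum_{co-observed} (x_i - y_i)^2 )

    i.e. the partial sum of squares is scaled up to the full sample count
    (the convention of R's ``dist``); *m* = 0 gives a missing distance.
    Under ``zero_impute`` missing counts become 0 and the plain Euclidean
    distance is used.
    """
    df = _prepare_values(matrix, missing_policy)
    X = df.to_numpy()
    p = X.shape[1]
    M = (~np.isnan(X)).astype(float)
    X0 = np.where(np.isnan(X), 0.0, X)
    sq = X0 * X0
    # sum over co-observed k of (x_ik - x_jk)^2 = A + B - 2C with the
    # opposite row's mask applied to each squared term
    A = sq @ M.T
    B = M @ sq.T
    C = X0 @ X0.T
    m = M @ M.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = (p / m) * (A + B - 2.0 * C)
    d2 = np.where(m > 0, np.maximum(d2, 0.0), np.nan)
    dist = np.sqrt(d2)
    np.fill_diagonal(dist, 0.0)
    out = pd.DataFrame(dist, index=df.index, columns=df.index)
    # exact symmetry despite floating-point accumulation order
    out = (out + out.T) / 2.0
    np.fill_diagonal(out.values, 0.0)
    return DissimilarityMatrix(out, method="euclidean", missing_policy=missing_policy)


def metric_distance(
    matrix: PhosphoMatrix,
    metric: str,
    *,
    missing_policy: str = "pairwise",
) -> DissimilarityMatrix:
    """Manhattan or Canberra distance over co-observed samples (optional).

    Provided for completeness; behaves like :func:`euclidean_distance`
    with the same p/m rescaling of the partial sum (Manhattan) or partial
    term sum (Canberra).
    """
    if metric not in _EXTRA_METRICS:
        raise ValueError(f"metric must be one of {sorted(_EXTRA_METRICS)}")
    df = _prepare_values(matrix, missing_policy)
    X = df.to_numpy()
    n, p = X.shape
    dist = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(np.isnan(X[i]) | np.isnan(X[j]))
            m = int(both.sum())
            if m == 0:
                continue
            xi, xj = X[i, both], X[j, both]
            if metric == "manhattan":
                s = float(np.abs(xi - xj).sum())
            else:  # canberra
                denom = np.abs(xi) + np.abs(xj)
                terms = np.where(denom > 0, np.abs(xi - xj) / np.where(denom > 0, denom, 1), 0.0)
                s = float(terms.sum())
            dist[i, j] = dist[j, i] = (p / m) * s
    np.fill_diagonal(dist, 0.0)
    out = pd.DataFrame(dist, index=df.index, columns=df.index)
    return DissimilarityMatrix(out, method=metric, missing_policy=missing_policy)


def fill_missing_distances(
    D: DissimilarityMatrix, fill_factor: float = 100.0
) -> DissimilarityMatrix:
    """Replace missing distances by ``fill_factor`` x the max real distance.

    A missing distance means no statistical relationship could be
    established, which for clustering purposes should read as "very far":
    two orders of magnitude beyond the largest real distance by default.
    Pushing the fill further out does not change downstream structure.
    """
    values = D.values().copy()
    off_diag = ~np.eye(values.shape[0], dtype=bool)
    finite = np.isfinite(values) & off_diag
    if not finite.any():
        raise ValueError("cannot fill: no finite off-diagonal distance")
    max_real = float(values[finite].max())
    fill_value = fill_factor * max_real
    values[np.isnan(values)] = fill_value
    out = pd.DataFrame(values, index=D.data.index, columns=D.data.columns)
    return DissimilarityMatrix(
        out,
        method=D.method,
        missing_policy=D.missing_policy,
        fill_factor=fill_factor,
        fill_value=fill_value,
        max_real=max_real,
        scaled=D.scaled,
    )


def _scaled(D: DissimilarityMatrix) -> DissimilarityMatrix:
    """Divide by the max real (pre-fill) distance; fills become fill_factor."""
    if D.scaled:
        return D
    if D.max_real is None:
        raise ValueError("matrix must be filled before scaling (fill records max_real)")
    # degenerate case: every real distance is exactly zero — nothing to scale
    unit = D.max_real if D.max_real > 0 else 1.0
    out = D.data / unit
    return DissimilarityMatrix(
        out,
        method=D.method,
        missing_policy=D.missing_policy,
        fill_factor=D.fill_factor,
        fill_value=D.fill_value / unit if D.fill_value is not None else None,
        max_real=1.0,
        scaled=True,
    )


def combine_sed(
    D_corr: DissimilarityMatrix, D_euclid: DissimilarityMatrix
) -> DissimilarityMatrix:
    """Average two filled dissimilarities on a common scale (the SED).

    Each input is divided by its own maximum *real* (pre-fill) distance —
    so real distances land in [0, 1] and fills equal their fill factor —
    then the entrywise mean is taken.  A pair filled in exactly one input
    ends up dominated by that fill, as it should: half the evidence says
    "no relationship at all".
    """
    if D_corr.genes != D_euclid.genes:
        raise ValueError("inputs must share the same gene labels in the same order")
    if not (D_corr.filled and D_euclid.filled):
        raise ValueError("fill both matrices before combining")
    a = _scaled(D_corr)
    b = _scaled(D_euclid)
    out = (a.data + b.data) / 2.0
    fill = None
    if a.fill_value is not None and b.fill_value is not None:
        fill = (a.fill_value + b.fill_value) / 2.0
    return DissimilarityMatrix(
        out,
        method="sed",
        missing_policy=D_corr.missing_policy,
        fill_factor=D_corr.fill_factor,
        fill_value=fill,
        max_real=1.0,
        scaled=True,
    )


def sed(
    matrix: PhosphoMatrix,
    *,
    corr_method: str = "spearman",
    min_overlap: int = 2,
    missing_policy: str = "pairwise",
    fill_factor: float = 100.0,
) -> DissimilarityMatrix:
    """Convenience pipeline: correlation + Euclidean -> fill -> combine."""
    dc = correlation_distance(
        matrix, corr_method, min_overlap=min_overlap, missing_policy=missing_policy
    )
    de = euclidean_distance(matrix, missing_policy=missing_policy)
    return combine_sed(
        fill_missing_distances(dc, fill_factor),
        fill_missing_distances(de, fill_factor),
    )


def write_dissimilarity(D: DissimilarityMatrix, path: str | Path) -> None:
    """Write the square matrix as TSV (``NA`` pre-fill) + JSON sidecar."""
    path = Path(path)
    D.data.to_csv(path, sep="\t", na_rep="NA", index_label="gene")
    meta = {
        "method": D.method,
        "missing_policy": D.missing_policy,
        "fill_factor": D.fill_factor,
        "fill_value": D.fill_value,
        "max_real": D.max_real,
        "scaled": D.scaled,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_dissimilarity(path: str | Path) -> DissimilarityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return DissimilarityMatrix(df, **meta)
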