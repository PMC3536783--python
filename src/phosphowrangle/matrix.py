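"""Gene x sample phosphopeptide count matrix with an explicit missing marker.

The central container of the package is a nonnegative count matrix in which
the absence of a measurement is recorded as missing (NaN internally, the
literal token ``NA`` on disk) and is never coded as zero.  An observed zero
is data; a missing cell is the statement "the spectrometer saw nothing and
we cannot know why".  Every downstream statistic in this package treats the
two differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PhosphoMatrix", "read_matrix", "write_matrix"]


@dataclass(frozen=True)
class PhosphoMatrix:
    """A gene x sample nonnegative count matrix with explicit missing cells.

    Parameters
    ----------
    data
        DataFrame indexed by gene symbol (rows) and sample id (columns).
        Cells are nonnegative counts; missing measurements are NaN.

    Notes
    -----
    Invariants enforced at construction:

    * row and column labels are unique and sorted lexicographically;
    * every gene and every sample has at least one observed cell;
    * all observed values are finite and >= 0.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("matrix must have at least one gene and one sample")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene labels: {dupes}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample labels: {dupes}")
        df = df.astype(float).sort_index(axis=0).sort_index(axis=1)
        values = df.to_numpy()
        observed = ~np.isnan(values)
        if not observed.any(axis=1).all():
            bad = df.index[~observed.any(axis=1)].tolist()
            raise ValueError(f"genes with no observed cell: {bad}")
        if not observed.any(axis=0).all():
            bad = df.columns[~observed.any(axis=0)].tolist()
            raise ValueError(f"samples with no observed cell: {bad}")
        if np.nanmin(values) < 0 or np.isinf(values).any():
            raise ValueError("observed counts must be finite and nonnegative")
        object.__setattr__(self, "data", df)

    # -- basic accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def observed(self) -> pd.DataFrame:
        """Boolean mask of observed (non-missing) cells."""
        return self.data.notna()

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    # -- derived statistics ----------------------------------------------

    def total_phosphorylation(self) -> pd.Series:
        """Per-gene sum of observed counts over all samples.

        Drives node size/colour in network renderings.
        """
        return self.data.sum(axis=1, skipna=True)

    def summary(self) -> dict:
        """Dimensions, sparsity and total signal of the matrix."""
        values = self.data.to_numpy()
        n_missing = int(np.isnan(values).sum())
        n_cells = values.size
        return {
            "n_genes": self.shape[0],
            "n_samples": self.shape[1],
            "percent_missing": 100.0 * n_missing / n_cells,
            "total_signal": float(np.nansum(values)),
        }

    def subset(self, genes=None, samples=None) -> "PhosphoMatrix":
        """Restrict to a gene and/or sample subset (labels kept sorted).

        The restriction must leave every kept gene and sample with at least
        one observation; use raw ``.data`` slicing for unchecked views.
        """
        df = self.data
        if genes is not None:
            missing = set(genes) - set(df.index)
            if missing:
                raise KeyError(f"genes not in matrix: {sorted(missing)}")
            df = df.loc[sorted(set(genes))]
        if samples is not None:
            missing = set(samples) - set(df.columns)
            if missing:
                raise KeyError(f"samples not in matrix: {sorted(missing)}")
            df = df[sorted(set(samples))]
        return PhosphoMatrix(df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhosphoMatrix):
            return NotImplemented
        if self.shape != other.shape:
            return False
        if self.genes != other.genes or self.samples != other.samples:
            return False
        a, b = self.values(), other.values()
        return bool(((a == b) | (np.isnan(a) & np.isnan(b))).all())


def matrix_summary(matrix: PhosphoMatrix) -> dict:
    """Functional alias for :meth:`PhosphoMatrix.summary`."""
    return matrix.summary()


MISSING_TOKEN = "NA"


def write_matrix(matrix: PhosphoMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with literal ``NA`` for missing cells.

    Integral counts are written without a decimal point so that the
    round-trip is bit-exact on integer data.
    """
    df = matrix.data

    def _fmt(x: float) -> str:
        if np.isnan(x):
            return MISSING_TOKEN
        if float(x).is_integer():
            return str(int(x))
        return repr(float(x))

    out = df.map(_fmt)
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> PhosphoMatrix:
    """Read a TSV matrix written by :func:`write_matrix`.

    ``NA`` is the only token interpreted as missing; a literal ``0`` is an
    observed zero count.  Duplicate gene or sample labels and ragged rows
    are errors.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=[MISSING_TOKEN],
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    return PhosphoMatrix(df)
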