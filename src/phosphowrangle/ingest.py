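"""Parse phosphopeptide spectrum tables into the gene x sample count matrix.

A spectrum table is a long-format file with one row per (protein, sample)
observation carrying a peptide count.  Ingestion maps protein identifiers
to gene symbols (HUGO-style), sums all counts per gene per sample, and
leaves every never-observed (gene, sample) cell missing.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import PhosphoMatrix

__all__ = [
    "SpectrumRecord",
    "parse_spectrum_table",
    "read_gene_map",
    "map_gene_symbols",
    "build_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpectrumRecord:
    """One (protein, sample) peptide-count observation."""

    protein_id: str
    sample_id: str
    peptide_count: int
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if not self.protein_id or not self.sample_id:
            raise ValueError("protein_id and sample_id must be non-empty")
        if self.peptide_count < 0:
            raise ValueError("peptide_count must be nonnegative")


def parse_spectrum_table(
    path: str | Path,
    *,
    protein_col: str = "protein",
    sample_col: str = "sample",
    count_col: str = "count",
    delimiter: str | None = None,
) -> list[SpectrumRecord]:
    """Parse a long-format spectrum table.

    Parameters
    ----------
    path
        Tab- or comma-separated file with a header row.
    protein_col, sample_col, count_col
        Header names of the three mandatory columns (layouts vary between
        repositories, so these are configurable).
    delimiter
        Field delimiter; sniffed from the header line when None.

    Raises
    ------
    ValueError
        If a mandatory column is missing or a count is non-numeric; the
        error names the offending line number.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty file, expected a header row")
        if delimiter is None:
            delimiter = "\t" if "\t" in header_line else ","
        header = next(csv.reader([header_line], delimiter=delimiter))
        for col in (protein_col, sample_col, count_col):
            if col not in header:
                raise ValueError(
                    f"{path}: missing mandatory column {col!r} (header: {header})"
                )
        idx = {c: header.index(c) for c in (protein_col, sample_col, count_col)}
        records: list[SpectrumRecord] = []
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) < len(header):
                raise ValueError(f"{path}: line {lineno}: expected {len(header)} fields")
            raw = row[idx[count_col]].strip()
            try:
                count = int(float(raw))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric count {raw!r}"
                ) from None
            records.append(
                SpectrumRecord(
                    protein_id=row[idx[protein_col]].strip(),
                    sample_id=row[idx[sample_col]].strip(),
                    peptide_count=count,
                )
            )
    return records


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column protein-id -> gene-symbol TSV (no header required).

    A header line is detected (and dropped) when its second field is one of
    the usual symbol column names.  Conflicting duplicate mappings are an
    error; exact duplicates are tolerated.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            pid, symbol = parts[0].strip(), parts[1].strip()
            if lineno == 1 and symbol.lower() in {"gene", "symbol", "gene_symbol"}:
                continue
            if pid in mapping and mapping[pid] != symbol:
                # conflicts are logged, not silently resolved
                logger.warning(
                    "conflicting mapping for %s: %s vs %s (keeping first)",
                    pid, mapping[pid], symbol,
                )
                continue
            mapping[pid] = symbol
    return mapping


def map_gene_symbols(
    records: Iterable[SpectrumRecord],
    gene_map: Mapping[str, str],
    policy: str = "passthrough",
) -> list[SpectrumRecord]:
    """Attach gene symbols to spectrum records.

    ``policy='passthrough'`` keeps unmapped protein ids as their own symbol
    so no signal is silently lost; ``policy='drop'`` removes them with a
    warning.  The number of unmapped ids is logged either way.
    """
    if policy not in {"drop", "passthrough"}:
        raise ValueError(f"unknown policy {policy!r}")
    out: list[SpectrumRecord] = []
    n_unmapped = 0
    for rec in records:
        symbol = gene_map.get(rec.protein_id)
        if symbol is None:
            n_unmapped += 1
            if policy == "drop":
                continue
            symbol = rec.protein_id
        out.append(replace(rec, gene_symbol=symbol))
    if n_unmapped:
        logger.warning(
            "%d record(s) with unmapped protein ids (policy=%s)", n_unmapped, policy
        )
    return out


def build_matrix(records: Sequence[SpectrumRecord]) -> PhosphoMatrix:
    """Sum peptide counts per (gene, sample) into a :class:`PhosphoMatrix`.

    Cells with no contributing record are missing.  Total signal is
    conserved: the matrix sums to the sum of the record counts.
    """
    if not records:
        raise ValueError("cannot build a matrix from zero records")
    acc: dict[tuple[str, str], int] = defaultdict(int)
    for rec in records:
        symbol = rec.gene_symbol if rec.gene_symbol is not None else rec.protein_id
        acc[(symbol, rec.sample_id)] += rec.peptide_count
    genes = sorted({g for g, _ in acc})
    samples = sorted({s for _, s in acc})
    df = pd.DataFrame(np.nan, index=genes, columns=samples, dtype=float)
    for (g, s), count in acc.items():
        df.at[g, s] = float(count)
    return PhosphoMatrix(df)
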