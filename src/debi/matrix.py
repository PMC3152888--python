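"""Expression / binary matrix containers, TSV I/O and fold-change binarization.

An :class:`ExpressionMatrix` holds log2 expression ratios for ``n`` genes
across ``m`` samples.  Binarization thresholds each entry against a c-fold
regulation cut-off, producing one boolean matrix per regulation direction:
``UP`` marks entries with value >= log2(c), ``DOWN`` marks entries with
value <= -log2(c).  Pre-binarized 0/1 tables (e.g. gene-set membership
matrices) are read directly and tagged ``AS_GIVEN``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

UP = "up"
DOWN = "down"
AS_GIVEN = "as_given"

_DIRECTIONS = (UP, DOWN, AS_GIVEN)


class MatrixFormatError(ValueError):
    """Raised for malformed expression / binary tables."""


def _check_ids(ids: Sequence[str], axis: str) -> list[str]:
    ids = [str(x) for x in ids]
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise MatrixFormatError(f"duplicate {axis} identifier: {x!r}")
        seen.add(x)
    if not ids:
        raise MatrixFormatError(f"need at least one {axis}")
    return ids


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix; NaN entries are missing values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise MatrixFormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class BinaryMatrix:
    """Boolean gene x sample matrix tagged with the regulation direction.

    ``cutoff_c`` records the fold-change cut-off used for binarization and is
    ``None`` for matrices supplied already binarized (``AS_GIVEN``).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    bits: np.ndarray
    direction: str = AS_GIVEN
    cutoff_c: float | None = None

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise MatrixFormatError("bit matrix shape does not match identifier lists")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _parse_table(path, delimiter: str):
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    rows = [r for r in rows if r and not all(c.strip() == "" for c in r)]
    if len(rows) < 2:
        raise MatrixFormatError(f"{path}: need a header row and at least one gene row")
    header = rows[0]
    sample_ids = [c.strip() for c in header[1:]]
    m = len(sample_ids)
    gene_ids: list[str] = []
    cells: list[list[str]] = []
    for rnum, row in enumerate(rows[1:], start=2):
        if len(row) != m + 1:
            raise MatrixFormatError(
                f"{path}: row {rnum} has {len(row) - 1} value fields, expected {m}"
            )
        gene_ids.append(row[0].strip())
        cells.append(row[1:])
    return gene_ids, sample_ids, cells


def read_expression(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes-in-rows expression table.

    First row: sample identifiers (the top-left cell is ignored); first
    column: gene identifiers.  Empty cells become missing values (NaN).
    Duplicate identifiers, ragged rows and non-numeric cells raise
    :class:`MatrixFormatError` naming the offending coordinate.
    """
    gene_ids, sample_ids, cells = _parse_table(path, delimiter)
    values = np.full((len(gene_ids), len(sample_ids)), np.nan)
    for i, row in enumerate(cells):
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise MatrixFormatError(
                    f"{path}: non-numeric cell {cell!r} at gene "
                    f"{gene_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
    return ExpressionMatrix(gene_ids, sample_ids, values)


def read_binary(path, delimiter: str = "\t") -> BinaryMatrix:
    """Read a pre-binarized 0/1 table in the same layout as ``read_expression``."""
    gene_ids, sample_ids, cells = _parse_table(path, delimiter)
    bits = np.zeros((len(gene_ids), len(sample_ids)), dtype=bool)
    for i, row in enumerate(cells):
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell in ("", "0"):
                continue
            if cell == "1":
                bits[i, j] = True
            else:
                raise MatrixFormatError(
                    f"{path}: entry {cell!r} at gene {gene_ids[i]!r}, sample "
                    f"{sample_ids[j]!r} is not 0/1"
                )
    return BinaryMatrix(gene_ids, sample_ids, bits, direction=AS_GIVEN)


def write_expression(E: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene" + delimiter + delimiter.join(E.sample_ids) + "\n")
        for gid, row in zip(E.gene_ids, E.values):
            cells = ["" if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(gid + delimiter + delimiter.join(cells) + "\n")


def binarize(E: ExpressionMatrix, c: float, direction: str) -> BinaryMatrix:
    """Threshold log2 ratios against a c-fold regulation cut-off.

    ``UP``: bit set where value >= log2(c).  ``DOWN``: bit set where
    value <= -log2(c).  Missing values binarize to 0.
    """
    if not c > 1:
        raise ValueError(f"fold-change cut-off must be > 1, got {c}")
    if direction not in (UP, DOWN):
        raise ValueError("direction must be 'up' or 'down'")
    thr = math.log2(c)
    vals = E.values
    with np.errstate(invalid="ignore"):
        bits = vals >= thr if direction == UP else vals <= -thr
    bits &= ~np.isnan(vals)
    return BinaryMatrix(list(E.gene_ids), list(E.sample_ids), bits, direction, c)
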