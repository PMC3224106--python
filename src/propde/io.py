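"""Tab-separated input/output for paired expression matrices and results.

The native matrix layout is one row per gene: a ``gene_id`` column, then the
n reference-channel columns (R block) followed by the n test-channel columns
(G block), so a well-formed file has 1 + 2n columns.  Lines starting with
``#`` are comments.  ``NA`` is the missing-value sentinel in result files;
input matrices must not contain missing cells (zeros are legitimate values,
not missing).
"""

from __future__ import annotations

import csv
import math

import numpy as np
import pandas as pd

NA = "NA"

RESULT_COLUMNS = [
    "gene_id",
    "p_bar",
    "p_hat",
    "r_hat",
    "statistic",
    "df",
    "p_value",
    "p_adjusted",
    "significant",
    "missing",
    "method",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_paired_matrix(path):
    """Parse a paired expression matrix TSV.

    Returns ``(gene_ids, R, G)`` with R and G as K x n float arrays.  Raises
    :class:`ParseError` with a line number for ragged rows, non-numeric or
    negative cells, an even overall column count, or duplicate gene ids.
    """
    gene_ids: list[str] = []
    r_rows: list[list[float]] = []
    g_rows: list[list[float]] = []
    n = None
    ncols = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header_seen = False
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if not header_seen:
                ncols = len(row)
                if ncols < 3 or (ncols - 1) % 2 != 0:
                    raise ParseError(
                        f"line {lineno}: expected 1 + 2n columns "
                        f"(gene_id, n reference, n test); got {ncols}"
                    )
                n = (ncols - 1) // 2
                header_seen = True
                continue
            if len(row) != ncols:
                raise ParseError(
                    f"line {lineno}: ragged row ({len(row)} fields, expected {ncols})"
                )
            gene_id = row[0]
            if gene_id in set(gene_ids):
                raise ParseError(f"line {lineno}: duplicate gene_id {gene_id!r}")
            values = []
            for col, cell in enumerate(row[1:], start=2):
                try:
                    v = float(cell)
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: non-numeric cell {cell!r} in column {col}"
                    ) from None
                if math.isnan(v) or math.isinf(v):
                    raise ParseError(f"line {lineno}: non-finite cell in column {col}")
                if v < 0:
                    raise ParseError(
                        f"line {lineno}: negative value {cell} in column {col}"
                    )
                values.append(v)
            gene_ids.append(gene_id)
            r_rows.append(values[:n])
            g_rows.append(values[n:])
    if not header_seen:
        raise ParseError("empty file: no header line found")
    if not gene_ids:
        raise ParseError("no data rows found")
    return gene_ids, np.asarray(r_rows), np.asarray(g_rows)


def write_paired_matrix(path, gene_ids, R, G) -> None:
    """Write a matrix in the native layout, with a header comment naming the
    column convention (reference block first, then test block)."""
    R = np.asarray(R)
    G = np.asarray(G)
    n = R.shape[1]
    with open(path, "w", newline="") as fh:
        fh.write("# paired expression matrix: reference block R_1..R_n, then test block G_1..G_n\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id"] + [f"R_{i+1}" for i in range(n)] + [f"G_{i+1}" for i in range(n)])
        for gid, r_row, g_row in zip(gene_ids, R, G):
            writer.writerow([gid] + [_fmt(v) for v in r_row] + [_fmt(v) for v in g_row])


def _fmt(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, str):
        return v
    if v is None:
        return NA
    f = float(v)
    if math.isnan(f):
        return NA
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return f"{f:.6g}"


def write_results(table: pd.DataFrame, path) -> None:
    """Serialize a per-gene results table as TSV.

    Column order is fixed, floats are printed at 6 significant digits, and
    undefined fields use the ``NA`` sentinel; rewriting the same rows yields
    a byte-identical file.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    cols = [c for c in RESULT_COLUMNS if c in table.columns]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for _, row in table[cols].iterrows():
            writer.writerow([_fmt(row[c]) for c in cols])


def read_results(path) -> pd.DataFrame:
    """Read a results TSV back (NA sentinel -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
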