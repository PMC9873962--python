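"""Shared file dialects: TSV expression matrices and CSV record tables.

Matrices are tab-separated with a header row of sample ids and miRNA ids in
the first column (tab-safe names). Record tables are plain CSV with a
mandatory header. Everything is UTF-8 with '.' as the decimal mark; floats
round-trip at 12 significant digits.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

__all__ = [
    "ParseError",
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _check_rectangular(path: Path, sep: str) -> None:
    width = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n = line.rstrip("\n").count(sep) + 1
            if width is None:
                width = n
            elif n != width:
                raise ParseError(
                    f"{path}: line {lineno} has {n} fields, expected {width}"
                )
    if width is None:
        raise ParseError(f"{path}: empty file")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a miRNA-by-sample intensity matrix from TSV.

    Returns a float DataFrame indexed by miRNA id with sample-id columns.
    Raises :class:`ParseError` for empty, ragged or non-numeric input,
    naming the first offending line.
    """
    path = Path(path)
    _check_rectangular(path, "\t")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: matrix has no sample columns")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index.get_loc(df.index[bad][0])
            raise ParseError(
                f"{path}: non-numeric cell in column {col!r}, line {row + 2}"
            )
    if df.isna().any().any():
        raise ParseError(f"{path}: missing cells are not allowed")
    return df.astype(float)


def write_matrix(m: pd.DataFrame, path: str | Path) -> None:
    """Write an intensity matrix as TSV with 12-significant-digit floats."""
    m.to_csv(path, sep="\t", float_format="%.12g", index_label="miRNA")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV record table (design, echo, survival, truth)."""
    path = Path(path)
    _check_rectangular(path, ",")
    return pd.read_csv(path)


def write_table(t: pd.DataFrame, path: str | Path) -> None:
    t.to_csv(path, index=False, float_format="%.12g")


def matrix_to_string(m: pd.DataFrame) -> str:
    buf = _io.StringIO()
    m.to_csv(buf, sep="\t", float_format="%.12g", index_label="miRNA")
    return buf.getvalue()
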