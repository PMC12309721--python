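"""Count-matrix containers and plain-text I/O.

The central container is :class:`CountMatrix`, a dense genes x columns matrix of
non-negative raw counts where columns are either bulk samples or single cells.
Dense TSV/CSV (genes as rows, first column gene ids, header row of column ids)
and CellRanger-style MatrixMarket triplet directories are supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """An input violates a structural invariant (negatives, duplicate ids, ...)."""


class ParseError(ValueError):
    """A file could not be parsed into a matrix."""


_VERSION_SUFFIX = re.compile(r"\.\d+$")


def strip_gene_version(gene_id: str) -> str:
    """Drop a trailing Ensembl-style version suffix (``ENSG...12.5`` -> ``ENSG...12``)."""
    return _VERSION_SUFFIX.sub("", gene_id)


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} ids: {dupes[:10]}")
    return ids


@dataclass
class CountMatrix:
    """Genes x columns matrix of non-negative counts with string identifiers.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows).
    column_ids
        Ordered, unique sample or cell identifiers (columns).
    values
        Array of shape ``(len(gene_ids), len(column_ids))``; must be finite and
        non-negative.
    """

    gene_ids: list[str]
    column_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.column_ids = _check_unique(self.column_ids, "column")
        self.values = np.asarray(self.values, dtype=np.float64)
        if not self.gene_ids or not self.column_ids:
            raise ValidationError("matrix must have at least one gene and one column")
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("matrix contains non-finite values")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value at gene {self.gene_ids[i]!r}, column {self.column_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            column_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=np.float64),
        )

    def subset_columns(self, column_ids: list[str]) -> "CountMatrix":
        idx = {c: j for j, c in enumerate(self.column_ids)}
        cols = [idx[c] for c in column_ids]
        return CountMatrix(list(self.gene_ids), list(column_ids), self.values[:, cols])


@dataclass
class NormalizedMatrix(CountMatrix):
    """A CountMatrix whose values went through a named normalization scheme."""

    scheme: str = "CPM"  # one of {CPM, TPM, MODEL_INPUT}


@dataclass
class GeneLengths:
    """Mapping of gene id to gene length in bases; all lengths strictly positive."""

    lengths: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = [g for g, l in self.lengths.items() if not (l > 0)]
        if bad:
            raise ValidationError(f"non-positive gene lengths for: {bad[:10]}")

    def __getitem__(self, gene_id: str) -> float:
        return self.lengths[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.lengths

    def vector_for(self, gene_ids: list[str]) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self.lengths]
        if missing:
            raise ValidationError(
                f"missing gene lengths for {len(missing)} genes, e.g. {missing[:10]}"
            )
        return np.array([self.lengths[g] for g in gene_ids], dtype=np.float64)


def read_gene_lengths(path: str | Path) -> GeneLengths:
    """Read a two-column TSV (gene_id, length in bases), with or without a header."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    # tolerate a header line
    try:
        float(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    try:
        lengths = {str(g): float(l) for g, l in zip(df.iloc[:, 0], df.iloc[:, 1])}
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric length value ({exc})") from exc
    return GeneLengths(lengths)


def write_gene_lengths(lengths: GeneLengths, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlength\n")
        for g, l in lengths.lengths.items():
            fh.write(f"{g}\t{l:g}\n")


def _read_dense(path: Path, sep: str, transposed: bool) -> CountMatrix:
    try:
        # round_trip parsing so write->read preserves values bit for bit
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as exc:  # pandas raises many flavours; surface file + cause
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate identifiers")
    non_numeric = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
    if len(non_numeric):
        bad_col = non_numeric[0]
        bad_rows = df.index[pd.to_numeric(df[bad_col], errors="coerce").isna()]
        raise ParseError(
            f"{path}: non-numeric value in column {bad_col!r}"
            + (f" at row {bad_rows[0]!r}" if len(bad_rows) else "")
        )
    if transposed:
        df = df.T
    return CountMatrix.from_frame(df)


_MTX_NAMES = ("matrix.mtx",)
_FEATURE_NAMES = ("features.tsv", "genes.tsv", "features.txt")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.txt")


def _find_one(directory: Path, names: tuple[str, ...], what: str) -> Path:
    for name in names:
        cand = directory / name
        if cand.exists():
            return cand
    raise ParseError(f"{directory}: no {what} file (looked for {', '.join(names)})")


def _read_mtx_dir(directory: Path, transposed: bool) -> CountMatrix:
    mtx = _find_one(directory, _MTX_NAMES, "matrix")
    feats = _find_one(directory, _FEATURE_NAMES, "features")
    bars = _find_one(directory, _BARCODE_NAMES, "barcodes")
    try:
        mat = scipy.io.mmread(mtx)
    except Exception as exc:
        raise ParseError(f"{mtx}: {exc}") from exc
    dense = np.asarray(
        mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
    )
    gene_ids = [line.split("\t")[0].strip() for line in feats.read_text().splitlines() if line.strip()]
    col_ids = [line.split("\t")[0].strip() for line in bars.read_text().splitlines() if line.strip()]
    if transposed:
        dense = dense.T
    if dense.shape != (len(gene_ids), len(col_ids)):
        raise ParseError(
            f"{directory}: matrix shape {dense.shape} does not match "
            f"{len(gene_ids)} features x {len(col_ids)} barcodes"
        )
    return CountMatrix(gene_ids, col_ids, dense)


def read_count_matrix(
    path: str | Path,
    fmt: str | None = None,
    transposed: bool = False,
    strip_versions: bool = False,
) -> CountMatrix:
    """Read a count matrix from TSV, CSV, or a MatrixMarket triplet directory.

    Parameters
    ----------
    path
        File (dense) or directory (sparse triplet: matrix.mtx + features + barcodes).
    fmt
        One of ``tsv``, ``csv``, ``mtx``; inferred from the path when ``None``.
    transposed
        Set when the on-disk orientation is columns-as-genes.
    strip_versions
        Strip Ensembl version suffixes from gene ids after reading; duplicates
        created by stripping are a validation error.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "mtx"
        elif path.suffix.lower() == ".csv":
            fmt = "csv"
        else:
            fmt = "tsv"
    if fmt == "mtx":
        m = _read_mtx_dir(path, transposed)
    elif fmt in ("tsv", "csv"):
        if not path.exists():
            raise FileNotFoundError(path)
        m = _read_dense(path, "\t" if fmt == "tsv" else ",", transposed)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if strip_versions:
        m = CountMatrix(
            [strip_gene_version(g) for g in m.gene_ids], m.column_ids, m.values
        )
    return m


def write_count_matrix(m: CountMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write a dense TSV/CSV (genes as rows). Values use shortest round-trip repr,
    so write-then-read preserves them bit for bit."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "\t" if fmt == "tsv" else ","
    with open(path, "w") as fh:
        fh.write("gene_id" + sep + sep.join(m.column_ids) + "\n")
        for i, g in enumerate(m.gene_ids):
            row = m.values[i]
            fh.write(g + sep + sep.join(repr(float(v)) for v in row) + "\n")
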