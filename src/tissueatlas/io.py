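"""Expression-matrix I/O, global transforms and filters, and run-summary statistics.

The pipeline's universal currency is a gene x tissue matrix of non-negative
TPM (transcripts per million) values, exchanged as plain UTF-8 TSV with a
``gene_id`` header cell, tissue labels across the header row and gene
identifiers in the first column.  Sequencing run summaries (read classes with
base and read counts) are a second, much smaller tabular input from which
derived statistics such as mean read length are computed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "MatrixFormatError",
    "MatrixValidationError",
    "read_expression_matrix",
    "write_expression_matrix",
    "log2_transform",
    "filter_min_tpm",
    "read_run_summary",
    "summarize_run",
]


class MatrixFormatError(ValueError):
    """The file does not conform to the expression-matrix TSV dialect."""


class MatrixValidationError(ValueError):
    """The matrix content violates an invariant (negative, NaN, duplicate labels)."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated gene x tissue expression matrix.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and tissue labels as
        columns.  Values must be finite and non-negative.  At least two
        tissues are required; a zero-gene matrix is permitted only as the
        (warned) result of an over-aggressive expression filter.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("ExpressionMatrix requires a pandas DataFrame")
        if df.shape[1] < 2:
            raise MatrixValidationError("expression matrix needs at least 2 tissues")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate tissue labels: {dups[:5]}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise MatrixValidationError("expression values must be numeric")
        if values.size:
            bad = ~np.isfinite(values) | (values < 0)
            if bad.any():
                gi, ti = map(int, np.argwhere(bad)[0])
                raise MatrixValidationError(
                    f"invalid expression value {values[gi, ti]!r} at "
                    f"gene {df.index[gi]!r}, tissue {df.columns[ti]!r} "
                    "(values must be finite and >= 0)"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissue_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.data.shape[1]

    def subset(self, gene_ids) -> "ExpressionMatrix":
        """Row-subset by gene id, preserving the requested order."""
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)])


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a gene x tissue TPM matrix from TSV.

    Expects a header row of tissue labels (first cell is the gene-id column
    name, conventionally ``gene_id``) and one row per gene.  Row and column
    order are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # malformed TSV
        raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] < 1:
        raise MatrixFormatError(f"{path}: no gene rows")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        # locate the first offending cell for the error message
        for c in non_numeric:
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = coerced.isna() & df[c].notna()
            if bad.any():
                gene = df.index[bad.argmax()]
                raise MatrixValidationError(
                    f"{path}: non-numeric value {df.loc[gene, c]!r} at "
                    f"gene {gene!r}, tissue {c!r}"
                )
        df[non_numeric] = df[non_numeric].apply(pd.to_numeric)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write the matrix as TSV (UTF-8, tab delimiter, no quoting).

    Values are written at full float precision so that write-then-read is an
    identity on labels and values.
    """
    df = m.data.copy()
    df.index.name = df.index.name or "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Replace every value x by log2(x + pseudocount).

    A pseudocount of 0 is only admissible when the matrix has no zeros.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    values = m.values
    if pseudocount == 0 and (values == 0).any():
        raise ValueError("pseudocount 0 with zero values present: log2 undefined")
    out = np.log2(values + pseudocount)
    return ExpressionMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns))


def filter_min_tpm(m: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Retain genes whose maximum TPM across tissues is >= ``threshold``.

    The boundary is inclusive and gene order is preserved.  An empty result
    is returned (with a warning) rather than raised.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if m.n_genes == 0:
        return m
    keep = m.data.max(axis=1) >= threshold
    if not keep.any():
        warnings.warn(
            f"filter_min_tpm: no gene reaches TPM {threshold}; returning empty matrix",
            stacklevel=2,
        )
    return ExpressionMatrix(m.data.loc[keep])


# ---------------------------------------------------------------------------
# Sequencing run summaries


def read_run_summary(path) -> pd.DataFrame:
    """Read a run-summary TSV with columns read_class, total_bases, read_count.

    total_bases and read_count may be blank for classes where the upstream
    report omits them.
    """
    df = pd.read_csv(path, sep="\t", dtype={"read_class": str})
    required = {"read_class"}
    if not required.issubset(df.columns):
        raise MatrixFormatError(f"run summary needs columns {sorted(required)}")
    for col in ("total_bases", "read_count"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def summarize_run(
    rs: pd.DataFrame,
    ratio_pairs: tuple[tuple[str, str], ...] = (("flnc", "ccs"),),
) -> dict:
    """Derive per-class mean read lengths and read-class count ratios.

    For each class with both ``total_bases`` and ``read_count`` present, the
    mean length is ``round(total_bases / read_count)`` in bp (integer, as
    sequencing reports print it).  For each (numerator, denominator) pair in
    ``ratio_pairs`` — matched case-insensitively against read-class name
    prefixes — the percentage ratio of read counts is reported rounded to two
    decimals, e.g. full-length non-chimeric over circular-consensus reads.
    """
    rs = rs.copy()
    rs["_key"] = rs["read_class"].str.strip().str.lower()
    mean_lengths: dict[str, int] = {}
    for _, row in rs.iterrows():
        tb = row.get("total_bases")
        rc = row.get("read_count")
        if pd.notna(tb) and pd.notna(rc):
            if rc == 0:
                raise ZeroDivisionError(
                    f"read class {row['read_class']!r} has zero read_count"
                )
            mean_lengths[str(row["read_class"])] = int(round(float(tb) / float(rc)))
    ratios: dict[str, float] = {}
    for num, den in ratio_pairs:
        num_rows = rs[rs["_key"].str.startswith(num.lower())]
        den_rows = rs[rs["_key"].str.startswith(den.lower())]
        if num_rows.empty or den_rows.empty:
            raise KeyError(f"ratio classes {num!r}/{den!r} not both present")
        num_count = float(num_rows.iloc[0]["read_count"])
        den_count = float(den_rows.iloc[0]["read_count"])
        if den_count == 0:
            raise ZeroDivisionError(f"read class {den!r} has zero read_count")
        ratios[f"{num.upper()}/{den.upper()}"] = round(100.0 * num_count / den_count, 2)
    return {"mean_length_bp": mean_lengths, "count_ratio_percent": ratios}
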