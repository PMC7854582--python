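"""Reading, writing and validation of expression matrices and result tables.

Expression data travel as a pandas DataFrame with genes in rows (index =
upper-cased gene symbols) and samples in columns, holding finite,
non-negative FPKM-like abundances.  Sample metadata is a pandas Series
mapping sample id -> group label.  Supported on-disk formats: delimited
text (TSV/CSV, header row of sample ids, first column = gene symbol) and
GCT 1.2 / 1.3.
"""

from __future__ import annotations

import io as _stdio
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genes import HoxGeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "validate_expression",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "subset_to_gene_set",
    "write_table",
    "read_table",
]

# Fewer genes than this and a 39-gene Pearson correlation stops being
# meaningful; `intersect` subsetting refuses to go below it.
MIN_GENES_FOR_CORRELATION = 10


class FormatError(ValueError):
    """Malformed file structure (header, dimensions, GCT version line)."""


class ValidationError(ValueError):
    """Structurally parsable data violating an expression-matrix invariant."""


def validate_expression(m: pd.DataFrame) -> pd.DataFrame:
    """Check ExpressionMatrix invariants; returns `m` unchanged on success.

    Invariants: at least one gene and one sample; unique upper-cased gene
    symbols; unique sample ids; every value finite and non-negative.
    """
    if not isinstance(m, pd.DataFrame):
        raise ValidationError("expression matrix must be a DataFrame")
    if m.shape[0] < 1 or m.shape[1] < 1:
        raise ValidationError("expression matrix needs at least 1 gene and 1 sample")
    upper = m.index.astype(str).str.upper()
    if upper.duplicated().any():
        dups = sorted(set(upper[upper.duplicated()]))
        raise ValidationError(f"duplicate gene symbols after case-folding: {dups}")
    if m.columns.duplicated().any():
        dups = sorted(set(m.columns[m.columns.duplicated()]))
        raise ValidationError(f"duplicate sample ids: {dups}")
    values = m.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = m.columns[[not np.issubdtype(d, np.number) for d in m.dtypes]]
        raise ValidationError(f"non-numeric values in columns: {list(bad)}")
    finite = np.isfinite(values)
    if not finite.all():
        g, s = np.argwhere(~finite)[0]
        raise ValidationError(
            f"non-finite value at gene {m.index[g]!r}, sample {m.columns[s]!r}"
        )
    neg = values < 0
    if neg.any():
        g, s = np.argwhere(neg)[0]
        raise ValidationError(
            f"negative value {values[g, s]} at gene {m.index[g]!r}, "
            f"sample {m.columns[s]!r}"
        )
    return m


def _finalize(m: pd.DataFrame) -> pd.DataFrame:
    m = m.copy()
    m.index = m.index.astype(str).str.strip().str.upper()
    m.index.name = "gene"
    m.columns = m.columns.astype(str)
    try:
        m = m.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell in expression matrix: {exc}") from exc
    return validate_expression(m)


def read_expression(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read an expression matrix from TSV, CSV or GCT.

    `format` is inferred from the file suffix when omitted.  Gene symbols
    are upper-cased; the GCT Description column is discarded.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".gct": "gct"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise FormatError(f"cannot infer format from suffix of {path.name!r}")
    if format not in {"tsv", "csv", "gct"}:
        raise FormatError(f"unknown expression format {format!r}")
    if format == "gct":
        return _read_gct(path)
    sep = "\t" if format == "tsv" else ","
    try:
        m = pd.read_csv(path, sep=sep, index_col=0, header=0,
                        float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed {format} file {path}: {exc}") from exc
    if m.columns.size == 0:
        raise FormatError(f"{path}: header row with sample ids is required")
    return _finalize(m)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in {"#1.2", "#1.3"}:
            raise FormatError(f"{path}: unsupported GCT version line {version!r}")
        dims = fh.readline().strip().split("\t")
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed GCT dimensions line")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer GCT dimensions {dims}") from exc
        # 1.2 has a fixed Description column; 1.3 declares row/column
        # metadata counts in dims fields 3-4.  All metadata is ignored.
        if version == "#1.3":
            n_row_meta = int(dims[2]) if len(dims) > 2 else 0
            n_col_meta = int(dims[3]) if len(dims) > 3 else 0
        else:
            n_row_meta, n_col_meta = 1, 0
        body = pd.read_csv(_stdio.StringIO(fh.read()), sep="\t", header=0,
                           float_precision="round_trip")
    if body.shape[1] != 1 + n_row_meta + n_samples:
        raise FormatError(
            f"{path}: GCT header has {body.shape[1]} columns, expected "
            f"{1 + n_row_meta + n_samples}"
        )
    body = body.iloc[n_col_meta:]  # drop column-metadata rows (1.3)
    m = body.set_index(body.columns[0]).iloc[:, n_row_meta:]
    if m.shape != (n_genes, n_samples):
        raise FormatError(
            f"{path}: GCT declares {n_genes}x{n_samples} but body is "
            f"{m.shape[0]}x{m.shape[1]}"
        )
    return _finalize(m)


def write_expression(m: pd.DataFrame, path: str | Path, format: str | None = None) -> Path:
    """Write an expression matrix as TSV, CSV or GCT (inferred from suffix)."""
    path = Path(path)
    validate_expression(m)
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".gct": "gct"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.shape[0]}\t{m.shape[1]}\n")
            fh.write("Name\tDescription\t" + "\t".join(m.columns) + "\n")
            for gene, row in m.iterrows():
                cells = "\t".join(repr(float(v)) for v in row)
                fh.write(f"{gene}\tna\t{cells}\n")
    else:
        sep = "\t" if format == "tsv" else ","
        out = m.copy()
        out.index.name = "gene"
        out.to_csv(path, sep=sep, float_format=None)
    return path


def read_metadata(path: str | Path) -> pd.Series:
    """Read a two-column sample_id<TAB>label table with header."""
    t = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if t.shape[1] < 2:
        raise FormatError(f"{path}: metadata needs sample_id and label columns")
    sample_ids = t.iloc[:, 0].str.strip()
    labels = t.iloc[:, 1].str.strip()
    if sample_ids.duplicated().any():
        dups = sorted(set(sample_ids[sample_ids.duplicated()]))
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    if (sample_ids == "").any() or sample_ids.isna().any():
        raise ValidationError("empty sample id in metadata")
    if (labels == "").any() or labels.isna().any():
        raise ValidationError("empty group label in metadata")
    meta = pd.Series(labels.to_numpy(), index=pd.Index(sample_ids, name="sample_id"))
    meta.name = "label"
    return meta


def write_metadata(meta: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    out = meta.rename("label").rename_axis("sample_id")
    out.to_csv(path, sep="\t")
    return path


def subset_to_gene_set(
    m: pd.DataFrame, gs: HoxGeneSet, policy: str = "strict"
) -> pd.DataFrame:
    """Restrict an expression matrix to the HOX gene set, in gene-set order.

    Symbols are matched case-insensitively after applying the legacy-alias
    map.  `strict` demands all 39 genes; `intersect` keeps the present
    subset (warning logged) but refuses fewer than
    ``MIN_GENES_FOR_CORRELATION`` genes.
    """
    if policy not in {"strict", "intersect"}:
        raise ValueError(f"unknown subset policy {policy!r}")
    validate_expression(m)
    canonical = {gs.canonicalize(g): g for g in m.index}
    present = [g for g in gs.genes if g in canonical]
    missing = [g for g in gs.genes if g not in canonical]
    if policy == "strict" and missing:
        raise ValidationError(f"missing HOX genes under strict policy: {missing}")
    if len(present) < MIN_GENES_FOR_CORRELATION:
        raise ValidationError(
            f"only {len(present)} of {len(gs)} HOX genes present; "
            f"need >= {MIN_GENES_FOR_CORRELATION} for a meaningful correlation"
        )
    if missing:
        logger.warning("subset: %d HOX genes absent: %s", len(missing), missing)
    out = m.loc[[canonical[g] for g in present]]
    out.index = pd.Index(present, name="gene")
    return out


def write_table(t: pd.DataFrame, path: str | Path) -> Path:
    """Write a code table or score matrix as TSV with >= 6 significant digits."""
    if not isinstance(t, pd.DataFrame) or t.size == 0:
        raise ValidationError("refusing to write an empty table")
    path = Path(path)
    t.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by `write_table` (row labels in column 1)."""
    return pd.read_csv(path, sep="\t", index_col=0)
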