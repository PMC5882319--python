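"""Tab-delimited readers and writers for expression and clinical data.

The expression dialect is plain TSV: first column probe id, header row of
sample ids.  A GCT-flavoured reader (version line ``#1.2`` followed by a
dimensions line) is provided for convenience; the writer always emits
plain TSV.  Floats are written with 17 significant digits so that a
write/read cycle round-trips bit-identically.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_batch",
    "write_batch",
    "read_clinical",
    "write_clinical",
]

FLOAT_FMT = "%.17g"


def read_expression(path, batch_path=None) -> ExpressionMatrix:
    """Read a probe-by-sample TSV (or GCT) matrix, optionally with batches."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        values = pd.read_csv(path, sep="\t", skiprows=2, index_col=0, float_precision="round_trip")
        # GCT carries a Description column after the id column
        if values.columns[0].lower() in {"description", "desc"}:
            values = values.drop(columns=values.columns[0])
    else:
        values = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    batch = read_batch(batch_path) if batch_path is not None else None
    return ExpressionMatrix(values, batch)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_batch(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "batch" not in df.columns:
        raise ValueError("batch table must have a 'batch' column")
    s = df["batch"].astype(str)
    s.index = s.index.astype(str)
    return s


def write_batch(batch: pd.Series, path) -> None:
    df = batch.rename("batch").to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_clinical(path) -> ClinicalTable:
    """Read the clinical TSV keyed by ``sample_id``.

    Required columns: ``time_years``, ``event``.  Optional covariates:
    ``who_grade``, ``mitotic_category``, ``simpson_grade``, ``sex``,
    ``location``; empty cells become missing values.
    """
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype={"sample_id": str},
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    for col in ("who_grade", "mitotic_category", "simpson_grade", "sex", "location"):
        if col in df.columns:
            df[col] = df[col].astype("string").astype(object)
            df.loc[df[col].isna(), col] = None
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
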