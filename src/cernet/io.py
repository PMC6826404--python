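"""Readers and writers for the plain-text table dialects used by the pipeline.

All files are UTF-8, tab-delimited:

* count matrix  -- row 1 = sample ids, column 1 = gene id, integer cells
* group map     -- columns ``sample_id``, ``group``
* annotations   -- columns ``gene_id``, ``biotype``, ``length_bp`` (empty for miRNA)
* generic stage tables (DE records, correlation records, triples, enrichment)
  are written with :func:`write_table` using a fixed float format so reruns
  are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BIOTYPES, CountMatrix, ExpressionMatrix
from .errors import ParseError

FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a stage table deterministically (tab-separated, fixed floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(matrix: CountMatrix | pd.DataFrame, path: str | Path) -> Path:
    df = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")
    return path


def read_counts(path: str | Path, groups: pd.Series | None = None) -> CountMatrix | pd.DataFrame:
    """Read a count matrix; wrap into :class:`CountMatrix` when groups are given."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    if groups is None:
        return df
    return CountMatrix(df.astype(np.int64), groups)


def write_groups(groups: pd.Series, path: str | Path) -> Path:
    df = pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()})
    return write_table(df, path)


def read_groups(path: str | Path) -> pd.Series:
    df = read_table(path)
    if list(df.columns) != ["sample_id", "group"]:
        raise ParseError(f"{path}: expected columns sample_id, group; got {list(df.columns)}")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> Path:
    cols = ["gene_id", "biotype", "length_bp"]
    df = annotations[cols].copy()
    # keep miRNA lengths as empty cells rather than "nan"
    df["length_bp"] = df["length_bp"].astype("Int64")
    return write_table(df, path)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    expected = ["gene_id", "biotype", "length_bp"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}; got {list(df.columns)}")
    bad = ~df["biotype"].isin(BIOTYPES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
        raise ParseError(f"{path}:{row}: unknown biotype {df.loc[bad.idxmax(), 'biotype']!r}")
    df["length_bp"] = df["length_bp"].astype("Int64")
    return df


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(
        path, sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT, lineterminator="\n"
    )
    return path


def read_expression(path: str | Path, unit: str, groups: pd.Series | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return ExpressionMatrix(df, unit, groups)
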