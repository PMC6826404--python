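"""Core in-memory containers: raw count matrices and normalized expression.

Matrices are thin wrappers around a pandas DataFrame (genes in rows, samples
in columns) that enforce the invariants the pipeline relies on: counts are
non-negative integers, identifiers are unique, and the sample->group map
names exactly two conditions (e.g. undifferentiated vs differentiated
preadipocytes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

FPKM = "FPKM"
TPM = "TPM"

#: biotypes recognised throughout the pipeline
BIOTYPES = ("lncRNA", "miRNA", "mRNA")


@dataclass
class CountMatrix:
    """Raw fragment/tag counts, genes x samples, with a two-group design.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample; values must
        be non-negative integers.
    groups
        Series mapping each sample id (index) to its group label. Exactly two
        distinct labels are required and every sample column must be mapped.
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ParameterError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ParameterError("duplicate sample ids in count matrix")
        values = self.counts.to_numpy()
        if values.size:
            if np.any(values < 0):
                raise ParameterError("counts must be non-negative")
            if not np.allclose(values, np.round(values)):
                raise ParameterError("counts must be integral")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ParameterError(f"samples without group label: {missing}")
        if self.groups.nunique() != 2:
            raise ParameterError(
                f"exactly two group labels required, got {sorted(self.groups.unique())}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def group_labels(self) -> tuple[str, str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return tuple(seen)  # type: ignore[return-value]

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class ExpressionMatrix:
    """Normalized expression (FPKM or TPM), genes x samples."""

    values: pd.DataFrame
    unit: str
    groups: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.unit not in (FPKM, TPM):
            raise ParameterError(f"unit must be FPKM or TPM, got {self.unit!r}")
        arr = self.values.to_numpy()
        if arr.size and np.any(arr < 0):
            raise ParameterError("expression values must be non-negative")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns
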