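"""Within-sample normalization of raw counts.

Long transcripts (lncRNA, mRNA) are normalized to FPKM, which corrects for
both sequencing depth and transcript length::

    FPKM = 10^9 * C / (N * L)

where C is the fragment count for the transcript in a sample, N the
sample's total aligned fragments (column sum of the supplied matrix) and L
the transcript length in bases. miRNA tag counts are normalized to TPM
(tags per million), which is length-free::

    TPM = C / (column total) * 10^6

Between-sample normalization (TMM and relatives) is deliberately out of
scope; these are the plain within-sample definitions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import FPKM, TPM, CountMatrix, ExpressionMatrix
from .errors import AnnotationError, DegenerateInputError


def _library_sizes(counts: pd.DataFrame) -> pd.Series:
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DegenerateInputError(
            f"all-zero count column(s): {list(zero.index)}; library size undefined"
        )
    return totals.astype(float)


def fpkm(counts: CountMatrix, annotations: pd.DataFrame) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    Parameters
    ----------
    counts
        Raw counts with at least one nonzero value per sample.
    annotations
        DataFrame with columns ``gene_id`` and ``length_bp`` covering every
        gene in ``counts``; lengths must be positive.
    """
    lengths = annotations.set_index("gene_id")["length_bp"]
    lengths = lengths.reindex(counts.gene_ids)
    missing = lengths[lengths.isna()]
    if len(missing):
        raise AnnotationError(f"no transcript length for gene(s): {list(missing.index)}")
    lengths = lengths.astype(float)
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])
        raise AnnotationError(f"non-positive transcript length for gene(s): {bad}")
    n = _library_sizes(counts.counts)
    # one rounding per cell: precompute 10^9 / (N * L) and scale the counts
    factor = 1e9 / np.outer(lengths.to_numpy(), n.to_numpy())
    values = counts.counts * factor
    return ExpressionMatrix(values, FPKM, counts.groups)


def tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Tags per million: depth-only normalization; every column sums to 10^6."""
    n = _library_sizes(counts.counts)
    values = 1e6 * counts.counts.div(n, axis=1)
    return ExpressionMatrix(values, TPM, counts.groups)
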