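"""ceRNA candidate construction: correlation filters and the shared-miRNA test.

The screen runs in three steps over differentially expressed genes:

1. predicted miRNA->target pairs (target = lncRNA or mRNA) are kept when the
   Spearman rank correlation of the two expression profiles across all
   samples is strictly below ``scc_mirna_target_max`` (default -0.7) — a
   miRNA should anti-correlate with a transcript it represses;
2. every DE-lncRNA x DE-mRNA pair is kept when its Spearman correlation is
   strictly above ``scc_lnc_mrna_min`` (default 0.9) — two transcripts
   competing for the same miRNAs should co-vary;
3. each surviving lncRNA-mRNA pair is tested for sharing more miRNAs than
   chance with the hypergeometric upper tail

       p = 1 - sum_{i=0}^{n-1} C(M,i) C(U-M, N-i) / C(U,N)

   where n is the number of miRNAs shared by the pair, M and N the numbers
   of (filter-passing) miRNAs targeting the lncRNA and the mRNA, and U the
   size of the miRNA universe. Pairs with p strictly below ``cerna_p_max``
   (default 0.05, uncorrected, matching the original screen) are accepted;
   one triple is emitted per shared miRNA.

The hypergeometric tail is computed with exact integer arithmetic, summing
the upper tail directly (no cancellation); by default U is the number of
miRNAs assayed, configurable to the differentially expressed subset.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .config import ThresholdConfig
from .containers import ExpressionMatrix
from .errors import DegenerateInputError, MissingIdError, ParameterError

logger = logging.getLogger(__name__)


def spearman(x, y) -> float:
    """Spearman rank correlation (mean ranks on ties).

    Raises :class:`DegenerateInputError` on a constant vector, where the
    correlation is undefined, rather than silently returning 0 or NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("spearman: vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise ParameterError(f"spearman: need at least 3 observations, got {len(x)}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("spearman: constant vector, correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    if len(set(rx)) == n and len(set(ry)) == n:
        # tie-free: the classical rank-difference identity is exact in floats
        # for small integer ranks, so values landing on a threshold compare
        # exactly against it
        d2 = float(np.sum((rx - ry) ** 2))
        return 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
    return float(stats.spearmanr(x, y).statistic)


def hypergeometric_p(n: int, M: int, N: int, U: int) -> float:
    """Upper-tail probability that at least ``n`` of ``N`` draws (without
    replacement) from a universe of ``U`` fall inside a marked subset of
    size ``M``. Exact integer arithmetic; n = 0 returns 1 by convention."""
    for name, v in (("n", n), ("M", M), ("N", N), ("U", U)):
        if int(v) != v or v < 0:
            raise ParameterError(f"hypergeometric_p: {name} must be a non-negative integer")
    n, M, N, U = int(n), int(M), int(N), int(U)
    if M > U or N > U:
        raise ParameterError(f"hypergeometric_p: M={M}, N={N} must not exceed U={U}")
    if n > min(M, N):
        raise ParameterError(f"hypergeometric_p: n={n} exceeds min(M, N)={min(M, N)}")
    if n == 0:
        return 1.0
    tail = sum(comb(M, i) * comb(U - M, N - i) for i in range(n, min(M, N) + 1) if N - i <= U - M)
    return float(Fraction(tail, comb(U, N)))


def _corr_records(
    pairs: list[tuple[str, str]],
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    predicate,
) -> pd.DataFrame:
    """Spearman over all samples for each (id_a, id_b); columns of ``expr_b``
    are aligned to ``expr_a``'s sample order."""
    samples = list(expr_a.sample_ids)
    if set(samples) != set(expr_b.sample_ids):
        raise ParameterError("expression matrices cover different sample sets")
    a_vals = expr_a.values
    b_vals = expr_b.values[samples]
    rows = []
    for id_a, id_b in pairs:
        if id_a not in a_vals.index:
            raise MissingIdError(f"id {id_a!r} absent from expression matrix")
        if id_b not in b_vals.index:
            raise MissingIdError(f"id {id_b!r} absent from expression matrix")
        scc = spearman(a_vals.loc[id_a].to_numpy(), b_vals.loc[id_b].to_numpy())
        rows.append((id_a, id_b, scc, len(samples), predicate(scc)))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "scc", "n_samples", "passed"])


def filter_mirna_targets(
    pairs: pd.DataFrame,
    mirna_expr: ExpressionMatrix,
    target_expr: ExpressionMatrix,
    thresholds: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Correlation-filter predicted miRNA->target pairs.

    ``pairs`` needs columns ``mirna_id`` and ``target_id``; the caller is
    expected to have restricted them to differentially expressed genes.
    ``passed`` is strict: scc < threshold (default -0.7).
    """
    thresholds = thresholds or ThresholdConfig()
    cut = thresholds.scc_mirna_target_max
    records = _corr_records(
        list(zip(pairs["mirna_id"], pairs["target_id"])),
        mirna_expr,
        target_expr,
        lambda s: s < cut,
    )
    return records.rename(columns={"id_a": "mirna_id", "id_b": "target_id"})


def filter_lnc_mrna(
    del_ids,
    dem_ids,
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    thresholds: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Score every DE-lncRNA x DE-mRNA pair; ``passed`` = scc > threshold
    (default 0.9, strict)."""
    thresholds = thresholds or ThresholdConfig()
    cut = thresholds.scc_lnc_mrna_min
    pairs = list(product(sorted(del_ids), sorted(dem_ids)))
    records = _corr_records(pairs, lnc_expr, mrna_expr, lambda s: s > cut)
    return records.rename(columns={"id_a": "lncrna_id", "id_b": "mrna_id"})


TRIPLE_COLUMNS = ["lncrna_id", "mirna_id", "mrna_id", "n", "M", "N", "U", "p_hyper", "accepted"]


def assemble_triples(
    mirna_lnc: pd.DataFrame,
    mirna_mrna: pd.DataFrame,
    lnc_mrna: pd.DataFrame,
    universe_size: int,
    thresholds: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Combine the three filtered record sets into candidate ceRNA triples.

    For each passing lncRNA-mRNA pair the shared miRNAs are counted on the
    *passing* miRNA-target records (M = passing miRNAs of the lncRNA, N = of
    the mRNA, n = shared); the pair-level hypergeometric p is replicated
    onto each (lncRNA, shared miRNA, mRNA) triple. ``universe_size`` is U.
    """
    thresholds = thresholds or ThresholdConfig()
    if mirna_lnc.empty or mirna_mrna.empty or lnc_mrna.empty:
        logger.warning("assemble_triples: empty input record set; no triples")
        return pd.DataFrame(columns=TRIPLE_COLUMNS)

    lnc_targets: dict[str, set[str]] = {}
    for _, row in mirna_lnc[mirna_lnc["passed"]].iterrows():
        lnc_targets.setdefault(row["target_id"], set()).add(row["mirna_id"])
    mrna_targets: dict[str, set[str]] = {}
    for _, row in mirna_mrna[mirna_mrna["passed"]].iterrows():
        mrna_targets.setdefault(row["target_id"], set()).add(row["mirna_id"])

    rows = []
    for _, row in lnc_mrna[lnc_mrna["passed"]].iterrows():
        lnc, mrna = row["lncrna_id"], row["mrna_id"]
        mi_l = lnc_targets.get(lnc, set())
        mi_m = mrna_targets.get(mrna, set())
        shared = sorted(mi_l & mi_m)
        if not shared:
            continue
        n, M, N = len(shared), len(mi_l), len(mi_m)
        p = hypergeometric_p(n, M, N, universe_size)
        accepted = p < thresholds.cerna_p_max
        for mi in shared:
            rows.append((lnc, mi, mrna, n, M, N, universe_size, p, accepted))
    triples = pd.DataFrame(rows, columns=TRIPLE_COLUMNS)
    if triples.empty:
        logger.warning("assemble_triples: no lncRNA-mRNA pair shares a passing miRNA")
    return triples.sort_values(["lncrna_id", "mirna_id", "mrna_id"], ignore_index=True)
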