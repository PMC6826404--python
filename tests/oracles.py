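"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where possible, the
libraries) they check: the hypergeometric tail is counted by enumerating
draws, Spearman is ranked by hand and pushed through the plain Pearson
formula, and Benjamini-Hochberg is the textbook step-up written directly.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def hypergeom_upper_tail_by_enumeration(n: int, M: int, N: int, U: int) -> float:
    """P(overlap >= n) by enumerating every size-N draw from a size-U urn
    whose first M elements are marked."""
    marked = set(range(M))
    hits = total = 0
    for draw in combinations(range(U), N):
        total += 1
        if len(marked.intersection(draw)) >= n:
            hits += 1
    return hits / total if total else 1.0


def overlap_tally_by_enumeration(M: int, N: int, U: int) -> dict[int, int]:
    """Counts of draws by overlap size; one enumeration serves every n."""
    marked = set(range(M))
    tally: dict[int, int] = {}
    for draw in combinations(range(U), N):
        k = len(marked.intersection(draw))
        tally[k] = tally.get(k, 0) + 1
    return tally


def rank_with_mean_ties(x) -> np.ndarray:
    """Average ranks computed from first principles (1-based)."""
    x = np.asarray(x, dtype=float)
    ranks = np.empty(len(x))
    for i, xi in enumerate(x):
        less = np.sum(x < xi)
        equal = np.sum(x == xi)
        # mean of the rank positions occupied by the tied block
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_by_rank_pearson(x, y) -> float:
    """Pearson correlation of mean ranks, written out longhand."""
    rx = rank_with_mean_ties(x)
    ry = rank_with_mean_ties(y)
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))


def bh_stepup(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = p[idx] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted
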