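"""Gene-set over-representation analysis against user-supplied sets.

A generic replacement for database-bound GO/KEGG enrichment: the caller
provides gene sets (GMT format) and a background universe — typically every
gene that entered differential-expression testing for the relevant biotype.
For a query of ``n_query`` background genes hitting ``k`` members of a set
of size ``K`` (within the background of ``N_bg``), the p-value is the
hypergeometric upper tail P(X >= k), the same arithmetic core as the
shared-miRNA ceRNA test. Significance follows the raw p < 0.05 gate of the
original screen; BH FDR is reported alongside but does not gate (flip it
yourself if you prefer the stricter convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cerna import hypergeometric_p
from .config import ThresholdConfig
from .errors import ParameterError, ParseError


@dataclass
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ParameterError(f"gene set {self.set_id!r} has no members")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT (one set per line: set_id <tab> description <tab> members...)."""
    path = Path(path)
    sets = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs id, description, >=1 member")
        members = frozenset(m for m in fields[2:] if m)
        if not members:
            raise ParseError(f"{path}:{lineno}: gene set {fields[0]!r} has no members")
        sets.append(GeneSet(set_id=fields[0], name=fields[1], members=members))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "\t".join([s.set_id, s.name, *sorted(s.members)]) for s in sets
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


RESULT_COLUMNS = ["set_id", "name", "k", "K", "n_query", "N_bg", "p_value", "fdr", "significant"]


def overrepresentation(
    query,
    gene_sets: list[GeneSet],
    background,
    thresholds: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    ``query`` must be a subset of ``background``; each set is intersected
    with the background before testing. Results are ordered by p-value.
    """
    thresholds = thresholds or ThresholdConfig()
    query = set(query)
    background = set(background)
    stray = sorted(query - background)
    if stray:
        raise ParameterError(f"query gene(s) not in background: {stray}")
    n_bg, n_query = len(background), len(query)
    rows = []
    for gs in gene_sets:
        members = gs.members & background
        if not members:
            continue
        k = len(query & members)
        p = hypergeometric_p(k, len(members), n_query, n_bg)
        rows.append((gs.set_id, gs.name, k, len(members), n_query, n_bg, p))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:7])
    if len(df):
        df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["significant"] = df["p_value"] < thresholds.enrichment_p_max
        df = df.sort_values(["p_value", "set_id"], ignore_index=True)
    else:
        df["fdr"] = []
        df["significant"] = []
    return df
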