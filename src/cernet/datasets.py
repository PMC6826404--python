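"""Bundled reference data: the published crucial ceRNA interactions.

The chicken preadipocyte differentiation screen this package re-implements
reported twelve crucial lncRNA-miRNA-mRNA interactions, built around four
miRNAs: three with literature support for a role in adipocyte
differentiation (gga-miR-128-1-5p, gga-miR-146a-3p, gga-miR-135a-5p) and
gga-miR-6615-3p, which was both highly connected and highly expressed in
that network. The printed list is reproduced here verbatim as a small
in-package fixture so the network-analysis operations can be exercised
against published numbers without any external data.
"""

from __future__ import annotations

import pandas as pd

#: (lncRNA, miRNA, mRNA) — the twelve reported crucial interactions
CRUCIAL_INTERACTIONS: tuple[tuple[str, str, str], ...] = (
    ("TCONS_00026544", "gga-miR-128-1-5p", "RASD1"),
    ("TCONS_00057272", "gga-miR-146a-3p", "FOXO6"),
    ("TCONS_00057242", "gga-miR-6615-3p", "FOXO6"),
    ("TCONS_00057242", "gga-miR-6615-3p", "ENSGALT00000043224"),
    ("TCONS_00040913", "gga-miR-6615-3p", "ENSGALT00000043224"),
    ("TCONS_00040913", "gga-miR-6615-3p", "ENSGALT00000050730"),
    ("TCONS_00038747", "gga-miR-6615-3p", "ENSGALT00000050730"),
    ("TCONS_00038748", "gga-miR-6615-3p", "ENSGALT00000050730"),
    ("TCONS_00055280", "gga-miR-135a-5p", "JAM3"),
    ("TCONS_00055280", "gga-miR-135a-5p", "GPR133"),
    ("TCONS_00055280", "gga-miR-135a-5p", "CLDN1"),
    ("TCONS_00055280", "gga-miR-135a-5p", "TMEM123"),
)

#: the four miRNAs the crucial selection was built around
CRUCIAL_MIRNAS: frozenset[str] = frozenset(
    {"gga-miR-128-1-5p", "gga-miR-146a-3p", "gga-miR-6615-3p", "gga-miR-135a-5p"}
)


def crucial_interaction_triples() -> pd.DataFrame:
    """The reported crucial interactions as an accepted-triple table
    (statistical columns are absent: only the identities were published)."""
    df = pd.DataFrame(CRUCIAL_INTERACTIONS, columns=["lncrna_id", "mirna_id", "mrna_id"])
    df["accepted"] = True
    return df
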