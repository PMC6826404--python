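#!/usr/bin/env python
"""Apply the Spearman co-expression filters.

Predicted miRNA->target pairs among DE genes must anti-correlate
(SCC < -0.7) and DE lncRNA x DE mRNA pairs must co-vary strongly
(SCC > 0.9). Writes results/run/correlate/ and reports how many pairs
survive each gate — decoy interactions between independent genes should
essentially all fail.
"""

import argparse
from pathlib import Path

import pandas as pd

from cernet.pipeline import stage_correlate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    parser.add_argument("--run", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    stage_correlate(args.run)
    for fname, label in (
        ("corr_mirna_lncrna.tsv", "miRNA-lncRNA (SCC < -0.7)"),
        ("corr_mirna_mrna.tsv", "miRNA-mRNA   (SCC < -0.7)"),
        ("corr_lncrna_mrna.tsv", "lncRNA-mRNA  (SCC > 0.9)"),
    ):
        rec = pd.read_csv(args.run / "correlate" / fname, sep="\t")
        print(f"{label}: {int(rec['passed'].sum())} of {len(rec)} scored pairs pass")


if __name__ == "__main__":
    main()
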