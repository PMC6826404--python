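#!/usr/bin/env python
"""Generate the synthetic two-condition experiment the analysis runs on.

Emulates the study design: undifferentiated vs differentiated preadipocytes,
three replicates each, with lncRNA/mRNA fragment counts and miRNA tag counts
(200 / 500 / 100 genes), 20 planted ceRNA triples and decoy interactions.
Writes the count matrices, annotations, interaction list and truth sidecar
under results/run/data/.
"""

import argparse
from pathlib import Path

from cernet.simulate import SimulationParams, generate_dataset, write_fixture


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    params = SimulationParams(seed=args.seed)
    dataset = generate_dataset(params)
    files = write_fixture(dataset, args.out / "data")

    print(f"simulated {params.n_lncrna} lncRNAs, {params.n_mirna} miRNAs, "
          f"{params.n_mrna} mRNAs across {2 * params.n_samples_per_group} samples")
    print(f"planted {len(dataset.truth.planted_triples)} ceRNA triples "
          f"({len(dataset.truth.planted_de)} planted DE genes); "
          f"{len(dataset.interactions)} predicted interactions "
          f"(incl. {2 * params.n_planted_triples} planted edges)")
    print(f"wrote {len(files)} files to {args.out / 'data'}")


if __name__ == "__main__":
    main()
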