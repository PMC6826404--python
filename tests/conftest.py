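from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cernet.containers import CountMatrix
from cernet.simulate import SimulationParams, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the study conditions (200/100/500 genes, 20 planted
    triples, 3 vs 3 samples), shared read-only across tests."""
    return generate_dataset(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast small dataset with planted structure."""
    params = SimulationParams(
        n_lncrna=40, n_mirna=25, n_mrna=60, n_planted_triples=5,
        decoy_interactions_per_mirna=3, seed=11,
    )
    return generate_dataset(params)


def make_counts(values, gene_ids=None, n_per_group=None, groups=None) -> CountMatrix:
    """Small helper to build a CountMatrix from a 2-D array."""
    values = np.asarray(values)
    n_genes, n_samples = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if groups is None:
        half = n_per_group if n_per_group is not None else n_samples // 2
        groups = ["undifferentiated"] * half + ["differentiated"] * (n_samples - half)
    samples = [f"s{i}" for i in range(n_samples)]
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    return CountMatrix(df, pd.Series(groups, index=samples, name="group"))
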