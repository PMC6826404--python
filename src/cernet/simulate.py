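"""Synthetic two-condition RNA-seq / miRNA-seq generator with planted ceRNA triples.

The generator emulates the expression structure of a preadipocyte
differentiation experiment: two groups (undifferentiated vs differentiated),
three biological replicates each by default, and three assays — lncRNA and
mRNA fragment counts plus miRNA tag counts — drawn from a negative-binomial
noise model (mean/dispersion parameterization, the standard RNA-seq count
model).

Planted signal
--------------
``n_planted_triples`` disjoint (lncRNA, miRNA, mRNA) triples carry the ceRNA
pattern: the miRNA's group mean is shifted by ``-de_log2fc`` log2 units in
the differentiated group while its lncRNA and mRNA partners shift by
``+de_log2fc`` (or the mirrored signs, chosen per triple from the seed).
Within a triple, counts are coupled through one shared per-sample latent
uniform: the lncRNA and mRNA are comonotone, the miRNA anti-comonotone
(negative-binomial quantile coupling). Marginals remain exactly
NB(mean, dispersion), so differential-expression behaviour is untouched,
while Spearman correlations across the six samples land in the regime a
ceRNA screen selects for (strongly negative miRNA-target, strongly positive
lncRNA-mRNA). Unplanted genes are independent and identically distributed
across groups.

The matching interaction list contains every planted (miRNA, lncRNA) and
(miRNA, mRNA) edge plus uniformly drawn decoy edges onto non-planted
targets; decoys are what the downstream correlation filter must reject.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from . import io
from .containers import CountMatrix
from .errors import ParameterError

GROUP_CTRL = "undifferentiated"
GROUP_CASE = "differentiated"


@dataclass
class SimulationParams:
    """Knobs of the synthetic experiment (defaults are the study conditions)."""

    n_lncrna: int = 200
    n_mirna: int = 100
    n_mrna: int = 500
    n_samples_per_group: int = 3
    n_planted_triples: int = 20
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    baseline_mean: float = 200.0
    decoy_interactions_per_mirna: int = 5
    gene_length_range: tuple[int, int] = (200, 3000)
    library_size_range: tuple[int, int] = (100_000, 200_000)
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_lncrna",
            "n_mirna",
            "n_mrna",
            "n_samples_per_group",
            "n_planted_triples",
            "decoy_interactions_per_mirna",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_planted_triples > min(self.n_lncrna, self.n_mirna, self.n_mrna):
            raise ParameterError(
                "n_planted_triples must be <= min(n_lncrna, n_mirna, n_mrna)"
            )
        if self.de_log2fc <= 0:
            raise ParameterError(f"de_log2fc must be > 0, got {self.de_log2fc}")
        if self.nb_dispersion <= 0:
            raise ParameterError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        if self.baseline_mean <= 0:
            raise ParameterError(f"baseline_mean must be > 0, got {self.baseline_mean}")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ParameterError(f"invalid gene_length_range {self.gene_length_range}")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ParameterError(f"invalid library_size_range {self.library_size_range}")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset (what the pipeline should find)."""

    planted_de: list[tuple[str, str]]  # (gene_id, "up"|"down" in differentiated)
    planted_triples: list[tuple[str, str, str]]  # (lncRNA, miRNA, mRNA)
    seed: int
    params: SimulationParams
    library_sizes: dict[str, dict[str, int]] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    lncrna: CountMatrix
    mirna: CountMatrix
    mrna: CountMatrix
    annotations: pd.DataFrame
    interactions: pd.DataFrame
    truth: SyntheticTruth


def _nb_params(mean: np.ndarray, dispersion: float) -> tuple[float, np.ndarray]:
    r = 1.0 / dispersion
    return r, r / (r + mean)


def _sample_ids(n_per_group: int) -> tuple[list[str], pd.Series]:
    samples = [f"undiff_{i + 1}" for i in range(n_per_group)] + [
        f"diff_{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        [GROUP_CTRL] * n_per_group + [GROUP_CASE] * n_per_group, index=samples, name="group"
    )
    return samples, groups


def generate_dataset(params: SimulationParams) -> SyntheticDataset:
    """Simulate the full dataset: three count matrices, annotations,
    interaction list and the truth sidecar. Identical params (incl. seed)
    give identical output."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    samples, groups = _sample_ids(params.n_samples_per_group)
    n_s = params.n_samples_per_group
    n_total = 2 * n_s

    ids = {
        "lncRNA": [f"lnc_{i + 1:04d}" for i in range(params.n_lncrna)],
        "miRNA": [f"mir_{i + 1:04d}" for i in range(params.n_mirna)],
        "mRNA": [f"mrna_{i + 1:04d}" for i in range(params.n_mrna)],
    }

    # gene baselines: lognormal spread around baseline_mean
    base = {
        bt: params.baseline_mean * np.exp(rng.normal(0.0, 1.0, size=len(ids[bt])))
        for bt in ("lncRNA", "miRNA", "mRNA")
    }

    # planted triples: disjoint members per biotype; detectable ceRNA members
    # are drawn as moderately-to-well expressed genes (tighter spread)
    nt = params.n_planted_triples
    picks = {
        bt: rng.choice(len(ids[bt]), size=nt, replace=False) if nt else np.array([], int)
        for bt in ("lncRNA", "miRNA", "mRNA")
    }
    for bt in ("lncRNA", "miRNA", "mRNA"):
        base[bt][picks[bt]] = params.baseline_mean * np.exp(
            rng.normal(0.0, 0.5, size=nt)
        )
    signs = rng.choice([1, -1], size=nt)

    # group-mean matrices per biotype
    shift = {"lncRNA": 1, "mRNA": 1, "miRNA": -1}
    mu = {}
    for bt in ("lncRNA", "miRNA", "mRNA"):
        m = np.tile(base[bt][:, None], (1, n_total)).astype(float)
        m[picks[bt], n_s:] *= 2.0 ** (shift[bt] * signs * params.de_log2fc)[:, None]
        mu[bt] = m

    # per-sample sequencing depth: scale means so the expected column total
    # matches a target drawn from library_size_range (independent per assay)
    for bt in ("lncRNA", "miRNA", "mRNA"):
        targets = rng.uniform(*params.library_size_range, size=n_total)
        expected = mu[bt].sum(axis=0)
        expected[expected == 0] = 1.0
        mu[bt] *= targets / expected

    r = 1.0 / params.nb_dispersion
    counts = {}
    for bt in ("lncRNA", "miRNA", "mRNA"):
        _, p = _nb_params(mu[bt], params.nb_dispersion)
        counts[bt] = rng.negative_binomial(r, p).astype(np.int64)

    # redraw planted rows with shared-latent quantile coupling; the latent is
    # stratified within each group (one uniform per equal-probability stratum,
    # strata randomly permuted) so each member's marginal stays exactly
    # NB(mean, dispersion) while realized group means concentrate near the
    # planted means instead of drifting jointly across the whole triple
    for t in range(nt):
        u_groups = []
        for _ in range(2):
            strata = rng.permutation(n_s)
            u_groups.append((strata + rng.uniform(size=n_s)) / n_s)
        u = np.concatenate(u_groups)
        for bt, uu in (("lncRNA", u), ("mRNA", u), ("miRNA", 1.0 - u)):
            uu = np.clip(uu, 1e-12, 1.0 - 1e-12)
            row = picks[bt][t]
            _, p = _nb_params(mu[bt][row], params.nb_dispersion)
            counts[bt][row] = nbinom.ppf(uu, r, p).astype(np.int64)

    matrices = {
        bt: CountMatrix(
            pd.DataFrame(counts[bt], index=pd.Index(ids[bt], name="gene_id"), columns=samples),
            groups,
        )
        for bt in ("lncRNA", "miRNA", "mRNA")
    }

    lo, hi = params.gene_length_range
    n_long = params.n_lncrna + params.n_mrna
    lengths = rng.integers(lo, hi + 1, size=n_long) if n_long else np.array([], int)
    annotations = pd.DataFrame(
        {
            "gene_id": ids["lncRNA"] + ids["miRNA"] + ids["mRNA"],
            "biotype": ["lncRNA"] * params.n_lncrna
            + ["miRNA"] * params.n_mirna
            + ["mRNA"] * params.n_mrna,
            "length_bp": list(lengths[: params.n_lncrna])
            + [pd.NA] * params.n_mirna
            + list(lengths[params.n_lncrna :]),
        }
    )
    annotations["length_bp"] = annotations["length_bp"].astype("Int64")

    planted_triples = [
        (ids["lncRNA"][picks["lncRNA"][t]], ids["miRNA"][picks["miRNA"][t]], ids["mRNA"][picks["mRNA"][t]])
        for t in range(nt)
    ]
    planted_de: list[tuple[str, str]] = []
    for t, s in enumerate(signs):
        lnc, mir, mrna = planted_triples[t]
        tgt_dir = "up" if s > 0 else "down"
        mir_dir = "down" if s > 0 else "up"
        planted_de += [(lnc, tgt_dir), (mir, mir_dir), (mrna, tgt_dir)]

    interactions = _build_interactions(params, rng, ids, planted_triples)

    truth = SyntheticTruth(
        planted_de=planted_de,
        planted_triples=planted_triples,
        seed=params.seed,
        params=params,
        library_sizes={
            bt: {s: int(matrices[bt].counts[s].sum()) for s in samples}
            for bt in ("lncRNA", "miRNA", "mRNA")
        },
    )
    return SyntheticDataset(
        lncrna=matrices["lncRNA"],
        mirna=matrices["miRNA"],
        mrna=matrices["mRNA"],
        annotations=annotations,
        interactions=interactions,
        truth=truth,
    )


def _build_interactions(
    params: SimulationParams,
    rng: np.random.Generator,
    ids: dict[str, list[str]],
    planted_triples: list[tuple[str, str, str]],
) -> pd.DataFrame:
    rows: list[tuple[str, str, str]] = []
    planted_targets = {lnc for lnc, _, _ in planted_triples} | {
        m for _, _, m in planted_triples
    }
    for lnc, mir, mrna in planted_triples:
        rows.append((mir, lnc, "lncRNA"))
        rows.append((mir, mrna, "mRNA"))
    # decoys: uniform over non-planted targets, unique per miRNA
    pool = [
        (t, "lncRNA") for t in ids["lncRNA"] if t not in planted_targets
    ] + [(t, "mRNA") for t in ids["mRNA"] if t not in planted_targets]
    k = min(params.decoy_interactions_per_mirna, len(pool))
    for mir in ids["miRNA"]:
        if k == 0:
            break
        for j in rng.choice(len(pool), size=k, replace=False):
            t, bt = pool[j]
            rows.append((mir, t, bt))
    df = pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_biotype"])
    return df.drop_duplicates(ignore_index=True)


# ---------------------------------------------------------------------------
# fixture round-trip


def _params_to_json(params: SimulationParams) -> dict:
    d = dataclasses.asdict(params)
    d["gene_length_range"] = list(d["gene_length_range"])
    d["library_size_range"] = list(d["library_size_range"])
    return d


def _params_from_json(d: dict) -> SimulationParams:
    d = dict(d)
    d["gene_length_range"] = tuple(d["gene_length_range"])
    d["library_size_range"] = tuple(d["library_size_range"])
    return SimulationParams(**d)


def write_fixture(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write all dataset components as TSV (+ JSON truth sidecar)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "lncrna_counts": io.write_counts(dataset.lncrna, out / "lncrna_counts.tsv"),
        "mirna_counts": io.write_counts(dataset.mirna, out / "mirna_counts.tsv"),
        "mrna_counts": io.write_counts(dataset.mrna, out / "mrna_counts.tsv"),
        "groups": io.write_groups(dataset.lncrna.groups, out / "groups.tsv"),
        "annotations": io.write_annotations(dataset.annotations, out / "annotations.tsv"),
        "interactions": io.write_table(dataset.interactions, out / "interactions.tsv"),
    }
    truth = {
        "seed": dataset.truth.seed,
        "params": _params_to_json(dataset.truth.params),
        "planted_de": [list(x) for x in dataset.truth.planted_de],
        "planted_triples": [list(x) for x in dataset.truth.planted_triples],
        "library_sizes": dataset.truth.library_sizes,
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    files["truth"] = truth_path
    return files


def read_fixture(out_dir: str | Path) -> SyntheticDataset:
    out = Path(out_dir)
    groups = io.read_groups(out / "groups.tsv")
    truth_raw = json.loads((out / "truth.json").read_text())
    truth = SyntheticTruth(
        planted_de=[tuple(x) for x in truth_raw["planted_de"]],
        planted_triples=[tuple(x) for x in truth_raw["planted_triples"]],
        seed=truth_raw["seed"],
        params=_params_from_json(truth_raw["params"]),
        library_sizes=truth_raw["library_sizes"],
    )
    return SyntheticDataset(
        lncrna=io.read_counts(out / "lncrna_counts.tsv", groups),
        mirna=io.read_counts(out / "mirna_counts.tsv", groups),
        mrna=io.read_counts(out / "mrna_counts.tsv", groups),
        annotations=io.read_annotations(out / "annotations.tsv"),
        interactions=io.read_table(out / "interactions.tsv"),
        truth=truth,
    )
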