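"""Staged pipeline: simulate/load -> quantify -> DE -> correlate -> ceRNA ->
network -> crucial (-> enrich), with a manifest for reproducibility.

Every stage reads its inputs from, and writes its outputs to, a fixed
layout under the run directory, so any stage can be recomputed
independently (that is also how the CLI subcommands work). All outputs are
plain text written deterministically; rerunning the same configuration
yields byte-identical files, and ``manifest.json`` records the SHA-256 of
every stage output together with the seed and thresholds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__, io
from .cerna import assemble_triples, filter_lnc_mrna, filter_mirna_targets
from .config import PipelineConfig, ThresholdConfig
from .containers import FPKM, TPM
from .diff_expr import classify_de, test_differential
from .enrichment import overrepresentation, read_gmt
from .errors import CernetError
from .interactions import read_interactions
from .network import build_network, export_network, identify_hubs, select_crucial, summarize_network
from .quantify import fpkm, tpm
from .simulate import generate_dataset, write_fixture

logger = logging.getLogger(__name__)

DATA = "data"
QUANTIFY = "quantify"
DE = "de"
CORRELATE = "correlate"
CERNA = "cerna"
NETWORK = "network"
CRUCIAL = "crucial"
ENRICH = "enrich"


def _read_data(run_dir: Path):
    data = run_dir / DATA
    groups = io.read_groups(data / "groups.tsv")
    return {
        "lncrna": io.read_counts(data / "lncrna_counts.tsv", groups),
        "mirna": io.read_counts(data / "mirna_counts.tsv", groups),
        "mrna": io.read_counts(data / "mrna_counts.tsv", groups),
        "annotations": io.read_annotations(data / "annotations.tsv"),
        "interactions": read_interactions(data / "interactions.tsv"),
        "groups": groups,
    }


def stage_data(config: PipelineConfig) -> list[Path]:
    """Simulate the dataset, or ingest user inputs, into ``<out>/data/``."""
    out = Path(config.out_dir) / DATA
    if config.simulation is not None:
        dataset = generate_dataset(config.simulation)
        return sorted(write_fixture(dataset, out).values())
    assert config.inputs is not None
    out.mkdir(parents=True, exist_ok=True)
    groups = io.read_groups(config.inputs["groups"])
    written = [
        io.write_counts(io.read_counts(config.inputs["lncrna_counts"], groups), out / "lncrna_counts.tsv"),
        io.write_counts(io.read_counts(config.inputs["mirna_counts"], groups), out / "mirna_counts.tsv"),
        io.write_counts(io.read_counts(config.inputs["mrna_counts"], groups), out / "mrna_counts.tsv"),
        io.write_groups(groups, out / "groups.tsv"),
        io.write_annotations(io.read_annotations(config.inputs["annotations"]), out / "annotations.tsv"),
        io.write_table(
            read_interactions(config.inputs["interactions"]).drop(columns="source"),
            out / "interactions.tsv",
        ),
    ]
    return sorted(written)


def stage_quantify(run_dir: str | Path) -> list[Path]:
    """FPKM for lncRNA/mRNA, TPM for miRNA."""
    run_dir = Path(run_dir)
    d = _read_data(run_dir)
    out = run_dir / QUANTIFY
    ann = d["annotations"]
    return sorted(
        [
            io.write_expression(fpkm(d["lncrna"], ann[ann["biotype"] == "lncRNA"]), out / "lncrna_fpkm.tsv"),
            io.write_expression(fpkm(d["mrna"], ann[ann["biotype"] == "mRNA"]), out / "mrna_fpkm.tsv"),
            io.write_expression(tpm(d["mirna"]), out / "mirna_tpm.tsv"),
        ]
    )


def stage_diff_expr(
    run_dir: str | Path,
    thresholds: ThresholdConfig | None = None,
    method: str = "moderated",
) -> list[Path]:
    """Per-biotype differential expression (FDR within biotype)."""
    run_dir = Path(run_dir)
    d = _read_data(run_dir)
    out = run_dir / DE
    thresholds = thresholds or ThresholdConfig()
    ann = d["annotations"]
    written = []
    for key, biotype in (("lncrna", "lncRNA"), ("mirna", "miRNA"), ("mrna", "mRNA")):
        ann_bt = ann[ann["biotype"] == biotype] if biotype != "miRNA" else None
        records = test_differential(d[key], ann_bt, method=method, thresholds=thresholds)
        records.insert(1, "biotype", biotype)
        written.append(io.write_table(records, out / f"de_{key}.tsv"))
    return sorted(written)


def _de_sets(run_dir: Path, thresholds: ThresholdConfig) -> dict[str, set[str]]:
    sets = {}
    for key in ("lncrna", "mirna", "mrna"):
        records = io.read_table(run_dir / DE / f"de_{key}.tsv")
        _, _, all_de = classify_de(records, thresholds)
        sets[key] = all_de
    return sets


def _expr(run_dir: Path):
    q = run_dir / QUANTIFY
    return {
        "lncrna": io.read_expression(q / "lncrna_fpkm.tsv", FPKM),
        "mrna": io.read_expression(q / "mrna_fpkm.tsv", FPKM),
        "mirna": io.read_expression(q / "mirna_tpm.tsv", TPM),
    }


def stage_correlate(run_dir: str | Path, thresholds: ThresholdConfig | None = None) -> list[Path]:
    """Spearman filters on DE-restricted predicted pairs and on DEL x DEM."""
    run_dir = Path(run_dir)
    thresholds = thresholds or ThresholdConfig()
    d = _read_data(run_dir)
    expr = _expr(run_dir)
    de = _de_sets(run_dir, thresholds)
    inter = d["interactions"]
    inter = inter[inter["mirna_id"].isin(de["mirna"])]
    out = run_dir / CORRELATE
    written = []
    for biotype, key in (("lncRNA", "lncrna"), ("mRNA", "mrna")):
        pairs = inter[(inter["target_biotype"] == biotype) & (inter["target_id"].isin(de[key]))]
        rec = filter_mirna_targets(pairs, expr["mirna"], expr[key], thresholds)
        written.append(io.write_table(rec, out / f"corr_mirna_{key}.tsv"))
    rec = filter_lnc_mrna(de["lncrna"], de["mrna"], expr["lncrna"], expr["mrna"], thresholds)
    written.append(io.write_table(rec, out / "corr_lncrna_mrna.tsv"))
    return sorted(written)


def stage_cerna(
    run_dir: str | Path,
    thresholds: ThresholdConfig | None = None,
    universe: str = "all",
) -> list[Path]:
    """Hypergeometric shared-miRNA test over passing pair sets."""
    run_dir = Path(run_dir)
    thresholds = thresholds or ThresholdConfig()
    c = run_dir / CORRELATE
    mi_lnc = io.read_table(c / "corr_mirna_lncrna.tsv")
    mi_mrna = io.read_table(c / "corr_mirna_mrna.tsv")
    lnc_mrna = io.read_table(c / "corr_lncrna_mrna.tsv")
    if universe == "all":
        u = len(io.read_counts(run_dir / DATA / "mirna_counts.tsv").index)
    elif universe == "demis":
        u = len(_de_sets(run_dir, thresholds)["mirna"])
    else:
        raise CernetError(f"unknown universe mode {universe!r}")
    triples = assemble_triples(mi_lnc, mi_mrna, lnc_mrna, u, thresholds)
    return [io.write_table(triples, run_dir / CERNA / "triples.tsv")]


def stage_network(run_dir: str | Path) -> list[Path]:
    """Tripartite graph over accepted triples; summary, hubs, SIF export."""
    run_dir = Path(run_dir)
    triples = io.read_table(run_dir / CERNA / "triples.tsv")
    net = build_network(triples)
    out = run_dir / NETWORK
    out.mkdir(parents=True, exist_ok=True)
    written = sorted(export_network(net, out).values())
    summary = summarize_network(net)
    summary["hubs"] = sorted(identify_hubs(net))
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    written.append(path)
    return sorted(written)


def stage_crucial(
    run_dir: str | Path,
    thresholds: ThresholdConfig | None = None,
    flagged_mirnas=(),
) -> list[Path]:
    """Crucial-interaction selection (flagged or hub-and-highly-expressed miRNAs)."""
    run_dir = Path(run_dir)
    thresholds = thresholds or ThresholdConfig()
    triples = io.read_table(run_dir / CERNA / "triples.tsv")
    net = build_network(triples)
    mirna_tpm = io.read_expression(run_dir / QUANTIFY / "mirna_tpm.tsv", TPM)
    sel = select_crucial(net, mirna_tpm, flagged_mirnas, thresholds)
    out = run_dir / CRUCIAL
    out.mkdir(parents=True, exist_ok=True)
    written = [io.write_table(sel.crucial_triples, out / "crucial_triples.tsv")]
    path = out / "selection.json"
    path.write_text(
        json.dumps(
            {
                "flagged_mirnas": sorted(sel.flagged_mirnas),
                "auto_mirnas": sorted(sel.auto_mirnas),
                "n_crucial_triples": len(sel.crucial_triples),
            },
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )
    written.append(path)
    return sorted(written)


def stage_enrich(
    run_dir: str | Path,
    gene_sets_path: str | Path,
    thresholds: ThresholdConfig | None = None,
) -> list[Path]:
    """Over-representation of network mRNAs against supplied gene sets,
    background = all mRNAs that entered DE testing."""
    run_dir = Path(run_dir)
    thresholds = thresholds or ThresholdConfig()
    triples = io.read_table(run_dir / CERNA / "triples.tsv")
    net = build_network(triples)
    query = net.nodes_of_biotype("mRNA")
    background = set(io.read_table(run_dir / DE / "de_mrna.tsv")["gene_id"])
    gene_sets = read_gmt(gene_sets_path)
    result = overrepresentation(query & background, gene_sets, background, thresholds)
    return [io.write_table(result, run_dir / ENRICH / "enrichment.tsv")]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write ``manifest.json``; returns the manifest."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds

    stages: list[tuple[str, list[Path]]] = []

    def run_stage(name: str, fn, *args, **kwargs) -> None:
        t0 = time.perf_counter()
        try:
            written = fn(*args, **kwargs)
        except Exception as exc:
            _write_manifest(config, stages, out, failed=name)
            raise CernetError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %-10s %5.2fs  %d file(s)", name, time.perf_counter() - t0, len(written))
        stages.append((name, written))

    run_stage(DATA, stage_data, config)
    run_stage(QUANTIFY, stage_quantify, out)
    run_stage(DE, stage_diff_expr, out, thresholds)
    run_stage(CORRELATE, stage_correlate, out, thresholds)
    run_stage(CERNA, stage_cerna, out, thresholds, config.universe)
    run_stage(NETWORK, stage_network, out)
    run_stage(CRUCIAL, stage_crucial, out, thresholds, config.flagged_mirnas)
    if config.gene_sets is not None:
        run_stage(ENRICH, stage_enrich, out, config.gene_sets, thresholds)

    return _write_manifest(config, stages, out, failed=None)


def _write_manifest(
    config: PipelineConfig, stages: list[tuple[str, list[Path]]], out: Path, failed: str | None
) -> dict:
    manifest = {
        "version": __version__,
        "seed": config.seed if config.simulation is None else config.simulation.seed,
        "universe": config.universe,
        "thresholds": dataclasses.asdict(config.thresholds),
        "flagged_mirnas": sorted(config.flagged_mirnas),
        "failed_stage": failed,
        "stages": {
            name: {str(p.relative_to(out)): _sha256(p) for p in written}
            for name, written in stages
        },
    }
    if config.simulation is not None:
        sim = dataclasses.asdict(config.simulation)
        sim["gene_length_range"] = list(sim["gene_length_range"])
        sim["library_size_range"] = list(sim["library_size_range"])
        manifest["simulation"] = sim
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
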