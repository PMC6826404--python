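"""Tripartite ceRNA network construction, hubs and crucial interactions.

The graph renders accepted triples with two undirected edge classes,
lncRNA-miRNA and miRNA-mRNA (no direct lncRNA-mRNA edges); degree is
counted on the deduplicated edge set, so a miRNA appearing in several
triples with the same lncRNA gains that neighbour once. Hubs are nodes
whose degree strictly exceeds the network's average degree 2|E|/|V|,
which is always recomputed from the network at hand — a published average
is a property of that study's network, not a constant of the method.

"Crucial" interactions are the triples whose miRNA is either flagged from
the literature or simultaneously highly connected (degree > average) and
highly expressed (mean TPM across samples > ``tpm_high``, default 4.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .config import ThresholdConfig
from .containers import ExpressionMatrix
from .errors import ParameterError, ParseError
from .io import write_table

logger = logging.getLogger(__name__)

EDGE_LNC_MI = "lnc_mi"
EDGE_MI_MRNA = "mi_mrna"


@dataclass
class CeRNANetwork:
    graph: nx.Graph
    triples: pd.DataFrame  # provenance: the accepted triples the graph renders

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degree_of(self) -> dict[str, int]:
        return dict(self.graph.degree())

    @property
    def avg_degree(self) -> float:
        if self.n_nodes == 0:
            return 0.0
        return 2.0 * self.n_edges / self.n_nodes

    def nodes_of_biotype(self, biotype: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["biotype"] == biotype}


@dataclass
class CrucialSelection:
    flagged_mirnas: set[str]
    auto_mirnas: set[str]
    crucial_triples: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_network(triples: pd.DataFrame, accepted_only: bool = True) -> CeRNANetwork:
    """Union of nodes/edges over triples, deduplicated. ``triples`` needs
    columns ``lncrna_id, mirna_id, mrna_id`` (+ ``accepted`` when filtering)."""
    if accepted_only and "accepted" in triples.columns:
        triples = triples[triples["accepted"]].reset_index(drop=True)
    g = nx.Graph()
    if triples.empty:
        logger.warning("build_network: no accepted triples; empty network")
        return CeRNANetwork(graph=g, triples=triples)
    for _, row in triples.iterrows():
        lnc, mi, mrna = row["lncrna_id"], row["mirna_id"], row["mrna_id"]
        g.add_node(lnc, biotype="lncRNA")
        g.add_node(mi, biotype="miRNA")
        g.add_node(mrna, biotype="mRNA")
        g.add_edge(lnc, mi, interaction=EDGE_LNC_MI)
        g.add_edge(mi, mrna, interaction=EDGE_MI_MRNA)
    return CeRNANetwork(graph=g, triples=triples.reset_index(drop=True))


def summarize_network(net: CeRNANetwork) -> dict:
    """Distinct node counts per biotype, triple count and average degree."""
    triples = net.triples
    distinct_triples = (
        triples[["lncrna_id", "mirna_id", "mrna_id"]].drop_duplicates() if len(triples) else triples
    )
    return {
        "n_lncrna": len(net.nodes_of_biotype("lncRNA")),
        "n_mirna": len(net.nodes_of_biotype("miRNA")),
        "n_mrna": len(net.nodes_of_biotype("mRNA")),
        "n_triples": len(distinct_triples),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "avg_degree": net.avg_degree,
    }


def identify_hubs(net: CeRNANetwork) -> set[str]:
    """Nodes with degree strictly greater than the network average."""
    avg = net.avg_degree
    return {node for node, deg in net.graph.degree() if deg > avg}


def select_crucial(
    net: CeRNANetwork,
    mirna_tpm: ExpressionMatrix | None = None,
    flagged_mirnas=(),
    thresholds: ThresholdConfig | None = None,
) -> CrucialSelection:
    """Triples whose miRNA is literature-flagged or (hub AND mean TPM >
    ``tpm_high``). Flagged ids absent from the network are warned about and
    ignored; without a TPM matrix no miRNA qualifies automatically."""
    thresholds = thresholds or ThresholdConfig()
    net_mirnas = net.nodes_of_biotype("miRNA")
    flagged = set(flagged_mirnas)
    absent = flagged - net_mirnas
    if absent:
        logger.warning("select_crucial: flagged miRNA(s) not in network: %s", sorted(absent))
    flagged &= net_mirnas

    auto: set[str] = set()
    if mirna_tpm is not None:
        hubs = identify_hubs(net)
        mean_tpm = mirna_tpm.values.mean(axis=1)
        for mi in net_mirnas:
            if mi in hubs and mi in mean_tpm.index and mean_tpm[mi] > thresholds.tpm_high:
                auto.add(mi)

    keep = flagged | auto
    crucial = net.triples[net.triples["mirna_id"].isin(keep)].reset_index(drop=True)
    return CrucialSelection(flagged_mirnas=flagged, auto_mirnas=auto, crucial_triples=crucial)


# ---------------------------------------------------------------------------
# export / import

_FORMATS = ("sif", "edge-tsv", "node-tsv")


def _node_table(net: CeRNANetwork) -> pd.DataFrame:
    hubs = identify_hubs(net)
    rows = [
        (n, d["biotype"], net.graph.degree(n), n in hubs)
        for n, d in net.graph.nodes(data=True)
    ]
    return pd.DataFrame(rows, columns=["node_id", "biotype", "degree", "hub"]).sort_values(
        "node_id", ignore_index=True
    )


def _edge_table(net: CeRNANetwork) -> pd.DataFrame:
    rows = []
    for a, b, d in net.graph.edges(data=True):
        if net.graph.nodes[a]["biotype"] == "miRNA":  # orient miRNA second for lnc_mi
            a, b = b, a
        if d["interaction"] == EDGE_MI_MRNA:  # orient miRNA first
            if net.graph.nodes[a]["biotype"] != "miRNA":
                a, b = b, a
        rows.append((a, d["interaction"], b))
    return pd.DataFrame(rows, columns=["source", "interaction", "target"]).sort_values(
        ["source", "interaction", "target"], ignore_index=True
    )


def export_network(net: CeRNANetwork, out_dir: str | Path, formats=_FORMATS) -> dict[str, Path]:
    """Write the network in Cytoscape-friendly text formats with
    deterministic (lexicographic) ordering."""
    unknown = [f for f in formats if f not in _FORMATS]
    if unknown:
        raise ParameterError(f"unknown export format(s) {unknown}; choose from {_FORMATS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    edges = _edge_table(net)
    if "sif" in formats:
        path = out / "network.sif"
        lines = [f"{r.source}\t{r.interaction}\t{r.target}" for r in edges.itertuples()]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        written["sif"] = path
    if "edge-tsv" in formats:
        written["edge-tsv"] = write_table(edges, out / "edges.tsv")
    if "node-tsv" in formats:
        written["node-tsv"] = write_table(_node_table(net), out / "nodes.tsv")
    return written


def import_network(out_dir: str | Path) -> CeRNANetwork:
    """Rebuild a network from an exported node/edge table pair. Triple
    provenance is not stored in the tables, so ``triples`` comes back empty."""
    out = Path(out_dir)
    nodes = pd.read_csv(out / "nodes.tsv", sep="\t")
    edges = pd.read_csv(out / "edges.tsv", sep="\t")
    g = nx.Graph()
    for r in nodes.itertuples():
        g.add_node(r.node_id, biotype=r.biotype)
    for r in edges.itertuples():
        if r.interaction not in (EDGE_LNC_MI, EDGE_MI_MRNA):
            raise ParseError(f"edges.tsv: unknown interaction class {r.interaction!r}")
        g.add_edge(r.source, r.target, interaction=r.interaction)
    return CeRNANetwork(graph=g, triples=pd.DataFrame(columns=["lncrna_id", "mirna_id", "mrna_id"]))
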