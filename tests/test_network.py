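"""Network construction, hubs, crucial-interaction selection, export."""

from __future__ import annotations

import networkx as nx
import pandas as pd
import pytest

from cernet.containers import ExpressionMatrix, TPM
from cernet.datasets import CRUCIAL_MIRNAS, crucial_interaction_triples
from cernet.errors import ParameterError
from cernet.network import (
    CeRNANetwork,
    build_network,
    export_network,
    identify_hubs,
    import_network,
    select_crucial,
    summarize_network,
)


def triples_df(rows):
    df = pd.DataFrame(rows, columns=["lncrna_id", "mirna_id", "mrna_id"])
    df["accepted"] = True
    return df


@pytest.fixture(scope="module")
def published_net():
    return build_network(crucial_interaction_triples())


class TestBuildAndSummarize:
    def test_single_triple_closed_form(self):
        net = build_network(triples_df([("l1", "m1", "g1")]))
        assert net.n_nodes == 3 and net.n_edges == 2
        assert net.degree_of == {"l1": 1, "m1": 2, "g1": 1}
        assert net.avg_degree == pytest.approx(4 / 3)

    def test_published_crucial_subnetwork_counts(self, published_net):
        """The 12 published crucial interactions involve 7 lncRNAs, 4 miRNAs
        and 8 distinct mRNAs (recounted from the printed list; the source
        text's own tally of seven mRNAs disagrees with its list)."""
        s = summarize_network(published_net)
        assert s["n_triples"] == 12
        assert s["n_lncrna"] == 7
        assert s["n_mirna"] == 4
        assert s["n_mrna"] == 8

    def test_published_mir6615_degree(self, published_net):
        """gga-miR-6615-3p touches 4 lncRNAs and 3 mRNAs: degree 7 on the
        deduplicated edge set (hand count)."""
        assert published_net.degree_of["gga-miR-6615-3p"] == 7

    def test_duplicate_triples_are_idempotent(self):
        once = build_network(triples_df([("l1", "m1", "g1")]))
        twice = build_network(triples_df([("l1", "m1", "g1")] * 3))
        assert nx.utils.graphs_equal(once.graph, twice.graph)

    def test_triple_order_invariance(self):
        rows = [("l1", "m1", "g1"), ("l2", "m1", "g1"), ("l2", "m2", "g2")]
        a = build_network(triples_df(rows))
        b = build_network(triples_df(rows[::-1]))
        assert nx.utils.graphs_equal(a.graph, b.graph)
        assert summarize_network(a) == summarize_network(b)

    def test_degree_sum_is_twice_edges(self, published_net):
        assert sum(published_net.degree_of.values()) == 2 * published_net.n_edges

    def test_empty_triples_give_empty_network(self):
        net = build_network(triples_df([]))
        assert net.n_nodes == 0
        assert summarize_network(net)["n_triples"] == 0
        assert identify_hubs(net) == set()


class TestHubs:
    def test_single_triple_hub_is_mirna(self):
        net = build_network(triples_df([("l1", "m1", "g1")]))
        assert identify_hubs(net) == {"m1"}

    def test_regular_graph_has_no_hubs(self):
        """All degrees equal the average: strict > leaves the hub set empty."""
        g = nx.Graph()
        for node, bt in (("l1", "lncRNA"), ("m1", "miRNA"), ("m2", "miRNA"), ("g1", "mRNA")):
            g.add_node(node, biotype=bt)
        g.add_edge("l1", "m1", interaction="lnc_mi")
        g.add_edge("l1", "m2", interaction="lnc_mi")
        g.add_edge("m1", "g1", interaction="mi_mrna")
        g.add_edge("m2", "g1", interaction="mi_mrna")
        net = CeRNANetwork(graph=g, triples=triples_df([]))
        assert net.avg_degree == 2.0
        assert identify_hubs(net) == set()

    def test_published_hubs_match_hand_census(self, published_net):
        """Average degree of the printed subnetwork is 32/19; the nodes
        strictly above it are the four miRNAs (degrees 2,2,7,5) and FOXO6
        (degree 2)."""
        assert published_net.avg_degree == pytest.approx(32 / 19)
        assert identify_hubs(published_net) == CRUCIAL_MIRNAS | {"FOXO6"}


class TestSelectCrucial:
    def test_no_flags_low_tpm_selects_nothing(self):
        net = build_network(triples_df([("l1", "m1", "g1")]))
        tpm_values = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=pd.Index(["m1"], name="gene_id"))
        sel = select_crucial(net, ExpressionMatrix(tpm_values, TPM))
        assert sel.auto_mirnas == set()
        assert sel.crucial_triples.empty

    def test_published_flags_select_all_12(self, published_net):
        """Flagging the four reported miRNAs recovers exactly the 12
        published crucial interactions."""
        sel = select_crucial(published_net, None, CRUCIAL_MIRNAS)
        assert len(sel.crucial_triples) == 12
        assert sel.flagged_mirnas == CRUCIAL_MIRNAS

    def test_auto_selection_by_degree_and_tpm(self):
        """A miRNA that is both a hub and highly expressed is selected
        automatically; its triples and only its triples are crucial."""
        rows = [("l1", "m1", "g1"), ("l2", "m1", "g2"), ("l3", "m2", "g3")]
        net = build_network(triples_df(rows))
        tpm_values = pd.DataFrame(
            {"s1": [50.0, 1.0], "s2": [40.0, 2.0]},
            index=pd.Index(["m1", "m2"], name="gene_id"),
        )
        sel = select_crucial(net, ExpressionMatrix(tpm_values, TPM))
        assert sel.auto_mirnas == {"m1"}
        assert set(sel.crucial_triples["mirna_id"]) == {"m1"}
        assert len(sel.crucial_triples) == 2

    def test_tpm_boundary_is_strict(self):
        net = build_network(triples_df([("l1", "m1", "g1"), ("l2", "m1", "g2")]))
        tpm_values = pd.DataFrame(
            {"s1": [4.5], "s2": [4.5]}, index=pd.Index(["m1"], name="gene_id")
        )
        sel = select_crucial(net, ExpressionMatrix(tpm_values, TPM))
        assert sel.auto_mirnas == set()  # mean TPM exactly 4.5 is not > 4.5

    def test_absent_flag_warned_and_ignored(self, published_net, caplog):
        sel = select_crucial(published_net, None, {"gga-miR-9999"})
        assert sel.crucial_triples.empty
        assert any("gga-miR-9999" in r.message for r in caplog.records)


class TestExport:
    def test_single_triple_two_sif_lines(self, tmp_path):
        net = build_network(triples_df([("l1", "m1", "g1")]))
        files = export_network(net, tmp_path)
        lines = files["sif"].read_text().splitlines()
        assert len(lines) == 2
        assert lines == ["l1\tlnc_mi\tm1", "m1\tmi_mrna\tg1"]

    def test_published_network_has_16_sif_lines(self, published_net, tmp_path):
        """Hand dedup of the printed triples gives 16 distinct edges."""
        files = export_network(published_net, tmp_path)
        lines = files["sif"].read_text().splitlines()
        assert len(lines) == 16
        assert len(set(lines)) == 16

    def test_round_trip_isomorphic(self, tmp_path, small_dataset):
        # small synthetic network via arbitrary triple rows
        rows = [("l1", "m1", "g1"), ("l2", "m1", "g1"), ("l2", "m2", "g2"), ("l3", "m3", "g2")]
        net = build_network(triples_df(rows))
        export_network(net, tmp_path)
        back = import_network(tmp_path)
        assert nx.utils.graphs_equal(net.graph, back.graph)

    def test_unknown_format_rejected(self, tmp_path):
        net = build_network(triples_df([("l1", "m1", "g1")]))
        with pytest.raises(ParameterError):
            export_network(net, tmp_path, formats=("graphml",))
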