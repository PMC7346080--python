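import numpy as np
import pandas as pd
import pytest

from lncforge.enrichment import GeneSet
from lncforge.predict import (annotate_by_adjacency, annotate_by_network,
                              format_report, pathway_gene_lnc_table,
                              summary_report)


@pytest.fixture()
def fixture_net():
    """Three pathways, hand-wired edges and enrichment for oracle joins."""
    edges = pd.DataFrame({
        "lnc_id": ["L1", "L1", "L2", "L3"],
        "mrna_id": ["M1", "M2", "M2", "M3"],
        "r": [0.999, -0.999, 0.9991, 0.9992],
        "n_samples": 12,
    })
    symbol_of = {"M1": "GA", "M2": "GB", "M3": "GC"}
    sets = [
        GeneSet("P1", "pw one", frozenset({"GA", "GB"})),
        GeneSet("P2", "pw two", frozenset({"GC"})),
        GeneSet("P3", "pw three", frozenset({"GZ"})),   # not in network
    ]
    enrichment = {
        "down": pd.DataFrame({
            "set_id": ["P1", "P2", "P3"],
            "name": ["pw one", "pw two", "pw three"],
            "p": [0.001, 0.01, 0.2],
            "significant": [True, True, False],
        }),
        "up": pd.DataFrame(columns=["set_id", "name", "p", "significant"]),
    }
    return edges, symbol_of, sets, enrichment


def nested_loop_oracle(edges, symbol_of, sets, enrichment):
    """Independent join: for every significant pathway and every edge whose
    mRNA symbol belongs to it, emit (lnc, pathway, direction)."""
    out = set()
    for direction, table in enrichment.items():
        for _, row in table.iterrows():
            if not row.get("significant", False):
                continue
            members = next(s.genes for s in sets if s.set_id == row["set_id"])
            for _, e in edges.iterrows():
                if symbol_of[e["mrna_id"]] in members:
                    out.add((e["lnc_id"], row["set_id"], direction))
    return out


class TestNetworkRoute:
    def test_matches_nested_loop_oracle(self, fixture_net):
        edges, symbol_of, sets, enrichment = fixture_net
        records = annotate_by_network(edges, enrichment, sets, symbol_of)
        got = set(zip(records["lnc_id"], records["set_id"], records["direction"]))
        assert got == nested_loop_oracle(edges, symbol_of, sets, enrichment)

    def test_pathway_without_network_mrnas_contributes_nothing(self, fixture_net):
        edges, symbol_of, sets, enrichment = fixture_net
        enrichment["down"].loc[2, "significant"] = True   # P3 has no network gene
        records = annotate_by_network(edges, enrichment, sets, symbol_of)
        assert "P3" not in set(records["set_id"])

    def test_one_record_per_lnc_pathway(self, fixture_net):
        edges, symbol_of, sets, enrichment = fixture_net
        records = annotate_by_network(edges, enrichment, sets, symbol_of)
        assert not records.duplicated(["lnc_id", "set_id", "direction"]).any()
        # L1 partners M1(GA) and M2(GB), both in P1 -> single record, two genes
        l1p1 = records[(records["lnc_id"] == "L1") & (records["set_id"] == "P1")]
        assert len(l1p1) == 1
        assert l1p1["supporting_genes"].iloc[0] == "GA,GB"

    def test_support_chain_is_explicit(self, fixture_net):
        edges, symbol_of, sets, enrichment = fixture_net
        records = annotate_by_network(edges, enrichment, sets, symbol_of)
        set_genes = {s.set_id: s.genes for s in sets}
        partner_symbols = {
            lnc: {symbol_of[m] for m in edges.loc[edges["lnc_id"] == lnc,
                                                  "mrna_id"]}
            for lnc in edges["lnc_id"].unique()
        }
        for rec in records.itertuples():
            for gene in rec.supporting_genes.split(","):
                assert gene in set_genes[rec.set_id]
                assert gene in partner_symbols[rec.lnc_id]


class TestAdjacencyRoute:
    def make_links(self):
        return pd.DataFrame({
            "lnc_id": ["LA", "LA", "LB", "LC"],
            "gene_id": ["G1", "G2", "G1", "G3"],
            "route": ["adjacent", "adjacent", "adjacent", "sense_partner"],
            "distance": [1000, 5000, 2000, 0],
            "r": [np.nan] * 4,
        })

    def test_planted_pathway_inherited_by_linked_lnc_only(self):
        links = self.make_links()
        universe = {f"S{i}" for i in range(1, 40)} | {"SG1", "SG2", "SG3"}
        symbol_of_gene = {"G1": "SG1", "G2": "SG2", "G3": "SG3"}
        de_dir = {"SG1": "down", "SG2": "down", "SG3": "up"}
        sets = [GeneSet("P1", "planted", frozenset({"SG1", "SG2"})),
                GeneSet("P2", "other", frozenset({"S1", "S2", "S3"}))]
        subtype = {"LA": "lincRNA", "LB": "lincRNA", "LC": "antisense"}
        records = annotate_by_adjacency(links, de_dir, sets, universe,
                                        subtype, symbol_of_gene)
        by_lnc = records.groupby("lnc_id")["set_id"].agg(set).to_dict()
        assert by_lnc.get("LA") == {"P1"} and by_lnc.get("LB") == {"P1"}
        assert "LC" not in by_lnc   # SG3's up-list {SG3} alone: P-sets not enriched

    def test_lnc_with_unenriched_gene_gets_no_record(self):
        links = pd.DataFrame({
            "lnc_id": ["LX"], "gene_id": ["G9"], "route": ["adjacent"],
            "distance": [100], "r": [np.nan],
        })
        universe = {f"S{i}" for i in range(40)} | {"SG9"}
        records = annotate_by_adjacency(
            links, {"SG9": "up"},
            [GeneSet("P1", "p", frozenset({"S1", "S2"}))],
            universe, {"LX": "lincRNA"}, {"G9": "SG9"},
        )
        assert len(records) == 0

    def test_empty_links(self):
        records = annotate_by_adjacency(
            pd.DataFrame(columns=["lnc_id", "gene_id", "route", "distance", "r"]),
            {}, [], {"A"}, {}, {},
        )
        assert len(records) == 0


class TestReport:
    def make_inputs(self):
        records = pd.DataFrame({
            "lnc_id": ["L1", "L2"], "subtype": ["lincRNA", "antisense"],
            "route": ["coexpression", "sense_partner"],
            "set_id": ["P1", "P1"], "pathway_name": ["pw", "pw"],
            "direction": ["down", "down"],
            "supporting_genes": ["GA", "GB"],
        })
        classifications = pd.DataFrame({
            "lnc_id": ["L1", "L2"],
            "positional_class": ["intergenic", "natural_antisense"],
            "subtype": ["lincRNA", "antisense"],
            "partner_gene_ids": ["", "G1"],
        })
        de = pd.DataFrame({
            "probe_id": ["L1", "M1"], "probe_type": ["lncRNA", "mRNA"],
            "direction": ["down", "down"], "significant": [True, True],
        })
        edges = pd.DataFrame({"lnc_id": ["L1"], "mrna_id": ["M1"],
                              "r": [0.999], "n_samples": [12]})
        return records, classifications, de, edges

    def test_counts(self):
        report = summary_report(*self.make_inputs())
        assert report["n_significant"] == {"lncRNA": 1, "mRNA": 1}
        assert report["subtype_counts"] == {"antisense": 1, "lincRNA": 1}
        assert report["n_function_records"] == 2
        assert report["pathways_with_predictions"] == ["P1"]

    def test_empty_inputs_zeroed(self):
        empty = pd.DataFrame(columns=["lnc_id", "set_id", "supporting_genes"])
        cls = pd.DataFrame(columns=["lnc_id", "positional_class", "subtype"])
        de = pd.DataFrame(columns=["probe_id", "probe_type", "direction",
                                   "significant"])
        edges = pd.DataFrame(columns=["lnc_id", "mrna_id", "r"])
        report = summary_report(empty, cls, de, edges)
        assert report["n_function_records"] == 0
        assert report["n_network_edges"] == 0
        assert "lncforge" in format_report(report)

    def test_pathway_table_layout(self):
        records, *_ = self.make_inputs()
        table = pathway_gene_lnc_table(records)
        assert set(table["gene"]) == {"GA", "GB"}
        assert table.loc[table["gene"] == "GA", "mrna_lncrna"].iloc[0] == \
            "GA <-> L1"
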